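"""Chloroplast-derived fragment (MTPT) detection in a gene-masked
mitochondrial genome, and presence/absence of those fragments across other
mitochondrial genomes.

The search is a seed-and-extend local aligner: exact k-mer anchors on both
strands, anchor chains refined with an affine-gap Smith-Waterman over the
candidate window (match +1, mismatch -2, gap open -5, gap extend -2).
E-values use the ungapped Karlin-Altschul form E = K*m*n*exp(-lambda*S)
with fixed documented constants K=0.41, lambda=1.28 for this scoring; the
identity and coverage floors, not the e-value, are the decisive filters.

Fragment calling masks protein/tRNA/rRNA exons (N never seeds), merges hits
within 30 bp on both genomes into Table-style fragments, and annotates each
fragment with the chloroplast genes it contains (intact vs pseudo).
Homolog presence in another genome requires >=80% identity over >=90% of
the fragment length (configurable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .core import (
    AnnotationSet,
    Genome,
    Interval,
    PipelineConfig,
    mask_features,
)

logger = logging.getLogger("mitokit")

KARLIN_K = 0.41
KARLIN_LAMBDA = 1.28
SEED_K = 11
CHAIN_GAP = 60
WINDOW_PAD = 40
MERGE_DISTANCE = 30
FULL_DP_LIMIT = 2_000_000  # m*n ceiling for seedless full-matrix fallback
CLEAN_FLANK = 8  # hit ends are trimmed back to this many clean match columns


@dataclass(frozen=True)
class LocalHit:
    query_interval: Interval
    subject_interval: Interval
    strand: str
    matches: int
    aln_length: int
    score: float
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.aln_length


@dataclass
class PlastidFragment:
    number: int
    mt_interval: Interval
    cp_interval: Interval
    length: int
    identity: float
    sequence: str
    genes_contained: list[tuple[str, str]] = field(default_factory=list)

    @property
    def fragment_id(self) -> str:
        return f"frag{self.number}"


@dataclass
class HomologPresence:
    """fragment_id -> species_id -> (present, best_identity, best_coverage)."""

    table: dict[str, dict[str, tuple[bool, float, float]]]

    def present_in(self, fragment_id: str) -> list[str]:
        return sorted(
            sp for sp, (p, _, _) in self.table.get(fragment_id, {}).items() if p
        )


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def evalue(score: float, m: int, n: int) -> float:
    x = KARLIN_LAMBDA * score
    if x > 700:
        return 0.0
    return KARLIN_K * m * n * math.exp(-x)


def _alignment_columns(aln, qwin: str, swin: str):
    """Per-column (q_advance, s_advance, is_match) triples of an alignment."""
    cols = []
    coords = aln.coordinates
    for seg in range(coords.shape[1] - 1):
        q0, q1 = int(coords[0][seg]), int(coords[0][seg + 1])
        s0, s1 = int(coords[1][seg]), int(coords[1][seg + 1])
        if q1 > q0 and s1 > s0:  # diagonal run
            for t in range(q1 - q0):
                cols.append((1, 1, qwin[q0 + t] == swin[s0 + t]))
        elif q1 > q0:
            cols.extend((1, 0, False) for _ in range(q1 - q0))
        else:
            cols.extend((0, 1, False) for _ in range(s1 - s0))
    return cols


def _trim_ragged_ends(cols):
    """Indices (lo, hi) of the column sub-range whose two flanks each end in
    CLEAN_FLANK clean diagonal matches; (None, None) if none exists.

    Local alignments can wander a few score-positive columns past a true
    homology boundary; requiring clean flanks pins hit edges to it.
    """
    def clean(i):
        return all(c == (1, 1, True) for c in cols[i : i + CLEAN_FLANK])

    lo, hi = 0, len(cols) - 1
    while hi - lo + 1 >= CLEAN_FLANK:
        if not clean(lo):
            lo += 1
        elif not all(
            c == (1, 1, True) for c in cols[hi - CLEAN_FLANK + 1 : hi + 1]
        ):
            hi -= 1
        else:
            return lo, hi
    return None, None


def _seed_windows(query: str, subject: str, k: int) -> list[tuple[int, int, int, int]]:
    """Candidate (q_start, q_end, s_start, s_end) windows from k-mer anchor
    chains (0-based half-open), merged when overlapping on both axes."""
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    diags: dict[int, list[int]] = {}
    for j in range(len(subject) - k + 1):
        for i in index.get(subject[j : j + k], ()):
            diags.setdefault(j - i, []).append(i)

    windows = []
    for d, starts in diags.items():
        starts = sorted(set(starts))
        cs = ce = None
        for s in starts:
            if cs is None:
                cs, ce = s, s + k
            elif s <= ce + CHAIN_GAP:
                ce = max(ce, s + k)
            else:
                windows.append((cs, ce, d))
                cs, ce = s, s + k
        if cs is not None:
            windows.append((cs, ce, d))

    boxes = []
    for cs, ce, d in windows:
        qs = max(0, cs - WINDOW_PAD)
        qe = min(len(query), ce + WINDOW_PAD)
        ss = max(0, cs + d - WINDOW_PAD)
        se = min(len(subject), ce + d + WINDOW_PAD)
        boxes.append([qs, qe, ss, se])

    boxes.sort()
    merged: list[list[int]] = []
    for b in boxes:
        if merged and b[0] <= merged[-1][1] and not (
            b[3] <= merged[-1][2] or b[2] >= merged[-1][3]
        ):
            merged[-1][1] = max(merged[-1][1], b[1])
            merged[-1][2] = min(merged[-1][2], b[2])
            merged[-1][3] = max(merged[-1][3], b[3])
        else:
            merged.append(b)
    return [tuple(b) for b in merged]


def local_search(
    query: str,
    subject: str,
    min_identity: float = 0.70,
    max_evalue: float = 1e-5,
    k: int = SEED_K,
) -> list[LocalHit]:
    """Maximal local alignments of query against subject on both strands.

    N-containing query k-mers never seed (masked regions stay silent).
    Overlapping hits are collapsed to the highest-scoring.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = _local_aligner()
    m, n = len(query), len(subject)
    hits: list[LocalHit] = []

    for strand in ("+", "-"):
        subj = subject if strand == "+" else reverse_complement(subject)
        boxes = _seed_windows(query, subj, k)
        if not boxes and m * n <= FULL_DP_LIMIT and "N" not in query:
            boxes = [(0, m, 0, n)]
        for qs, qe, ss, se in boxes:
            qwin, swin = query[qs:qe], subj[ss:se]
            alns = aligner.align(qwin, swin)
            if len(alns) == 0 or alns.score <= 0:
                continue
            aln = alns[0]
            cols = _alignment_columns(aln, qwin, swin)
            lo, hi = _trim_ragged_ends(cols)
            if lo is None:
                continue
            kept = cols[lo : hi + 1]
            aln_len = len(kept)
            matches = sum(1 for c in kept if c[2])
            q0 = int(aln.coordinates[0][0]) + sum(c[0] for c in cols[:lo])
            s0 = int(aln.coordinates[1][0]) + sum(c[1] for c in cols[:lo])
            q1 = q0 + sum(c[0] for c in kept)
            s1 = s0 + sum(c[1] for c in kept)
            q_iv = Interval(qs + q0 + 1, qs + q1, "+")
            abs_s0, abs_s1 = ss + s0, ss + s1  # half-open on subj strand
            if strand == "+":
                s_iv = Interval(abs_s0 + 1, abs_s1, "+")
            else:
                s_iv = Interval(n - abs_s1 + 1, n - abs_s0, "-")
            hits.append(
                LocalHit(
                    q_iv, s_iv, strand,
                    matches=matches,
                    aln_length=aln_len,
                    score=float(aln.score),
                    evalue=evalue(aln.score, m, n),
                )
            )

    hits = [
        h for h in hits
        if h.identity >= min_identity and h.evalue <= max_evalue
    ]
    # collapse overlapping hits, keeping the highest-scoring
    hits.sort(key=lambda h: -h.score)
    kept: list[LocalHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            q_olap = (
                min(h.query_interval.end, g.query_interval.end)
                - max(h.query_interval.start, g.query_interval.start) + 1
            )
            if q_olap > 0.5 * min(h.query_interval.span, g.query_interval.span):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: h.query_interval.start)
    return kept


# ---------------------------------------------------------------------------
# Fragment calling
# ---------------------------------------------------------------------------


def _merge_hits(hits: list[LocalHit], distance: int) -> list[list[LocalHit]]:
    """Group hits within `distance` bp on both genomes and same strand."""
    groups: list[list[LocalHit]] = []
    for h in sorted(hits, key=lambda h: h.query_interval.start):
        placed = False
        for grp in groups:
            last = grp[-1]
            if last.strand != h.strand:
                continue
            q_gap = h.query_interval.start - last.query_interval.end - 1
            s_lo = min(x.subject_interval.start for x in grp)
            s_hi = max(x.subject_interval.end for x in grp)
            s_gap = max(
                h.subject_interval.start - s_hi - 1,
                s_lo - h.subject_interval.end - 1,
            )
            if 0 <= q_gap <= distance and s_gap <= distance:
                grp.append(h)
                placed = True
                break
        if not placed:
            groups.append([h])
    return groups


def find_cp_insertions(
    mt: Genome,
    mt_ann: AnnotationSet | None,
    cp: Genome,
    cfg: PipelineConfig | None = None,
    cp_ann: AnnotationSet | None = None,
) -> list[PlastidFragment]:
    """Chloroplast-derived fragments in the gene-masked mt genome.

    Protein/tRNA/rRNA exons are masked to N before the search so conserved
    household genes shared by both organelles cannot produce hits.  Hits
    within 30 bp on both genomes merge into one fragment; fragments are
    numbered by decreasing length.
    """
    cfg = cfg or PipelineConfig()
    if mt_ann is None or len(mt_ann) == 0:
        logger.warning(
            "no mt annotation supplied: searching UNMASKED genome; conserved "
            "organellar genes will produce spurious fragments"
        )
        masked = mt.sequence
    else:
        masked = mask_features(mt, mt_ann, {"protein", "tRNA", "rRNA"})

    hits = local_search(
        masked, cp.sequence, cfg.mtpt_min_identity, cfg.mtpt_max_evalue
    )
    fragments: list[PlastidFragment] = []
    for grp in _merge_hits(hits, MERGE_DISTANCE):
        q_start = min(h.query_interval.start for h in grp)
        q_end = max(h.query_interval.end for h in grp)
        s_start = min(h.subject_interval.start for h in grp)
        s_end = max(h.subject_interval.end for h in grp)
        strand = grp[0].strand
        matches = sum(h.matches for h in grp)
        aln_len = sum(h.aln_length for h in grp)
        mt_iv = Interval(q_start, q_end, strand)
        fragments.append(
            PlastidFragment(
                number=0,
                mt_interval=mt_iv,
                cp_interval=Interval(s_start, s_end, "+"),
                length=mt_iv.span,
                identity=matches / aln_len,
                sequence=mt.sequence[q_start - 1 : q_end],
            )
        )

    fragments.sort(key=lambda f: (-f.length, f.mt_interval.start))
    for i, f in enumerate(fragments, start=1):
        f.number = i
        if cp_ann is not None:
            f.genes_contained = _contained_genes(f, cp_ann, cp)
    return fragments


def _contained_genes(
    frag: PlastidFragment, cp_ann: AnnotationSet, cp: Genome
) -> list[tuple[str, str]]:
    """Chloroplast genes overlapping the fragment's cp source interval.

    A gene is intact iff its full span lies inside the fragment and, for
    protein genes, the transferred mt copy still has an open reading frame
    (no internal stop, length a codon multiple); otherwise it is pseudo.
    """
    from .editing import translate_codon

    out = []
    for g in cp_ann.genes:
        span = g.genomic_span
        if not span.overlaps(frag.cp_interval):
            continue
        intact = frag.cp_interval.contains(span)
        if intact and g.category == "protein":
            # map the gene span through the (colinear) fragment into mt
            off_lo = span.start - frag.cp_interval.start
            off_hi = span.end - frag.cp_interval.start
            if frag.mt_interval.strand == "+":
                sub = frag.sequence[off_lo : off_hi + 1]
            else:  # cp-colinear view of a reverse-strand insertion
                sub = reverse_complement(frag.sequence)[off_lo : off_hi + 1]
            if span.strand == "-":
                sub = reverse_complement(sub)
            if len(sub) % 3 != 0:
                intact = False
            else:
                aas = [translate_codon(sub[i : i + 3])
                       for i in range(0, len(sub), 3)
                       if set(sub[i : i + 3]) <= set("ACGT")]
                if "*" in aas[:-1]:
                    intact = False
        out.append((g.name, "intact" if intact else "pseudo"))
    return out


def find_homologs(
    fragments: list[PlastidFragment],
    other_genomes: list[Genome],
    cfg: PipelineConfig | None = None,
) -> HomologPresence:
    """Best-hit presence of each fragment across other genomes.

    Presence requires best identity >= homolog_min_identity and coverage
    (alignment length over fragment length) >= homolog_min_coverage.
    """
    cfg = cfg or PipelineConfig()
    table: dict[str, dict[str, tuple[bool, float, float]]] = {}
    for frag in fragments:
        row: dict[str, tuple[bool, float, float]] = {}
        for g in other_genomes:
            hits = local_search(frag.sequence, g.sequence,
                                min_identity=0.5, max_evalue=10.0)
            if hits:
                best = max(hits, key=lambda h: h.score)
                ident = best.identity
                cov = best.aln_length / len(frag.sequence)
            else:
                ident = cov = 0.0
            present = (
                ident >= cfg.homolog_min_identity
                and cov >= cfg.homolog_min_coverage
            )
            row[g.id] = (present, ident, cov)
        table[frag.fragment_id] = row
    return HomologPresence(table)


def fragments_to_rows(fragments: list[PlastidFragment]) -> list[dict]:
    """Table-style rows: No., Length, Position "start-end", Genes Contained."""
    rows = []
    for f in fragments:
        genes = ";".join(
            f"{name}[{status}]" for name, status in f.genes_contained
        )
        rows.append(
            {
                "No.": f.number,
                "Length": f.length,
                "Position": f"{f.mt_interval.start}-{f.mt_interval.end}",
                "Identity": round(f.identity, 4),
                "Genes Contained": genes,
            }
        )
    return rows
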