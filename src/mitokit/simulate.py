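"""Deterministic synthetic mt/cp genome bundles with planted ground truth.

The generator emulates the structure of a plant mitochondrial genome at desk
scale: a circular molecule with forward- and reverse-strand genes, cis- and
trans-spliced introns, an identical duplicated gene pair ("-1/-2"), a
pseudogene, native and plastid-derived tRNAs, planted C->U (and rare U->C)
RNA edits in per-gene cDNAs, chloroplast-derived fragments, long direct and
inverted repeats, and perfect SSR loci at the screening minima.

Planted features never overlap genes or each other, and fragment/repeat/SSR
planting *overwrites* intergenic background rather than inserting, so gene
coordinates stay valid and every truth record is verifiable against the
emitted sequences by direct substring inspection.

All randomness flows from a single integer seed; identical seeds give
byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import reverse_complement

from .core import (
    AnnotationSet,
    GeneModel,
    Genome,
    Interval,
    PipelineConfig,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# Desk-scale defaults echoing a sacred-lotus-like genome composition: GC ~0.48 for
# the mitochondrial background, lower for the chloroplast donor.
MT_GC = 0.48
CP_GC = 0.38

MT_GENE_NAMES = [
    "rps19", "nad3", "nad1", "mttB", "trnM(CAT)", "rrn18", "trnN(GTT)",
    "atp9", "ccmB", "cox1", "sdh4", "rps12", "cob", "atp6", "nad7",
    "matR", "rps4", "ccmC", "nad4L", "rpl16",
]
CP_GENE_PLAN = [
    ("psbA", "protein", 600),
    ("trnH(GTG)", "tRNA", 75),
    ("rbcL", "protein", 450),
    ("trnN(GTT)", "tRNA", 72),
    ("ycf2", "protein", 900),
    ("trnM(CAT)", "tRNA", 74),
]


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic bundle.

    planted_edits:      (gene_id, cds_pos, direction) with direction C2U/U2C
    planted_fragments:  (mt Interval, cp Interval) per chloroplast fragment
    planted_repeats:    dicts with kind/interval_a/interval_b/length
    planted_ssrs:       (motif, n_units, start)
    """

    rng_seed: int
    planted_edits: list[tuple[str, int, str]] = field(default_factory=list)
    planted_fragments: list[tuple[Interval, Interval]] = field(default_factory=list)
    planted_repeats: list[dict] = field(default_factory=list)
    planted_ssrs: list[tuple[str, int, int]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def iv(i: Interval) -> dict:
            return {"start": i.start, "end": i.end, "strand": i.strand}

        doc = {
            "rng_seed": self.rng_seed,
            "planted_edits": [list(e) for e in self.planted_edits],
            "planted_fragments": [
                {"mt": iv(a), "cp": iv(b)} for a, b in self.planted_fragments
            ],
            "planted_repeats": [
                {
                    "kind": r["kind"],
                    "interval_a": iv(r["interval_a"]),
                    "interval_b": iv(r["interval_b"]),
                    "length": r["length"],
                }
                for r in self.planted_repeats
            ],
            "planted_ssrs": [list(s) for s in self.planted_ssrs],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text())

        def iv(d: dict) -> Interval:
            return Interval(d["start"], d["end"], d["strand"])

        return cls(
            rng_seed=doc["rng_seed"],
            planted_edits=[tuple(e) for e in doc["planted_edits"]],
            planted_fragments=[
                (iv(f["mt"]), iv(f["cp"])) for f in doc["planted_fragments"]
            ],
            planted_repeats=[
                {
                    "kind": r["kind"],
                    "interval_a": iv(r["interval_a"]),
                    "interval_b": iv(r["interval_b"]),
                    "length": r["length"],
                }
                for r in doc["planted_repeats"]
            ],
            planted_ssrs=[tuple(s) for s in doc["planted_ssrs"]],
        )


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _rng(seed, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _random_background(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(BASES, size=length, p=p)
    return bytearray(arr.tobytes())


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG start, random sense codons, one stop; no internal stops."""
    if n_codons < 3:
        raise ValueError("CDS needs at least 3 codons")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _write_segment(seq: bytearray, iv: Interval, piece: str) -> None:
    """Write `piece` at interval coordinates; piece is given on iv.strand."""
    if iv.strand == "-":
        piece = reverse_complement(piece)
    assert len(piece) == iv.span
    seq[iv.start - 1 : iv.end] = piece.encode("ascii")


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _occupied(ann: AnnotationSet | None, truth: SyntheticTruth | None) -> list[tuple[int, int]]:
    ivs: list[tuple[int, int]] = []
    if ann is not None:
        for g in ann.genes:
            for e in g.exons:
                ivs.append((e.start, e.end))
    if truth is not None:
        for mt_iv, _ in truth.planted_fragments:
            ivs.append((mt_iv.start, mt_iv.end))
        for r in truth.planted_repeats:
            for iv in (r["interval_a"], r["interval_b"]):
                ivs.append((iv.start, iv.end))
        for motif, n, start in truth.planted_ssrs:
            ivs.append((start, start + len(motif) * n - 1))
    return _merge_intervals(ivs)


def _free_gaps(
    occupied: list[tuple[int, int]], genome_len: int, margin: int = 25
) -> list[tuple[int, int]]:
    """Unoccupied 1-based inclusive gaps, shrunk by a safety margin."""
    gaps = []
    prev_end = 0
    for s, e in occupied + [(genome_len + 1, genome_len + 1)]:
        if s - 1 - prev_end >= 2 * margin + 1:
            gaps.append((prev_end + 1 + margin, s - 1 - margin))
        prev_end = max(prev_end, e)
    return gaps


def _take_slot(
    occupied: list[tuple[int, int]], genome_len: int, length: int,
    rng: np.random.Generator, margin: int = 25,
) -> int:
    """Reserve a free start position for a feature of the given length."""
    gaps = [(s, e) for s, e in _free_gaps(occupied, genome_len, margin)
            if e - s + 1 >= length]
    if not gaps:
        raise ValueError(
            f"no intergenic space for a {length}-bp feature "
            f"(genome {genome_len} bp, {len(occupied)} occupied intervals)"
        )
    s, e = gaps[int(rng.integers(len(gaps)))]
    start = s + int(rng.integers(e - s + 2 - length))
    occupied[:] = _merge_intervals(occupied + [(start, start + length - 1)])
    return start


# ---------------------------------------------------------------------------
# Genome generators
# ---------------------------------------------------------------------------


def generate_mt_genome(
    config: PipelineConfig,
    n_genes: int = 12,
    genome_len: int = 40_000,
    gc: float = MT_GC,
) -> tuple[Genome, AnnotationSet, SyntheticTruth]:
    """Circular synthetic mitochondrial genome with annotated genes.

    The first gene slots carry the structural variety the downstream stages
    need: an identical duplicated protein pair ("-1/-2"), a cis two-exon
    gene, a trans-spliced gene with exon groups on both strands, a
    pseudogene, then tRNA/rRNA/plastid-derived tRNA and plain proteins.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    min_len = n_genes * 300 + (n_genes + 1) * 120
    if genome_len < min_len:
        raise ValueError(
            f"genome_len {genome_len} too small for {n_genes} genes: "
            f"needs >= {min_len} bp ({n_genes} x 300 bp plus spacers)"
        )
    seed = config.rng_seed
    rng = _rng(seed, 0)
    seq = _random_background(rng, genome_len, gc)

    genes: list[GeneModel] = []
    cursor = 1 + int(rng.integers(120, 240))

    def spacer() -> int:
        return int(rng.integers(150, 400))

    def place(length: int, strand: str) -> Interval:
        nonlocal cursor
        if cursor + length - 1 > genome_len - 120:
            raise ValueError(
                f"infeasible packing: ran out of sequence at {cursor} while "
                f"placing a {length}-bp feature in a {genome_len}-bp genome"
            )
        iv = Interval(cursor, cursor + length - 1, strand)
        cursor = iv.end + 1 + spacer()
        return iv

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    name_pool = list(MT_GENE_NAMES)

    def next_name(preferred: str | None = None) -> str:
        if preferred is not None and preferred in name_pool:
            name_pool.remove(preferred)
            return preferred
        return name_pool.pop(0) if name_pool else f"orf{len(genes) + 1}"

    i = 0
    dup_cds: str | None = None
    dup_base: str | None = None
    while i < n_genes:
        role = i if i < 8 else 8
        if role in (0, 1) and n_genes >= 2:
            # identical duplicated pair, below the long-repeat length floor
            if dup_cds is None:
                dup_cds = _random_cds(rng, 110)  # 330 bp
                dup_base = next_name("rps19")
            copy = 1 if role == 0 else 2
            iv = place(len(dup_cds), rand_strand())
            _write_segment(seq, iv, dup_cds)
            genes.append(
                GeneModel(f"{dup_base}-{copy}", f"{dup_base}-{copy}", "protein", [iv])
            )
        elif role == 2:
            # cis-spliced two-exon protein gene
            name = next_name("nad3")
            cds = _random_cds(rng, 140)  # 420 bp
            strand = rand_strand()
            e1_len = 180
            intron = int(rng.integers(140, 220))
            total = len(cds) + intron
            iv_all = place(total, strand)
            if strand == "+":
                ex1 = Interval(iv_all.start, iv_all.start + e1_len - 1, "+")
                ex2 = Interval(ex1.end + intron + 1, iv_all.end, "+")
                order = [ex1, ex2]
            else:
                ex2 = Interval(iv_all.start, iv_all.end - e1_len - intron, "-")
                ex1 = Interval(iv_all.end - e1_len + 1, iv_all.end, "-")
                order = [ex1, ex2]
            _write_segment(seq, order[0], cds[:e1_len])
            _write_segment(seq, order[1], cds[e1_len:])
            genes.append(GeneModel(name, name, "protein", order))
        elif role == 3:
            # trans-spliced gene: two exon groups far apart, opposite strands
            name = next_name("nad1")
            cds = _random_cds(rng, 130)  # 390 bp
            e1_len = 150
            iv1 = place(e1_len, "+")
            iv2 = place(len(cds) - e1_len, "-")
            _write_segment(seq, iv1, cds[:e1_len])
            _write_segment(seq, iv2, cds[e1_len:])
            genes.append(
                GeneModel(name, name, "protein", [iv1, iv2], trans_spliced=True)
            )
        elif role == 4:
            # pseudogene: no reading frame maintained
            name = next_name("mttB")
            length = 301
            iv = place(length, rand_strand())
            piece = _random_background(rng, length, gc).decode("ascii")
            _write_segment(seq, iv, piece)
            genes.append(GeneModel(name, name, "pseudogene", [iv]))
        elif role == 5:
            name = next_name("trnM(CAT)")
            iv = place(75, rand_strand())
            genes.append(GeneModel(name, name, "tRNA", [iv]))
        elif role == 6:
            name = next_name("rrn18")
            iv = place(160, rand_strand())
            genes.append(GeneModel(name, name, "rRNA", [iv]))
        elif role == 7:
            name = next_name("trnN(GTT)")
            iv = place(72, rand_strand())
            genes.append(
                GeneModel(f"{name}-cp", f"{name}-cp", "tRNA", [iv],
                          origin="plastid_derived")
            )
        else:
            name = next_name()
            cds = _random_cds(rng, int(rng.integers(100, 160)))
            iv = place(len(cds), rand_strand())
            _write_segment(seq, iv, cds)
            genes.append(GeneModel(name, name, "protein", [iv]))
        i += 1

    genome = Genome("mt_synthetic", seq.decode("ascii"), "circular")
    ann = AnnotationSet(genome_id=genome.id, genes=genes)
    ann.validate_against(genome)
    return genome, ann, SyntheticTruth(rng_seed=seed)


def generate_cp_genome(
    seed: int, genome_len: int = 12_000, gc: float = CP_GC
) -> tuple[Genome, AnnotationSet]:
    """Small circular chloroplast donor genome with a few annotated genes."""
    rng = _rng(seed, 1)
    seq = _random_background(rng, genome_len, gc)
    genes = []
    cursor = 200
    for name, category, length in CP_GENE_PLAN:
        if cursor + length > genome_len - 200:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        iv = Interval(cursor, cursor + length - 1, strand)
        if category == "protein":
            _write_segment(seq, iv, _random_cds(rng, length // 3))
        genes.append(GeneModel(name, name, category, [iv]))
        cursor = iv.end + 1 + int(rng.integers(250, 600))
    genome = Genome("cp_synthetic", seq.decode("ascii"), "circular")
    return genome, AnnotationSet(genome_id=genome.id, genes=genes)


# ---------------------------------------------------------------------------
# cDNA with planted edits
# ---------------------------------------------------------------------------


def generate_cdna(
    genome: Genome,
    ann: AnnotationSet,
    truth_edits: list[tuple[str, int, str]],
    noise_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Per-gene cDNA = spliced CDS with planted edits (and optional noise).

    A C2U edit flips C->T in the cDNA; a U2C edit flips T->C.  Noise applies
    uniform random substitutions at `noise_rate` per position, skipping
    planted edit positions.
    """
    from .core import splice_cds

    rng = _rng(seed, 2)
    by_gene: dict[str, list[tuple[int, str]]] = {}
    for gene_id, pos, direction in truth_edits:
        by_gene.setdefault(gene_id, []).append((pos, direction))

    cdna: dict[str, str] = {}
    for g in ann.genes:
        if g.category not in ("protein", "pseudogene"):
            continue
        cds = splice_cds(genome, g)
        arr = bytearray(cds, "ascii")
        edited_pos = set()
        for pos, direction in by_gene.get(g.gene_id, []):
            if not (1 <= pos <= len(arr)):
                raise ValueError(f"{g.gene_id}: edit position {pos} outside CDS")
            base = chr(arr[pos - 1])
            if direction == "C2U":
                if base != "C":
                    raise ValueError(
                        f"{g.gene_id}: C2U edit at {pos} but CDS base is {base}"
                    )
                arr[pos - 1] = ord("T")
            elif direction == "U2C":
                if base != "T":
                    raise ValueError(
                        f"{g.gene_id}: U2C edit at {pos} but CDS base is {base}"
                    )
                arr[pos - 1] = ord("C")
            else:
                raise ValueError(f"unknown edit direction {direction!r}")
            edited_pos.add(pos)
        if noise_rate > 0:
            hits = np.flatnonzero(rng.random(len(arr)) < noise_rate)
            for idx in hits:
                if idx + 1 in edited_pos:
                    continue
                old = chr(arr[idx])
                alts = [b for b in "ACGT" if b != old]
                arr[idx] = ord(alts[int(rng.integers(3))])
        cdna[g.gene_id] = arr.decode("ascii")
    return cdna


def sample_edit_sites(
    genome: Genome,
    ann: AnnotationSet,
    n_c2u: int = 30,
    n_u2c: int = 3,
    seed: int = 0,
    min_pseudogene_edits: int = 2,
) -> list[tuple[str, int, str]]:
    """Draw random editable positions: C sites for C2U, T sites for U2C.

    At least `min_pseudogene_edits` C2U edits land in the pseudogene (if one
    exists) so the unpartitioned class is exercised.
    """
    from .core import splice_cds

    rng = _rng(seed, 3)
    c_sites: list[tuple[str, int]] = []
    t_sites: list[tuple[str, int]] = []
    pseudo_c: list[tuple[str, int]] = []
    for g in ann.genes:
        if g.category not in ("protein", "pseudogene"):
            continue
        cds = splice_cds(genome, g)
        for i, b in enumerate(cds, start=1):
            if b == "C":
                (pseudo_c if g.category == "pseudogene" else c_sites).append(
                    (g.gene_id, i)
                )
            elif b == "T" and g.category == "protein":
                t_sites.append((g.gene_id, i))

    edits: list[tuple[str, int, str]] = []
    taken: set[tuple[str, int]] = set()

    def draw(pool: list[tuple[str, int]], n: int, direction: str) -> None:
        avail = [p for p in pool if p not in taken]
        if n > len(avail):
            raise ValueError(f"cannot draw {n} {direction} sites from {len(avail)}")
        idx = rng.choice(len(avail), size=n, replace=False)
        for j in sorted(int(x) for x in idx):
            gene_id, pos = avail[j]
            taken.add((gene_id, pos))
            edits.append((gene_id, pos, direction))

    n_pseudo = min(min_pseudogene_edits, len(pseudo_c), n_c2u)
    draw(pseudo_c, n_pseudo, "C2U")
    draw(c_sites, n_c2u - n_pseudo, "C2U")
    draw(t_sites, n_u2c, "U2C")
    return sorted(edits)


# ---------------------------------------------------------------------------
# Plastid fragments, long repeats, SSRs
# ---------------------------------------------------------------------------


FLANK_DIVERGE = 8  # bases outside each planted locus forced to mismatch


def _force_mismatch(seq: bytearray, pos: int, avoid: str,
                    rng: np.random.Generator) -> None:
    """Set 1-based position `pos` to a random base different from `avoid`."""
    options = [b for b in "ACGT" if b != avoid]
    seq[pos - 1] = ord(options[int(rng.integers(len(options)))])


def _diverge_fragment_flanks(
    seq: bytearray, mt_iv: Interval, cp_seq: str, cp_iv: Interval,
    rng: np.random.Generator,
) -> None:
    """Make the mt bases flanking a planted fragment mismatch the cp
    continuation, so the maximal alignment boundary is exactly the planted
    boundary (chance continuation would blur the recorded truth)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L_mt, L_cp = len(seq), len(cp_seq)
    for t in range(1, FLANK_DIVERGE + 1):
        if mt_iv.strand == "+":
            pairs = [
                (mt_iv.start - t, cp_iv.start - t, False),
                (mt_iv.end + t, cp_iv.end + t, False),
            ]
        else:
            pairs = [
                (mt_iv.start - t, cp_iv.end + t, True),
                (mt_iv.end + t, cp_iv.start - t, True),
            ]
        for mp, cpp, complement in pairs:
            if not (1 <= mp <= L_mt and 1 <= cpp <= L_cp):
                continue
            base = cp_seq[cpp - 1]
            if complement:
                base = comp.get(base, base)
            _force_mismatch(seq, mp, base, rng)


def plant_cp_fragments(
    mt: Genome,
    cp: Genome,
    lengths: list[int],
    divergence: float = 0.0,
    seed: int = 0,
    mt_ann: AnnotationSet | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[Genome, SyntheticTruth]:
    """Copy disjoint chloroplast segments into intergenic mt loci.

    Each copy receives independent per-base substitutions at `divergence`.
    The mt background at the target locus is overwritten (length preserved);
    both strands are used.
    """
    rng = _rng(seed, 4)
    truth = truth or SyntheticTruth(rng_seed=seed)
    occupied = _occupied(mt_ann, truth)
    seq = bytearray(mt.sequence, "ascii")

    # disjoint source intervals in the cp genome
    if sum(lengths) + 40 * len(lengths) > len(cp):
        raise ValueError("cp genome too small for requested fragment lengths")
    cp_cursor = 1 + int(rng.integers(50))
    for k, length in enumerate(lengths):
        if length < 1:
            raise ValueError("fragment length must be >= 1")
        cp_iv = Interval(cp_cursor, cp_cursor + length - 1, "+")
        if cp_iv.end > len(cp):
            raise ValueError("cp genome too small for requested fragment lengths")
        cp_cursor = cp_iv.end + 1 + int(rng.integers(20, 60))
        strand = "+" if k % 2 == 0 else "-"
        piece = cp.sequence[cp_iv.start - 1 : cp_iv.end]
        if divergence > 0:
            arr = bytearray(piece, "ascii")
            hits = np.flatnonzero(rng.random(len(arr)) < divergence)
            for idx in hits:
                alts = [b for b in "ACGT" if b != chr(arr[idx])]
                arr[idx] = ord(alts[int(rng.integers(3))])
            piece = arr.decode("ascii")
        start = _take_slot(occupied, len(mt), length, rng)
        mt_iv = Interval(start, start + length - 1, strand)
        _write_segment(seq, mt_iv, piece)
        _diverge_fragment_flanks(seq, mt_iv, cp.sequence, cp_iv, rng)
        truth.planted_fragments.append((mt_iv, cp_iv))

    return Genome(mt.id, seq.decode("ascii"), mt.topology), truth


def plant_repeats_and_ssrs(
    genome: Genome,
    spec: dict,
    seed: int = 0,
    ann: AnnotationSet | None = None,
    truth: SyntheticTruth | None = None,
    gc: float = MT_GC,
) -> tuple[Genome, SyntheticTruth]:
    """Plant long direct/inverted repeat pairs and perfect SSR runs.

    spec keys: "direct" and "inverted" (lists of repeat lengths >= 20) and
    "ssrs" (list of (motif, n_units)).  SSR flanking bases are set so the
    planted run is maximal exactly as recorded.
    """
    rng = _rng(seed, 5)
    truth = truth or SyntheticTruth(rng_seed=seed)
    occupied = _occupied(ann, truth)
    seq = bytearray(genome.sequence, "ascii")

    for kind in ("direct", "inverted"):
        for length in spec.get(kind, []):
            if length < 20:
                raise ValueError(f"repeat length {length} < 20")
            core = _random_background(rng, length, gc).decode("ascii")
            s1 = _take_slot(occupied, len(genome), length, rng)
            s2 = _take_slot(occupied, len(genome), length, rng)
            iv1 = Interval(s1, s1 + length - 1, "+")
            second = core if kind == "direct" else reverse_complement(core)
            iv2 = Interval(s2, s2 + length - 1, "+")
            _write_segment(seq, iv1, core)
            _write_segment(seq, iv2, second)
            # force the flanks of copy B to mismatch copy A's continuation
            # so the repeat boundary is exactly as recorded
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            for t in range(1, FLANK_DIVERGE + 1):
                if kind == "direct":
                    pairs = [
                        (iv2.start - t, iv1.start - t, False),
                        (iv2.end + t, iv1.end + t, False),
                    ]
                else:
                    pairs = [
                        (iv2.start - t, iv1.end + t, True),
                        (iv2.end + t, iv1.start - t, True),
                    ]
                for bp_, ap_, complement in pairs:
                    if not (1 <= bp_ <= len(genome) and 1 <= ap_ <= len(genome)):
                        continue
                    base = chr(seq[ap_ - 1])
                    if complement:
                        base = comp.get(base, base)
                    _force_mismatch(seq, bp_, base, rng)
            a, b = sorted((iv1, iv2), key=lambda i: i.start)
            truth.planted_repeats.append(
                {"kind": kind, "interval_a": a, "interval_b": b, "length": length}
            )

    for motif, n_units in spec.get("ssrs", []):
        motif = motif.upper()
        u = len(motif)
        if not (1 <= u <= 6):
            raise ValueError(f"SSR unit length {u} not in 1..6")
        if u > 1 and any(motif == motif[:p] * (u // p) for p in range(1, u) if u % p == 0):
            raise ValueError(f"SSR motif {motif!r} is not primitive")
        run = motif * n_units
        start = _take_slot(occupied, len(genome), len(run) + 2, rng) + 1
        iv = Interval(start, start + len(run) - 1, "+")
        _write_segment(seq, iv, run)
        # fix flanks so the run is maximal exactly as planted
        left_ok = [b for b in "ACGT" if b != motif[-1]]
        right_ok = [b for b in "ACGT" if b != motif[0]]
        seq[start - 2] = ord(left_ok[int(rng.integers(len(left_ok)))])
        seq[iv.end] = ord(right_ok[int(rng.integers(len(right_ok)))])
        truth.planted_ssrs.append((motif, n_units, start))

    return Genome(genome.id, seq.decode("ascii"), genome.topology), truth


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

DEFAULT_FRAGMENT_LENGTHS = (1998, 621, 297, 141, 84, 54)
DEFAULT_REPEAT_SPEC = {
    "direct": [600, 550],
    "inverted": [700, 520],
    "ssrs": [("A", 10), ("AT", 5), ("AGC", 4), ("AATG", 3), ("AACTG", 3),
             ("AACGTG", 3)],
}


@dataclass
class Bundle:
    """A complete synthetic data bundle."""

    mt: Genome
    mt_ann: AnnotationSet
    cp: Genome
    cp_ann: AnnotationSet
    cdna: dict[str, str]
    truth: SyntheticTruth
    config: PipelineConfig


def generate_bundle(
    seed: int = 1,
    config: PipelineConfig | None = None,
    n_genes: int = 12,
    genome_len: int = 40_000,
    cp_len: int = 12_000,
    n_c2u: int = 30,
    n_u2c: int = 3,
    fragment_lengths: tuple[int, ...] = DEFAULT_FRAGMENT_LENGTHS,
    divergence: float = 0.0,
    repeat_spec: dict | None = None,
    noise_rate: float = 0.0,
) -> Bundle:
    """Generate an mt/cp pair with every class of planted truth.

    Defaults mirror the real analysis conditions at desk scale: 40-kb circular mt
    genome with 12 genes, 12-kb cp donor, 30 C->U plus 3 U->C edits, six
    fragments spanning the published 54-1998 bp length range, two direct and
    two inverted long repeats, and one SSR per unit length at exactly the
    screening minima.
    """
    config = config or PipelineConfig(rng_seed=seed)
    if config.rng_seed != seed:
        d = config.as_dict()
        d["ssr_min_units"] = {int(k): v for k, v in d["ssr_min_units"].items()}
        d["rng_seed"] = seed
        config = PipelineConfig(**d)

    mt, mt_ann, truth = generate_mt_genome(config, n_genes, genome_len)
    cp, cp_ann = generate_cp_genome(seed, cp_len)
    mt, truth = plant_cp_fragments(
        mt, cp, list(fragment_lengths), divergence, seed, mt_ann, truth
    )
    mt, truth = plant_repeats_and_ssrs(
        mt, repeat_spec if repeat_spec is not None else DEFAULT_REPEAT_SPEC,
        seed, mt_ann, truth,
    )
    edits = sample_edit_sites(mt, mt_ann, n_c2u=n_c2u, n_u2c=n_u2c, seed=seed)
    truth.planted_edits = edits
    cdna = generate_cdna(mt, mt_ann, edits, noise_rate=noise_rate, seed=seed)
    return Bundle(mt, mt_ann, cp, cp_ann, cdna, truth, config)
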