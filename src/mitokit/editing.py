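"""RNA-editing site calling from DNA/cDNA pairs, codon-effect classification,
per-gene editing frequencies, and cross-species shared-edit comparison.

Plant mitochondrial mRNAs are edited post-transcriptionally, overwhelmingly
C-to-U with rare U-to-C cases.  An edit is therefore called only at alignment
columns where the genomic DNA has C and the cDNA has T (C2U) or DNA has T and
cDNA has C (U2C); every other mismatch is reported as a non-edit discrepancy
(sequencing noise or a variant), never as an edit.

Codon effects are classified with the standard genetic code (plant
mitochondria use translation table 1): an edit is synonymous iff the edited
codon translates to the same amino acid, nonsynonymous otherwise.  Edits in
a pseudogene, which has no reading frame, are "unpartitioned".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table

from .core import GeneModel, cds_to_genomic, round_half_up

logger = logging.getLogger("mitokit")

_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODE[_stop] = "*"


def translate_codon(codon: str) -> str:
    """Single-letter amino acid (or ``*``) for a codon, standard code."""
    try:
        return _CODE[codon.upper()]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


@dataclass(frozen=True)
class EditingSite:
    gene_id: str
    cds_pos: int
    direction: str  # C2U or U2C
    genomic_pos: int | None = None
    codon_index: int | None = None
    codon_pos: int | None = None
    ref_codon: str | None = None
    edited_codon: str | None = None
    ref_aa: str | None = None
    edited_aa: str | None = None
    effect: str = "unpartitioned"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.gene_id, self.cds_pos, self.direction)


@dataclass(frozen=True)
class Discrepancy:
    """A DNA/cDNA mismatch that is not a C<->T pair (or an indel column)."""

    gene_id: str
    cds_pos: int | None
    dna_base: str
    cdna_base: str


@dataclass
class EditCallResult:
    sites: list[EditingSite]
    discrepancies: list[Discrepancy]


@dataclass(frozen=True)
class SharedEditSummary:
    species_a: str
    species_b: str
    n_shared: int
    n_unique_a: int
    n_unique_b: int


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

#: Global DNA/cDNA alignment scoring: match +1, mismatch -1, gap open -5,
#: gap extend -2 (the opening gap position costs -5, each further -2).
def _make_aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def align_dna_cdna(cds: str, cdna: str) -> tuple[str, str, float]:
    """Globally align a genomic CDS against its cDNA.

    Returns (gapped_cds, gapped_cdna, score).  With equal-length colinear
    inputs the alignment is gap-free.  A length ratio outside [0.8, 1.25]
    triggers a warning but the alignment is still returned.
    """
    if not cds or not cdna:
        raise ValueError("empty sequence")
    ratio = len(cdna) / len(cds)
    if not (0.8 <= ratio <= 1.25):
        warnings.warn(
            f"DNA/cDNA length ratio {ratio:.2f} outside [0.8, 1.25]; "
            "alignment may be unreliable",
            stacklevel=2,
        )
    aln = _make_aligner("global").align(cds, cdna)[0]
    return str(aln[0]), str(aln[1]), aln.score


# ---------------------------------------------------------------------------
# Edit classification
# ---------------------------------------------------------------------------

_EDITABLE = {"C2U": "C", "U2C": "T"}
_EDITED_TO = {"C2U": "T", "U2C": "C"}


def classify_edit(
    ref_codon: str, codon_pos: int, direction: str
) -> tuple[str, str, str, str]:
    """Apply an edit to a codon and classify its effect.

    Returns (edited_codon, ref_aa, edited_aa, effect) where effect is
    "synonymous" iff the amino acid is unchanged, else "nonsynonymous".
    """
    ref_codon = ref_codon.upper()
    if len(ref_codon) != 3 or not (1 <= codon_pos <= 3):
        raise ValueError(f"bad codon {ref_codon!r} / position {codon_pos}")
    if direction not in _EDITABLE:
        raise ValueError(f"unknown direction {direction!r}")
    if ref_codon[codon_pos - 1] != _EDITABLE[direction]:
        raise ValueError(
            f"codon {ref_codon} position {codon_pos} has "
            f"{ref_codon[codon_pos - 1]}, not editable for {direction}"
        )
    edited = (
        ref_codon[: codon_pos - 1] + _EDITED_TO[direction] + ref_codon[codon_pos:]
    )
    ref_aa = translate_codon(ref_codon)
    edited_aa = translate_codon(edited)
    effect = "synonymous" if ref_aa == edited_aa else "nonsynonymous"
    return edited, ref_aa, edited_aa, effect


# ---------------------------------------------------------------------------
# Edit calling
# ---------------------------------------------------------------------------


def call_edits(
    cds: str,
    cdna: str,
    gene: GeneModel | None = None,
    gene_id: str | None = None,
) -> EditCallResult:
    """Call editing sites from a genomic CDS and its cDNA.

    Only C<->T alignment columns are edit candidates; all other mismatches
    (and indel columns) become Discrepancy records.  Codon context is filled
    for protein genes; pseudogene edits are left "unpartitioned".
    """
    if gene is not None:
        gene_id = gene.gene_id
        is_protein = gene.category == "protein"
    else:
        gene_id = gene_id or "?"
        is_protein = True

    gapped_cds, gapped_cdna, _ = align_dna_cdna(cds, cdna)
    sites: list[EditingSite] = []
    discrepancies: list[Discrepancy] = []
    cds_pos = 0
    for a, b in zip(gapped_cds, gapped_cdna):
        if a != "-":
            cds_pos += 1
        if a == b:
            continue
        if a == "-" or b == "-":
            discrepancies.append(
                Discrepancy(gene_id, cds_pos if a != "-" else None, a, b)
            )
            continue
        if (a, b) == ("C", "T"):
            direction = "C2U"
        elif (a, b) == ("T", "C"):
            direction = "U2C"
        else:
            discrepancies.append(Discrepancy(gene_id, cds_pos, a, b))
            continue

        genomic_pos = cds_to_genomic(gene, cds_pos) if gene is not None else None
        if is_protein:
            codon_index = (cds_pos - 1) // 3 + 1
            codon_pos = (cds_pos - 1) % 3 + 1
            codon_start = (codon_index - 1) * 3
            ref_codon = cds[codon_start : codon_start + 3]
            if len(ref_codon) == 3 and set(ref_codon) <= set("ACGT"):
                edited_codon, ref_aa, edited_aa, effect = classify_edit(
                    ref_codon, codon_pos, direction
                )
            else:  # trailing partial codon or ambiguous base
                edited_codon = ref_aa = edited_aa = None
                effect = "unpartitioned"
            sites.append(
                EditingSite(
                    gene_id, cds_pos, direction, genomic_pos,
                    codon_index, codon_pos, ref_codon or None,
                    edited_codon, ref_aa, edited_aa, effect,
                )
            )
        else:
            sites.append(
                EditingSite(gene_id, cds_pos, direction, genomic_pos,
                            effect="unpartitioned")
            )
    return EditCallResult(sites, discrepancies)


def call_all_edits(
    genome,
    ann,
    cdna_map: dict[str, str],
    premrna_genes: set[str] | frozenset[str] = frozenset(),
) -> EditCallResult:
    """Run edit calling over every protein/pseudogene with a cDNA.

    Genes without a cDNA record are skipped with a logged reason.  Genes in
    `premrna_genes` had their amplicon derived from unspliced pre-mRNA, so
    the cDNA is compared against the unspliced genomic span; positions that
    fall inside exons are mapped back to spliced-CDS coordinates for codon
    classification, intron positions stay unpartitioned.
    """
    from .core import premrna, splice_cds

    sites: list[EditingSite] = []
    discrepancies: list[Discrepancy] = []
    for g in ann.genes:
        if g.category not in ("protein", "pseudogene"):
            continue
        cdna = cdna_map.get(g.gene_id)
        if cdna is None:
            logger.info("gene %s skipped: no cDNA amplicon", g.gene_id)
            continue
        if g.gene_id in premrna_genes:
            res = _call_edits_premrna(genome, g, cdna)
        else:
            res = call_edits(splice_cds(genome, g), cdna, gene=g)
        sites.extend(res.sites)
        discrepancies.extend(res.discrepancies)
    return EditCallResult(sites, discrepancies)


def _call_edits_premrna(genome, gene: GeneModel, cdna: str) -> EditCallResult:
    """Edit calling against the unspliced transcript of a cis gene."""
    from .core import premrna

    pre = premrna(genome, gene)
    raw = call_edits(pre, cdna, gene=None, gene_id=gene.gene_id)

    # map pre-mRNA positions into spliced-CDS coordinates where possible
    span = gene.genomic_span
    exon_offsets: list[tuple[int, int, int]] = []  # (pre_start, pre_end, cds_start)
    cds_cursor = 1
    for e in gene.exons:
        if gene.strand == "+":
            pre_s = e.start - span.start + 1
        else:
            pre_s = span.end - e.end + 1
        exon_offsets.append((pre_s, pre_s + e.span - 1, cds_cursor))
        cds_cursor += e.span

    from .core import splice_cds

    cds = splice_cds(genome, gene)
    sites = []
    for s in raw.sites:
        cds_pos = None
        for pre_s, pre_e, cds_s in exon_offsets:
            if pre_s <= s.cds_pos <= pre_e:
                cds_pos = cds_s + (s.cds_pos - pre_s)
                break
        if cds_pos is None:  # intronic edit position: no codon context
            sites.append(
                EditingSite(gene.gene_id, s.cds_pos, s.direction,
                            effect="unpartitioned")
            )
            continue
        codon_index = (cds_pos - 1) // 3 + 1
        codon_pos = (cds_pos - 1) % 3 + 1
        codon_start = (codon_index - 1) * 3
        ref_codon = cds[codon_start : codon_start + 3]
        if len(ref_codon) == 3 and gene.category == "protein":
            edited_codon, ref_aa, edited_aa, effect = classify_edit(
                ref_codon, codon_pos, s.direction
            )
        else:
            edited_codon = ref_aa = edited_aa = None
            effect = "unpartitioned"
        sites.append(
            EditingSite(
                gene.gene_id, cds_pos, s.direction,
                cds_to_genomic(gene, cds_pos), codon_index, codon_pos,
                ref_codon, edited_codon, ref_aa, edited_aa, effect,
            )
        )
    return EditCallResult(sites, raw.discrepancies)


# ---------------------------------------------------------------------------
# Frequencies, dedup, partition statistics
# ---------------------------------------------------------------------------


def editing_frequency(n_edits: int, cds_length: int) -> float:
    """Edits per 100 nt of CDS, half-up rounded to 3 decimals."""
    if cds_length <= 0:
        raise ValueError("cds_length must be > 0")
    return round_half_up(100.0 * n_edits / cds_length, 3)


def editing_profile(
    sites: list[EditingSite], cds_lengths: dict[str, int]
) -> list[dict]:
    """Per-gene edit counts and edits/100 nt, sorted by frequency."""
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.gene_id] = counts.get(s.gene_id, 0) + 1
    rows = []
    for gene_id, length in cds_lengths.items():
        n = counts.get(gene_id, 0)
        rows.append(
            {
                "gene_id": gene_id,
                "n_edits": n,
                "cds_length": length,
                "freq_per_100nt": editing_frequency(n, length),
            }
        )
    rows.sort(key=lambda r: (-r["freq_per_100nt"], r["gene_id"]))
    return rows


def _copy_base(name: str) -> str | None:
    """Base name of an identical-copy gene ("rps19-1" -> "rps19")."""
    for suffix in ("-1", "-2", "-3", "-4"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return None


def dedupe_copies(
    sites: list[EditingSite],
    ann,
    cds_map: dict[str, str] | None = None,
) -> list[EditingSite]:
    """Report edits of identical duplicated gene copies once.

    Copies are recognized by the "-1/-2" naming convention; when `cds_map`
    is provided the spliced CDS sequences must also be identical (divergent
    "-a/-b" copies are always kept separately).  The lexicographically first
    copy is the representative.
    """
    groups: dict[str, list[str]] = {}
    for g in ann.genes:
        base = _copy_base(g.name)
        if base is not None:
            groups.setdefault(base, []).append(g.gene_id)

    drop: set[str] = set()
    for base, members in groups.items():
        if len(members) < 2:
            continue
        members = sorted(members)
        rep = members[0]
        if cds_map is not None:
            identical = all(
                cds_map.get(m) == cds_map.get(rep) for m in members[1:]
            )
            if not identical:
                continue
        edit_sets = {
            m: {(s.cds_pos, s.direction) for s in sites if s.gene_id == m}
            for m in members
        }
        if all(edit_sets[m] == edit_sets[rep] for m in members[1:]):
            drop.update(members[1:])
    return [s for s in sites if s.gene_id not in drop]


def partition_counts(sites: list[EditingSite]) -> dict[str, int]:
    out = {"nonsynonymous": 0, "synonymous": 0, "unpartitioned": 0}
    for s in sites:
        out[s.effect] += 1
    return out


def nonsynonymous_share(
    n_nonsyn: int, n_syn: int, n_unpartitioned: int = 0,
    of_partitioned_only: bool = False,
) -> float:
    """Percent of edits that change the amino acid, to the nearest percent.

    By default the denominator is all edits including unpartitioned
    pseudogene sites; with `of_partitioned_only` it is nonsyn+syn only.
    """
    denom = n_nonsyn + n_syn + (0 if of_partitioned_only else n_unpartitioned)
    if denom == 0:
        raise ValueError("no edits")
    return round_half_up(100.0 * n_nonsyn / denom, 0)


# ---------------------------------------------------------------------------
# Cross-species comparison
# ---------------------------------------------------------------------------


def compare_editing_sets(
    sites_a: list[EditingSite],
    cds_a: dict[str, str],
    sites_b: list[EditingSite],
    cds_b: dict[str, str],
    species_a: str = "a",
    species_b: str = "b",
) -> SharedEditSummary:
    """Pairwise shared/unique edit counts over orthologous genes.

    Ortholog pairs are matched by gene name; per pair the CDSs are globally
    aligned and an edit is shared iff both species have an edit of the same
    direction in the same aligned column.  An edit aligned to a gap is
    unique by definition.  Genes present in only one species are excluded
    (logged); their edits do not enter the totals.
    """
    genes_a = set(cds_a)
    genes_b = set(cds_b)
    shared_genes = genes_a & genes_b
    for g in sorted((genes_a | genes_b) - shared_genes):
        logger.info("gene %s present in only one species: excluded", g)

    by_gene_a: dict[str, list[EditingSite]] = {}
    for s in sites_a:
        by_gene_a.setdefault(s.gene_id, []).append(s)
    by_gene_b: dict[str, list[EditingSite]] = {}
    for s in sites_b:
        by_gene_b.setdefault(s.gene_id, []).append(s)

    n_shared = n_unique_a = n_unique_b = 0
    for gene in sorted(shared_genes):
        ga, gb, _ = align_dna_cdna(cds_a[gene], cds_b[gene])
        col_of_a: dict[int, int] = {}
        col_of_b: dict[int, int] = {}
        pa = pb = 0
        for col, (x, y) in enumerate(zip(ga, gb)):
            if x != "-":
                pa += 1
                col_of_a[pa] = col if y != "-" else -1
            if y != "-":
                pb += 1
                col_of_b[pb] = col if x != "-" else -1

        edits_a = [
            (col_of_a.get(s.cds_pos, -1), s.direction)
            for s in by_gene_a.get(gene, [])
        ]
        edits_b = [
            (col_of_b.get(s.cds_pos, -1), s.direction)
            for s in by_gene_b.get(gene, [])
        ]
        set_a = {c for c in edits_a if c[0] >= 0}
        set_b = {c for c in edits_b if c[0] >= 0}
        both = set_a & set_b
        n_shared += len(both)
        n_unique_a += sum(1 for c in edits_a if c not in both)
        n_unique_b += sum(1 for c in edits_b if c not in both)

    return SharedEditSummary(species_a, species_b, n_shared, n_unique_a, n_unique_b)


def sites_to_rows(sites: list[EditingSite]) -> list[dict]:
    """EditingSite records as flat dicts for TSV output."""
    return [
        {
            "gene_id": s.gene_id,
            "cds_pos": s.cds_pos,
            "genomic_pos": s.genomic_pos,
            "direction": s.direction,
            "codon_index": s.codon_index,
            "codon_pos": s.codon_pos,
            "ref_codon": s.ref_codon,
            "edited_codon": s.edited_codon,
            "ref_aa": s.ref_aa,
            "edited_aa": s.edited_aa,
            "effect": s.effect,
        }
        for s in sites
    ]
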