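"""Domain types, FASTA/GFF3 I/O, coordinate arithmetic and genome summaries.

Coordinate convention (used everywhere in this package): positions are
1-based and intervals are inclusive on both ends, the convention of GenBank
feature tables.  Origin-crossing features on circular genomes are represented
as ordered multi-segment exon lists; an interval never has ``end < start``.

Rounding of reported statistics is fixed half-up (never banker's):
percent-of-genome to 1 decimal, GC% to 2 decimals, editing frequency and
assembly accuracy to 3 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import reverse_complement

logger = logging.getLogger("mitokit")

VALID_BASES = frozenset("ACGTN")
GENE_CATEGORIES = frozenset({"protein", "tRNA", "rRNA", "pseudogene", "orf"})
GENE_ORIGINS = frozenset({"native", "plastid_derived"})

FASTA_WRAP = 60


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval with a strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class Genome:
    """A single circular- or linear-mapping nucleotide molecule."""

    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"genome {self.id!r}: invalid characters {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"genome {self.id!r}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, iv: Interval) -> str:
        """Sequence of an interval, reverse-complemented for the - strand."""
        if iv.end > len(self.sequence):
            raise ValueError(f"interval {iv.start}..{iv.end} beyond genome end")
        s = self.sequence[iv.start - 1 : iv.end]
        return reverse_complement(s) if iv.strand == "-" else s


@dataclass
class GeneModel:
    """A gene as an ordered list of exon segments in coding order.

    Display-name suffix conventions: "-a"/"-b" mark divergent gene copies,
    "-1"/"-2" mark identical copies, "-cp" marks plastid-derived genes.
    """

    gene_id: str
    name: str
    category: str
    exons: list[Interval]
    origin: str = "native"
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"gene {self.gene_id}: unknown category {self.category!r}")
        if self.origin not in GENE_ORIGINS:
            raise ValueError(f"gene {self.gene_id}: unknown origin {self.origin!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        ivs = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if not self.trans_spliced and len({e.strand for e in self.exons}) > 1:
            raise ValueError(f"gene {self.gene_id}: cis gene with mixed strands")

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def cds_length(self) -> int:
        return sum(e.span for e in self.exons)

    @property
    def genomic_span(self) -> Interval:
        return Interval(
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )


@dataclass
class AnnotationSet:
    genome_id: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_id(s): {dup}")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def validate_against(self, genome: Genome) -> None:
        for g in self.genes:
            for e in g.exons:
                if e.end > len(genome):
                    raise ValueError(
                        f"gene {g.gene_id}: exon {e.start}..{e.end} outside genome"
                    )


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults are the published screening settings.

    ``ssr_min_units`` maps SSR unit length 1..6 to the minimum repeat count
    (MISA-style minima 10, 5, 4, 3, 3, 3).  Long repeats are >500 bp at
    >=99% identity.  Plastid-derived fragments are called at >=70% identity
    and e-value <=1e-5; their homologs in other mitochondrial genomes at
    >=80% identity over >=90% of the fragment.
    """

    ssr_min_units: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
    )
    long_repeat_min_len: int = 500
    long_repeat_min_identity: float = 0.99
    mtpt_min_identity: float = 0.70
    mtpt_max_evalue: float = 1e-5
    homolog_min_identity: float = 0.80
    homolog_min_coverage: float = 0.90
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for u in range(1, 7):
            if self.ssr_min_units.get(u, 0) < 1:
                raise ValueError(f"ssr_min_units[{u}] must be >= 1")
        for name in (
            "long_repeat_min_identity",
            "mtpt_min_identity",
            "homolog_min_identity",
            "homolog_min_coverage",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} not in (0, 1]")
        if self.long_repeat_min_len < 1:
            raise ValueError("long_repeat_min_len must be >= 1")
        if self.mtpt_max_evalue < 0:
            raise ValueError("mtpt_max_evalue must be >= 0")

    def as_dict(self) -> dict:
        return {
            "ssr_min_units": {str(k): v for k, v in self.ssr_min_units.items()},
            "long_repeat_min_len": self.long_repeat_min_len,
            "long_repeat_min_identity": self.long_repeat_min_identity,
            "mtpt_min_identity": self.mtpt_min_identity,
            "mtpt_max_evalue": self.mtpt_max_evalue,
            "homolog_min_identity": self.homolog_min_identity,
            "homolog_min_coverage": self.homolog_min_coverage,
            "rng_seed": self.rng_seed,
        }


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a multi-record FASTA file into Genome objects.

    Topology is taken from a ``topology=circular`` token in the header and
    defaults to linear.  Sequences are uppercased on read.
    """
    path = Path(path)
    genomes: list[Genome] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}:{header_line}: record {header!r} has no sequence")
        tokens = header.split()
        rec_id = tokens[0]
        topology = "linear"
        for tok in tokens[1:]:
            if tok.startswith("topology="):
                topology = tok.split("=", 1)[1]
        genomes.append(Genome(rec_id, seq, topology))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.upper())
    flush()
    if not genomes:
        raise ValueError(f"{path}: empty FASTA file")
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path) -> None:
    """Write genomes as 60-column-wrapped FASTA with a topology token."""
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id} topology={g.topology}\n")
            for i in range(0, len(g.sequence), FASTA_WRAP):
                fh.write(g.sequence[i : i + FASTA_WRAP] + "\n")


def write_sequences(seqs: dict[str, str], path: str | Path) -> None:
    """Write a plain id -> sequence mapping (e.g. per-gene cDNA) as FASTA."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read FASTA into a plain id -> sequence mapping (first token as key)."""
    out: dict[str, str] = {}
    for g in read_fasta(path):
        out[g.id] = g.sequence
    return out


# ---------------------------------------------------------------------------
# GFF3 dialect I/O
# ---------------------------------------------------------------------------
#
# gene rows carry ID, Name, category, origin, trans_spliced attributes;
# exon rows carry Parent and an optional integer coding_order.  Exon lists
# are ordered by coding_order when present, otherwise by genomic position
# (ascending on +, descending on -).


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed attribute {part!r}")
        k, v = part.split("=", 1)
        attrs[k] = v
    return attrs


def read_annotation(path: str | Path, genome: Genome) -> AnnotationSet:
    path = Path(path)
    gene_rows: dict[str, dict] = {}
    exon_rows: list[tuple[int, dict, Interval]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            _, _, ftype, start, end, _, strand, _, attr_text = cols
            attrs = _parse_attributes(attr_text)
            iv = Interval(int(start), int(end), strand)
            if iv.end > len(genome):
                raise ValueError(
                    f"{path}:{lineno}: feature {iv.start}..{iv.end} outside genome "
                    f"(length {len(genome)})"
                )
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene row without ID")
                if gid in gene_rows:
                    raise ValueError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
                gene_rows[gid] = attrs
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: exon row without Parent")
                exon_rows.append((lineno, attrs, iv))

    by_gene: dict[str, list[tuple[dict, Interval]]] = {g: [] for g in gene_rows}
    for lineno, attrs, iv in exon_rows:
        parent = attrs["Parent"]
        if parent not in by_gene:
            raise ValueError(f"{path}:{lineno}: exon Parent {parent!r} not a gene")
        by_gene[parent].append((attrs, iv))

    genes = []
    for gid, attrs in gene_rows.items():
        pairs = by_gene[gid]
        if not pairs:
            raise ValueError(f"gene {gid!r} has no exons")
        if all("coding_order" in a for a, _ in pairs):
            pairs.sort(key=lambda p: int(p[0]["coding_order"]))
        else:
            strand = pairs[0][1].strand
            pairs.sort(key=lambda p: p[1].start, reverse=(strand == "-"))
        genes.append(
            GeneModel(
                gene_id=gid,
                name=attrs.get("Name", gid),
                category=attrs.get("category", "protein"),
                origin=attrs.get("origin", "native"),
                trans_spliced=attrs.get("trans_spliced", "false").lower() == "true",
                exons=[iv for _, iv in pairs],
            )
        )
    ann = AnnotationSet(genome_id=genome.id, genes=genes)
    ann.validate_against(genome)
    return ann


def write_annotation(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            span = g.genomic_span
            attrs = (
                f"ID={g.gene_id};Name={g.name};category={g.category};"
                f"origin={g.origin};trans_spliced={str(g.trans_spliced).lower()}"
            )
            fh.write(
                f"{ann.genome_id}\tmitokit\tgene\t{span.start}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for order, e in enumerate(g.exons, start=1):
                fh.write(
                    f"{ann.genome_id}\tmitokit\texon\t{e.start}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tParent={g.gene_id};coding_order={order}\n"
                )


# ---------------------------------------------------------------------------
# Splicing and masking
# ---------------------------------------------------------------------------


def splice_cds(genome: Genome, gene: GeneModel) -> str:
    """Concatenate exon sequences in coding order (reverse-complementing
    - strand exons); handles cis multi-exon and trans-spliced genes."""
    return "".join(genome.fetch(e) for e in gene.exons)


def premrna(genome: Genome, gene: GeneModel) -> str:
    """Unspliced transcript (genomic span incl. introns) of a cis gene."""
    if gene.trans_spliced:
        raise ValueError(f"gene {gene.gene_id}: pre-mRNA undefined for trans-spliced gene")
    return genome.fetch(gene.genomic_span)


def cds_to_genomic(gene: GeneModel, cds_pos: int) -> int:
    """Map a 1-based position in the spliced CDS to its genomic coordinate."""
    if not (1 <= cds_pos <= gene.cds_length):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {gene.cds_length}")
    offset = cds_pos - 1
    for e in gene.exons:
        if offset < e.span:
            return e.start + offset if e.strand == "+" else e.end - offset
        offset -= e.span
    raise AssertionError("unreachable")


def mask_features(genome: Genome, ann: AnnotationSet, categories: set[str]) -> str:
    """Replace every position covered by an exon of a gene in the selected
    categories with N; sequence length is preserved."""
    unknown = set(categories) - GENE_CATEGORIES
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    seq = bytearray(genome.sequence, "ascii")
    for g in ann.genes:
        if g.category not in categories:
            continue
        for e in g.exons:
            seq[e.start - 1 : e.end] = b"N" * e.span
    return seq.decode("ascii")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryRow:
    category: str
    feature: str
    count: int
    total_bp: int
    percent_of_genome: float


@dataclass
class GenomeSummary:
    genome_id: str
    genome_length: int
    gc_percent: float
    rows: list[SummaryRow]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("Category\tFeature\tNumber\tbp\tpercent\n")
            fh.write(f"genome\tlength\t1\t{self.genome_length}\t100.0\n")
            fh.write(f"genome\tG + C\t.\t.\t{self.gc_percent:.2f}\n")
            for r in self.rows:
                fh.write(
                    f"{r.category}\t{r.feature}\t{r.count}\t{r.total_bp}\t"
                    f"{r.percent_of_genome:.1f}\n"
                )


def gc_percent(sequence: str) -> float:
    """GC% to two decimals; N positions count toward the length denominator."""
    gc = sequence.count("G") + sequence.count("C")
    return round_half_up(100.0 * gc / len(sequence), 2)


def genome_percent(total_bp: int, genome_len: int, ndigits: int = 1) -> float:
    """Percent of the genome a feature class occupies, half-up rounded."""
    if genome_len <= 0:
        raise ValueError("genome length must be > 0")
    return round_half_up(100.0 * total_bp / genome_len, ndigits)


def interval_union_size(intervals: Iterable[Interval]) -> int:
    """Total bp covered by the union of intervals (strand-ignorant)."""
    ivs = sorted((i.start, i.end) for i in intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def cis_intron_intervals(gene: GeneModel) -> list[Interval]:
    """Intron spans between consecutive exons of a cis multi-exon gene,
    derived from annotation geometry."""
    if gene.trans_spliced or len(gene.exons) < 2:
        return []
    exons = sorted(gene.exons, key=lambda e: e.start)
    out = []
    for a, b in zip(exons, exons[1:]):
        if b.start > a.end + 1:
            out.append(Interval(a.end + 1, b.start - 1, gene.strand))
    return out


def summarize_genome(
    genome: Genome,
    ann: AnnotationSet,
    repeats: Sequence = (),
    ssrs: Sequence = (),
    long_repeat_min_len: int = 500,
) -> GenomeSummary:
    """Feature-class statistics table: per-category gene counts/bp/percent,
    cis-intron totals from annotation geometry, repeat and SSR coverage."""
    L = len(genome)

    def gene_row(category: str, feature: str, pred) -> SummaryRow:
        sel = [g for g in ann.genes if pred(g)]
        bp = sum(g.cds_length for g in sel)
        return SummaryRow(category, feature, len(sel), bp, genome_percent(bp, L))

    rows = [
        gene_row("Genes", "protein coding", lambda g: g.category == "protein"),
        gene_row("Genes", "pseudogenes", lambda g: g.category == "pseudogene"),
        gene_row("Genes", "rRNA", lambda g: g.category == "rRNA"),
        gene_row(
            "Genes",
            "mt-derived tRNA",
            lambda g: g.category == "tRNA" and g.origin == "native",
        ),
        gene_row(
            "Genes",
            "cp-derived tRNA",
            lambda g: g.category == "tRNA" and g.origin == "plastid_derived",
        ),
        gene_row("Genes", "ORF", lambda g: g.category == "orf"),
    ]

    cis_introns = [iv for g in ann.genes for iv in cis_intron_intervals(g)]
    n_trans = sum(1 for g in ann.genes if g.trans_spliced)
    cis_bp = sum(iv.span for iv in cis_introns)
    rows.append(
        SummaryRow("Introns", "cis-spliced", len(cis_introns), cis_bp,
                   genome_percent(cis_bp, L))
    )
    rows.append(SummaryRow("Introns", "trans-spliced", n_trans, 0, 0.0))

    long_pairs = [r for r in repeats if r.length > long_repeat_min_len]
    short_pairs = [r for r in repeats if 20 < r.length <= long_repeat_min_len]
    for feature, pairs in (
        (f"Repeats(>{long_repeat_min_len})", long_pairs),
        (f"Short Repeats(20<, <{long_repeat_min_len})", short_pairs),
    ):
        ivs = [iv for r in pairs for iv in (r.interval_a, r.interval_b)]
        bp = interval_union_size(ivs)
        rows.append(
            SummaryRow("Repeats", feature, len(pairs), bp, genome_percent(bp, L))
        )

    ssr_bp = interval_union_size([s.interval for s in ssrs])
    rows.append(
        SummaryRow("Repeats", "SSRs", len(list(ssrs)), ssr_bp, genome_percent(ssr_bp, L))
    )

    return GenomeSummary(genome.id, L, gc_percent(genome.sequence), rows)


# ---------------------------------------------------------------------------
# Assembly bookkeeping arithmetic
# ---------------------------------------------------------------------------


def coverage_depth(total_read_bp: int, genome_len: int) -> int:
    """Sequencing depth = total read bp over genome length, nearest integer."""
    if genome_len <= 0:
        raise ValueError("genome length must be > 0")
    if total_read_bp <= 0:
        raise ValueError("total read bp must be > 0")
    return int(round_half_up(total_read_bp / genome_len, 0))


def mean_read_length(total_read_bp: int, n_reads: int) -> int:
    """Mean read length to the nearest integer bp."""
    if n_reads <= 0:
        raise ValueError("read count must be > 0")
    return int(round_half_up(total_read_bp / n_reads, 0))


def validation_accuracy(n_mismatches: int, validated_bp: int) -> float:
    """Percent of Sanger-validated bases matching the assembly, 3 decimals."""
    if validated_bp <= 0:
        raise ValueError("validated bp must be > 0")
    if not (0 <= n_mismatches <= validated_bp):
        raise ValueError("mismatches outside [0, validated_bp]")
    return round_half_up(100.0 * (validated_bp - n_mismatches) / validated_bp, 3)
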