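"""Collinear gene-cluster detection between two annotated gene orders.

A simplified synteny-block finder over gene *names* rather than protein
similarity: organelle gene nomenclature is standardized, so two genomes'
shared genes are matched by name (ignoring "-1/-2" identical-copy suffixes
and the "-cp"/"(cp)" plastid-origin tag; divergent "-a/-b" copies match by
base name).  After projecting both orders onto the shared name set, a
collinear cluster is a maximal run of genes adjacent in both orders, in the
same or exactly reversed direction.  Circular gene orders are scanned
across the origin.  Strand agreement is recorded but not required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import AnnotationSet


@dataclass
class GeneOrder:
    genome_id: str
    entries: list[tuple[str, str]]  # (gene name, strand)
    circular: bool = False

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CollinearCluster:
    genes: tuple[str, ...]
    orientation: str  # same | inverted

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def notation(self) -> str:
        return "-".join(self.genes)


_COPY_SUFFIX = re.compile(r"-[0-9]+$")
_AB_SUFFIX = re.compile(r"-[ab]$")


def canonical_name(name: str) -> str:
    """Matching key for a gene name: strips identical-copy numbers,
    divergent-copy letters, and the plastid-origin tag."""
    name = name.strip()
    name = name.replace("(cp)", "").replace("-cp", "")
    name = _COPY_SUFFIX.sub("", name)
    name = _AB_SUFFIX.sub("", name)
    return name


def gene_order_from_annotation(ann: AnnotationSet, circular: bool = False) -> GeneOrder:
    """Gene order by start position of the first exon; trans-spliced genes
    contribute one entry per exon group, suffixed with the exon numbers
    (e.g. "nad1_exon2,3")."""
    entries: list[tuple[int, str, str]] = []
    for g in ann.genes:
        if g.trans_spliced:
            for idx, e in enumerate(g.exons, start=1):
                entries.append((e.start, f"{g.name}_exon{idx}", e.strand))
        else:
            span = g.genomic_span
            entries.append((span.start, g.name, g.strand))
    entries.sort()
    return GeneOrder(ann.genome_id, [(n, s) for _, n, s in entries], circular)


def project_shared(order_a: GeneOrder, order_b: GeneOrder) -> tuple[GeneOrder, GeneOrder]:
    """Restrict both orders to gene names present in both (canonical-name
    matching); duplicated names keep their first occurrence only."""

    def first_occurrences(order: GeneOrder) -> dict[str, int]:
        seen: dict[str, int] = {}
        for i, (name, _) in enumerate(order.entries):
            seen.setdefault(canonical_name(name), i)
        return seen

    occ_a = first_occurrences(order_a)
    occ_b = first_occurrences(order_b)
    shared = set(occ_a) & set(occ_b)

    def project(order: GeneOrder, occ: dict[str, int]) -> GeneOrder:
        keep = {occ[n] for n in shared}
        entries = [
            (canonical_name(name), strand)
            for i, (name, strand) in enumerate(order.entries)
            if i in keep
        ]
        return GeneOrder(order.genome_id, entries, order.circular)

    return project(order_a, occ_a), project(order_b, occ_b)


def find_clusters(
    order_a: GeneOrder, order_b: GeneOrder, max_gap: int = 0
) -> list[CollinearCluster]:
    """Maximal collinear runs of the two projected orders.

    Consecutive shared genes in `a` must be within `max_gap` intervening
    genes in `b`, consistently forward (same) or backward (inverted).
    Circular orders wrap across the origin; each cluster is reported once.
    """
    a, b = project_shared(order_a, order_b)
    names_a = a.names
    pos_b = {name: i for i, (name, _) in enumerate(b.entries)}
    n_a, n_b = len(names_a), len(b)
    if n_a < 2:
        return []

    def step_ok(prev: str, cur: str, direction: int) -> bool:
        delta = pos_b[cur] - pos_b[prev]
        if b.circular:
            delta = (delta + n_b) % n_b
            if direction < 0:
                delta = delta - n_b if delta > 0 else delta
        return 1 <= direction * delta <= max_gap + 1

    # scan a (doubled if circular) for maximal runs in either direction
    scan = names_a + (names_a if a.circular else [])
    clusters: list[CollinearCluster] = []
    seen: set[frozenset] = set()
    i = 0
    while i < len(scan) - 1:
        best = None
        for direction in (+1, -1):
            j = i
            while (
                j + 1 < len(scan)
                and j + 1 - i < n_a
                and step_ok(scan[j], scan[j + 1], direction)
            ):
                j += 1
            if j > i and (best is None or j > best[0]):
                best = (j, direction)
        if best is None:
            i += 1
            continue
        j, direction = best
        genes = tuple(scan[i : j + 1])
        key = frozenset(genes)
        if key not in seen:
            seen.add(key)
            clusters.append(
                CollinearCluster(genes, "same" if direction > 0 else "inverted")
            )
        i = j + 1

    # drop clusters wholly contained in another (circular doubling artifacts)
    out = []
    for c in clusters:
        if any(
            c is not d and set(c.genes) < set(d.genes) for d in clusters
        ):
            continue
        out.append(c)
    return out


def clusters_to_rows(clusters: list[CollinearCluster]) -> list[dict]:
    return [
        {"cluster": c.notation, "size": c.size, "orientation": c.orientation}
        for c in clusters
    ]
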