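"""Relative synonymous codon usage (RSCU) and codon-position composition.

RSCU of a codon is its observed count divided by the mean count of its
synonymous family: rscu = count / (family_total / family_size).  A value of
1 means no bias; the values of a family always sum to the family size when
the family is used at all.  Families follow the standard genetic code (the
code plant mitochondria translate with); the three stop codons form their
own family.  Families with zero total count have undefined RSCU and are
reported as empty rather than 0.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio.Data.CodonTable import standard_dna_table

from .core import round_half_up

logger = logging.getLogger("mitokit")

AMINO_ACID: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    AMINO_ACID[_stop] = "*"

#: amino acid (or '*') -> tuple of synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(AMINO_ACID.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)


@dataclass
class RSCUTable:
    counts: dict[str, int]
    rscu: dict[str, float | None]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tamino_acid\tcount\trscu\n")
            for codon in sorted(AMINO_ACID):
                r = self.rscu[codon]
                fh.write(
                    f"{codon}\t{AMINO_ACID[codon]}\t{self.counts[codon]}\t"
                    f"{'' if r is None else f'{r:.4f}'}\n"
                )


def _iter_codons(cds_list: list[str], label: str = "CDS"):
    """Yield codons from each CDS; non-ACGT codons are skipped (logged)."""
    for i, cds in enumerate(cds_list):
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(
                f"{label} #{i + 1} length {len(cds)} is not divisible by 3"
            )
        for j in range(0, len(cds), 3):
            codon = cds[j : j + 3]
            if set(codon) <= set("ACGT"):
                yield codon
            else:
                logger.info("skipping ambiguous codon %r in %s #%d", codon, label, i + 1)


def compute_rscu(cds_list: list[str]) -> RSCUTable:
    """RSCU over the pooled codon counts of a set of coding sequences."""
    counts = Counter(_iter_codons(cds_list))
    full_counts = {codon: counts.get(codon, 0) for codon in AMINO_ACID}
    rscu: dict[str, float | None] = {}
    for family in FAMILIES.values():
        total = sum(full_counts[c] for c in family)
        if total == 0:
            for c in family:
                rscu[c] = None
        else:
            mean = total / len(family)
            for c in family:
                rscu[c] = full_counts[c] / mean
    return RSCUTable(full_counts, rscu)


def third_position_at_fraction(
    cds_list: list[str], include_stops: bool = True
) -> float:
    """Percent of codons with A or T at the third position, two decimals.

    Stop codons count toward the denominator by default (flag to exclude).
    """
    n_at = n_total = 0
    for codon in _iter_codons(cds_list):
        if not include_stops and AMINO_ACID[codon] == "*":
            continue
        n_total += 1
        if codon[2] in "AT":
            n_at += 1
    if n_total == 0:
        raise ValueError("no codons counted")
    return round_half_up(100.0 * n_at / n_total, 2)
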