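"""Long direct/inverted repeat detection and perfect-SSR (microsatellite)
screening.

Long repeats are found with an exact-seed approach (k-mer anchors, default
k=31) followed by ungapped extension with mismatch tolerance down to the
identity floor; this is complete in practice for the >=99%-identity,
>500-bp repeats the screen targets (a mismatch every ~100 bp still leaves
abundant 31-mer anchors).  ">500 bp" means alignment length strictly
greater than the floor.

SSRs are maximal perfect tandem repeats of a primitive 1-6 nt unit meeting
per-unit-length minimum counts (MISA-style, defaults 10/5/4/3/3/3).  A run
reportable at several unit lengths surfaces only at its smallest unit
(larger units over the same run are non-primitive and filtered).  Runs of N
are never SSRs.

Circular genomes are scanned with a min(len, 600)-bp overhang appended so
origin-spanning features are caught; duplicate calls from the overhang are
removed by modular coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

from .core import Genome, Interval

CIRCULAR_OVERHANG = 600
SEED_K = 31
CHAIN_GAP = 200
XDROP = 12
MISMATCH_PENALTY = 3
CLEAN_FLANK = 8


@dataclass(frozen=True)
class RepeatPair:
    kind: str  # direct | inverted
    interval_a: Interval
    interval_b: Interval
    length: int
    identity: float


@dataclass(frozen=True)
class SSRLocus:
    motif: str  # actual repeating unit at the locus
    n_units: int
    interval: Interval

    @property
    def canonical_motif(self) -> str:
        """Lexicographically least rotation of the unit."""
        return min(self.motif[i:] + self.motif[:i] for i in range(len(self.motif)))

    @property
    def length(self) -> int:
        return len(self.motif) * self.n_units


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def _is_primitive(unit: str) -> bool:
    u = len(unit)
    return not any(
        unit == unit[:p] * (u // p) for p in range(1, u) if u % p == 0
    )


def _scan_ssrs(seq: str, ssr_min_units: dict[int, int]) -> list[tuple[int, str, int]]:
    """All left-maximal perfect runs in a linear string.

    Returns (start0, unit, n_units) with 0-based starts.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    L = len(seq)
    out = []
    for u in sorted(ssr_min_units):
        th = ssr_min_units[u]
        if L < u * th:
            continue
        m = arr[:-u] == arr[u:]  # m[j]: position j starts a period-u match
        # maximal runs of True in m
        padded = np.concatenate(([False], m, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1  # inclusive
        for a, b in zip(starts, ends):
            region_len = (b - a + 1) + u
            n_full = region_len // u
            if n_full < th:
                continue
            unit = seq[a : a + u]
            if "N" in unit or not _is_primitive(unit):
                continue
            out.append((int(a), unit, int(n_full)))
    return out


def find_ssrs(genome: Genome, ssr_min_units: dict[int, int]) -> list[SSRLocus]:
    """Maximal perfect SSR loci meeting the per-unit-length minima."""
    L = len(genome)
    if genome.topology == "circular":
        overhang = min(L, CIRCULAR_OVERHANG)
        seq = genome.sequence + genome.sequence[:overhang]
    else:
        overhang = 0
        seq = genome.sequence

    runs = _scan_ssrs(seq, ssr_min_units)
    loci: list[SSRLocus] = []
    wrapped_spans: list[tuple[int, int, int]] = []  # (start0, end0, unit len)
    for a, unit, n in runs:
        if a >= L:
            continue  # lives entirely in the overhang copy
        end0 = a + len(unit) * n - 1
        if end0 >= L:
            wrapped_spans.append((a, end0, len(unit)))
        loci.append(SSRLocus(unit, n, Interval(a + 1, end0 + 1)))

    if wrapped_spans:
        # a wrapped run re-surfaces at the sequence start as a shorter echo;
        # drop runs whose +L shift lies inside a wrapped run of same period
        def shadowed(locus: SSRLocus) -> bool:
            s0 = locus.interval.start - 1 + L
            e0 = locus.interval.end - 1 + L
            return any(
                u == len(locus.motif) and ws <= s0 and e0 <= we
                for ws, we, u in wrapped_spans
            )

        loci = [
            lo for lo in loci
            if not (lo.interval.start - 1 < overhang and shadowed(lo))
        ]

    loci.sort(key=lambda s: (s.interval.start, len(s.motif)))
    return loci


# ---------------------------------------------------------------------------
# Long repeats
# ---------------------------------------------------------------------------


def _seed_diagonals(seq_a: str, seq_b: str, k: int, self_compare: bool):
    """Map diagonal (start_b - start_a) -> sorted seed starts in a."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        kmer = seq_a[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    diags: dict[int, list[int]] = {}
    if self_compare:
        for positions in index.values():
            if len(positions) < 2:
                continue
            for x in range(len(positions)):
                for y in range(x + 1, len(positions)):
                    d = positions[y] - positions[x]
                    diags.setdefault(d, []).append(positions[x])
    else:
        for j in range(len(seq_b) - k + 1):
            kmer = seq_b[j : j + k]
            if "N" in kmer:
                continue
            for i in index.get(kmer, ()):
                diags.setdefault(j - i, []).append(i)
    for d in diags:
        diags[d] = sorted(set(diags[d]))
    return diags


def _chain_seeds(starts: list[int], k: int, max_gap: int) -> list[list[int]]:
    """Group seed starts on one diagonal into chains (seed-start lists)."""
    chains: list[list[int]] = []
    cur: list[int] = []
    for s in starts:
        if not cur or s <= cur[-1] + k - 1 + max_gap:
            cur.append(s)
        else:
            chains.append(cur)
            cur = [s]
    if cur:
        chains.append(cur)
    return chains


def _extend_ungapped(
    a: np.ndarray, b: np.ndarray, a0: int, a1: int, b0: int,
    min_identity: float,
) -> tuple[int, int, int] | None:
    """X-drop ungapped extension of an anchored match region.

    a[a0..a1] is anchored against b[b0..b0+(a1-a0)].  Returns
    (a_start, a_end, n_matches) after extension and end-trimming, or None.
    """
    off = b0 - a0
    lo, hi = a0, a1

    # left extension
    best = score = 0
    best_i = lo
    i = lo - 1
    while i >= 0 and i + off >= 0:
        score += 1 if a[i] == b[i + off] else -MISMATCH_PENALTY
        if score > best:
            best, best_i = score, i
        if best - score > XDROP:
            break
        i -= 1
    lo = best_i

    # right extension
    best = score = 0
    best_i = hi
    i = hi + 1
    while i < len(a) and i + off < len(b):
        score += 1 if a[i] == b[i + off] else -MISMATCH_PENALTY
        if score > best:
            best, best_i = score, i
        if best - score > XDROP:
            break
        i += 1
    hi = best_i

    # trim ragged ends: both flanks must end in CLEAN_FLANK clean matches
    match = a[lo : hi + 1] == b[lo + off : hi + off + 1]
    s, e = 0, len(match) - 1
    while e - s + 1 >= CLEAN_FLANK:
        if not match[s : s + CLEAN_FLANK].all():
            s += 1
        elif not match[e - CLEAN_FLANK + 1 : e + 1].all():
            e -= 1
        else:
            break
    if e - s + 1 < CLEAN_FLANK:
        return None
    lo2, hi2 = lo + s, lo + e
    n_match = int(match[s : e + 1].sum())
    if n_match / (hi2 - lo2 + 1) < min_identity:
        return None
    return lo2, hi2, n_match


def _collapse_candidates(cands: list[tuple]) -> list[tuple]:
    """Drop candidates whose both loci are contained in a longer one."""
    cands = sorted(cands, key=lambda c: -(c[1] - c[0]))
    kept: list[tuple] = []
    for c in cands:
        a0, a1, b0, b1 = c[:4]
        contained = any(
            ka0 <= a0 and a1 <= ka1 and kb0 <= b0 and b1 <= kb1
            for ka0, ka1, kb0, kb1, *_ in kept
        )
        if not contained:
            kept.append(c)
    return kept


def find_long_repeats(
    genome: Genome,
    min_len: int = 500,
    min_identity: float = 0.99,
    k: int = SEED_K,
) -> list[RepeatPair]:
    """All repeat pairs with alignment length > min_len at >= min_identity,
    in direct and reverse-complement orientation; self-hits excluded and
    symmetric duplicates collapsed."""
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    L = len(genome)
    if genome.topology == "circular":
        seq = genome.sequence + genome.sequence[: min(L, CIRCULAR_OVERHANG)]
    else:
        seq = genome.sequence
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)

    pairs: list[RepeatPair] = []
    seen: set[tuple] = set()

    def emit(kind: str, a0: int, a1: int, b0: int, b1: int, n_match: int,
             b_strand: str) -> None:
        length = a1 - a0 + 1
        if length <= min_len:
            return
        iv_a = Interval(a0 + 1, a1 + 1, "+")
        iv_b = Interval(b0 + 1, b1 + 1, b_strand)
        if (iv_a.start, iv_a.end) == (iv_b.start, iv_b.end):
            return  # self-hit
        a, b = sorted((iv_a, iv_b), key=lambda i: (i.start, i.end))
        # modular dedup for circular overhang copies
        mod_a = ((a.start - 1) % L, (a.end - 1) % L)
        mod_b = ((b.start - 1) % L, (b.end - 1) % L)
        if mod_a == mod_b:
            return  # overhang copy aligned to its own source
        key = (kind, mod_a, mod_b)
        if key in seen:
            return
        seen.add(key)
        if a.start - 1 >= L and b.start - 1 >= L:
            return
        pairs.append(RepeatPair(kind, a, b, length, n_match / length))

    def try_extend(other: np.ndarray, seeds: list[int], d: int, on_hit) -> None:
        """Extend a seed chain; on identity failure split it at its widest
        internal seed gap (two repeat copies on one anti-diagonal can get
        chained across a non-matching spacer) and retry the halves."""
        cs, ce = seeds[0], seeds[-1] + k - 1
        ext = _extend_ungapped(arr, other, cs, ce, cs + d, min_identity)
        if ext is not None:
            on_hit(*ext)
            return
        if len(seeds) < 2:
            return
        gaps = [seeds[i + 1] - seeds[i] for i in range(len(seeds) - 1)]
        widest = max(range(len(gaps)), key=gaps.__getitem__)
        if gaps[widest] <= 2 * k:
            return
        try_extend(other, seeds[: widest + 1], d, on_hit)
        try_extend(other, seeds[widest + 1 :], d, on_hit)

    # direct orientation: genome vs itself
    diags = _seed_diagonals(seq, seq, k, self_compare=True)
    for d, starts in diags.items():
        if d == 0:
            continue
        for seeds in _chain_seeds(starts, k, CHAIN_GAP):
            try_extend(
                arr, seeds, d,
                lambda a0, a1, n, d=d: emit(
                    "direct", a0, a1, a0 + d, a1 + d, n, "+"
                ),
            )

    # inverted orientation: genome vs its reverse complement
    rc = reverse_complement(seq)
    rc_arr = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
    diags = _seed_diagonals(seq, rc, k, self_compare=False)
    L2 = len(seq)

    def emit_inverted(a0: int, a1: int, n_match: int, d: int) -> None:
        rj0, rj1 = a0 + d, a1 + d  # rc coordinates mapped back to genome
        b0, b1 = L2 - 1 - rj1, L2 - 1 - rj0
        emit("inverted", a0, a1, b0, b1, n_match, "-")

    for d, starts in diags.items():
        for seeds in _chain_seeds(starts, k, CHAIN_GAP):
            try_extend(
                rc_arr, seeds, d,
                lambda a0, a1, n, d=d: emit_inverted(a0, a1, n, d),
            )

    # drop nested sub-alignments of the same locus pair
    cand = [
        (p.interval_a.start, p.interval_a.end, p.interval_b.start,
         p.interval_b.end, p)
        for p in pairs
    ]
    kept = {id(c[4]) for c in _collapse_candidates(cand)}
    out = [p for p in pairs if id(p) in kept]
    out.sort(key=lambda p: (-p.length, p.interval_a.start))
    return out


def realized_identity(genome: Genome, pair: RepeatPair) -> float:
    """Recompute a pair's identity directly from the two loci."""
    a = genome_slice(genome, pair.interval_a)
    b = genome_slice(genome, pair.interval_b)
    if pair.kind == "inverted":
        b = reverse_complement(b)
    n = sum(1 for x, y in zip(a, b) if x == y)
    return n / max(len(a), len(b))


def genome_slice(genome: Genome, iv: Interval) -> str:
    """Forward-strand sequence of an interval, wrapping on circular genomes."""
    L = len(genome)
    if iv.end <= L:
        return genome.sequence[iv.start - 1 : iv.end]
    if genome.topology != "circular":
        raise ValueError("interval beyond linear genome end")
    return genome.sequence[iv.start - 1 :] + genome.sequence[: iv.end - L]
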