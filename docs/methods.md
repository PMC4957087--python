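# Methods

mitokit re-implements, as a tested library and CLI, the comparative analyses
typically run on a newly assembled plant mitochondrial genome: RNA-editing
site identification from DNA/cDNA amplicon pairs, relative synonymous codon
usage, long-repeat and microsatellite screening, detection of
chloroplast-derived insertions (MTPT) with cross-species homolog scoring,
collinear gene-cluster detection, and the genome feature-class summary.
Because those analyses are usually validated against a specific sequenced
genome and its sequencing traces — neither of which ships with a software
package — every stage is exercised against synthetic genomes with planted,
machine-checkable ground truth.

## Conventions

Coordinates are 1-based, inclusive on both ends (GenBank feature-table
convention). Origin-crossing features on circular molecules are stored as
ordered multi-segment exon lists, never as intervals with `end < start`.
Reported statistics use fixed half-up rounding: percent-of-genome to 1
decimal, GC% to 2 decimals, editing frequency and assembly accuracy to 3
decimals. GC% counts N positions in the denominator (the naive length-based
computation). Cis-intron totals are derived from annotation geometry (gaps
between consecutive exons of a cis gene), not stored separately.

## RNA editing

Plant mitochondrial mRNAs are edited almost exclusively C-to-U, with rare
U-to-C events. Edit calling aligns each gene's spliced CDS against its cDNA
globally (match +1, mismatch −1, gap open −5, gap extend −2; with
equal-length colinear inputs the alignment is gap-free) and emits a site
only at columns where DNA has C and cDNA has T (C2U) or DNA has T and cDNA
has C (U2C). Every other mismatch is quality-control output (a
"discrepancy"), never an edit — this is what makes calling robust to
sequencing noise: precision over non-C/T mismatches is structurally 1.0.
Chromatogram peaks, which a wet-lab workflow would also consult, are not
available to a sequence-only tool; a minimum-quality hook exists but is a
no-op.

Codon effects use the standard genetic code (plant mitochondria translate
with table 1): synonymous iff the amino acid is unchanged. Edits in a
pseudogene have no reading frame and are classified "unpartitioned"; the
nonsynonymous share is reported both over all edits and over partitioned
edits only, labeled. Initiator codons are translated positionally with no
special-casing. Genes whose amplicon derives from unspliced pre-mRNA can be
flagged; their cDNA is compared against the genomic span, and positions
inside exons are mapped back to spliced-CDS coordinates for codon context
(intronic positions stay unpartitioned). Identical duplicated gene copies
(the "-1/-2" naming convention) with identical edit sets are reported once
under the lexicographically first copy; divergent "-a/-b" copies are always
kept separate.

Cross-species comparison matches orthologs by gene name, aligns the two
CDSs globally, and counts an edit as shared iff both species carry an edit
of the same direction in the same aligned column. An edit aligned against a
gap is unique by definition (the column is not comparable). This
alignment-column rule is a documented design choice; matching by codon
homology would be an alternative.

## Codon usage

RSCU of a codon is its pooled count divided by the mean count of its
synonymous family; families follow the standard code and the three stop
codons form their own family. Families with zero usage report an empty RSCU
rather than 0 (avoids 0/0); single-codon families (Met, Trp) are 1 whenever
used. The third-position A/T fraction counts stop codons in its denominator
by default (flag to exclude); which choice a published figure used is often
unstated, so both are available.

## Repeats and SSRs

Long repeats are found by exact 31-mer anchoring, per-diagonal chaining, and
ungapped X-drop extension (mismatch −3, X-drop 12), in both direct and
reverse-complement orientation. An extension is trimmed until both ends
finish in 8 clean match columns, then kept if alignment length strictly
exceeds the floor (default 500 bp) and identity meets the floor (default
0.99). At ≥99% identity, mismatches are ~1 per 100 bp, so 31-mer anchors are
abundant and the seed-and-extend search is complete in practice; the test
suite bounds misses against planted truth. Two copies of an inverted repeat
lie on one anti-diagonal, so a chain that spans the non-matching spacer is
split at its widest seed gap and the halves retried. Gapped (indel-bearing)
repeats are out of scope, matching the ungapped design.

SSRs are maximal perfect tandem repeats of a primitive 1–6-nt unit meeting
per-unit-length minimum counts (defaults 10, 5, 4, 3, 3, 3 — the MISA-style
minima). Reporting only primitive units automatically realises the
"smallest unit wins" rule: any larger-unit view of the same run has a
periodic (non-primitive) unit. The `motif` field stores the actual unit at
the locus so the substring invariant (`motif * n_units` equals the genomic
substring) holds exactly; `canonical_motif` (least rotation) is provided for
grouping and rotation-invariance checks. Runs of N are never SSRs; compound
or interrupted SSRs are out of scope. Circular genomes are scanned with a
min(length, 600)-bp overhang so origin-spanning runs are caught once,
deduplicated by modular coordinates.

## Chloroplast-derived fragments (MTPT)

Protein, tRNA and rRNA exons of the mitochondrial genome are first masked to
N (N never seeds), eliminating hits to household genes conserved between the
two organelles; whether ORFs should also be masked is genuinely open and the
default is not to. The masked genome is searched against the chloroplast
genome with a seed-and-extend local aligner (11-mer anchors, candidate
windows refined by affine-gap Smith–Waterman: match +1, mismatch −2, open
−5, extend −2). Hit ends are trimmed to 8 clean match columns for the same
boundary-pinning reason as repeats; the reported score is the aligner's
optimum before trimming. E-values use the ungapped Karlin–Altschul form
E = K·m·n·e^(−λS) with fixed documented constants K = 0.41, λ = 1.28
(approximate parameters for this scoring); the identity floor (default 70%)
and e-value ceiling (1e−5) filter hits, but for all realistic inputs the
identity and coverage floors, not the e-value, decide. Bit-exact BLAST
statistics are out of scope and unnecessary at these thresholds.

Hits within 30 bp on both genomes merge into one fragment (fragment-level
rather than HSP-level granularity; the merge distance is a documented
choice). Fragments are numbered by decreasing length. Each is annotated
with the chloroplast genes it contains: intact requires full span
containment plus, for protein genes, an open reading frame in the
transferred copy (codon-multiple length, no internal stop); tRNAs require
containment only (folding checks are out of scope). Homolog presence of a
fragment in another mitochondrial genome requires a best local hit with
identity ≥ 80% over ≥ 90% of the fragment length. A nuclear-insertion scan
is the same masked search with a different subject; no special code path.

Detection floor: a fragment shorter than the 11-bp seed, or so divergent
that no exact 11-mer survives, can be missed; at the emulated conditions
(fragments ≥ 54 bp, divergence ≤ 5%) recovery is complete in the test
suite.

## Gene-order collinearity

Synteny is computed over gene names, not protein similarity: organelle gene
nomenclature is standardized, and published cluster definitions are
name-level. Names are canonicalized (identical-copy "-1/-2" and plastid
"-cp"/"(cp)" tags stripped; divergent "-a/-b" copies match by base name);
duplicated names keep their first occurrence. Both orders are projected
onto the shared name set, then maximal runs are found where consecutive
genes of one order are within `max_gap` (default 0: strict adjacency) in
the other, consistently forward or backward. Circular orders are scanned
across the origin by doubling; clusters are reported once. Strand agreement
is recorded but not required — conserved clusters in real genomes include
mixed-strand arrangements. Trans-spliced genes contribute one gene-order
entry per exon group ("nad1_exon2" style).

## Synthetic data

The generator emulates the real analysis conditions at desk scale, chosen once:

| parameter | default | rationale |
| --- | --- | --- |
| mt genome | 40 kb circular, 12 genes | large enough for every feature class, seconds to analyse (the real genome is 524,797 bp / 63 genes) |
| background GC | 0.48 | echoes the genome's 48.16% GC, so GC-dependent stages see realistic composition |
| cp donor | 12 kb circular, 6 genes, GC 0.38 | chloroplast-like composition |
| planted edits | 30 C→U + 3 U→C | three U-to-C echoes the published count; ≥2 edits land in the pseudogene |
| fragments | 1998, 621, 297, 141, 84, 54 bp, 0% divergence | spans the published 54–1998 bp range including both extremes |
| long repeats | 2 direct + 2 inverted, 520–700 bp | scaled from the published 4+4 |
| SSRs | one per unit length at exactly the minima | threshold edges exercised |

Gene structure covers the cases the pipeline must handle: an identical
duplicated pair ("-1/-2", kept under 500 bp so it is not itself a long
repeat), a cis two-exon gene, a trans-spliced gene with exon groups on both
strands, a pseudogene, native/plastid-derived tRNAs, an rRNA, and plain
protein genes on both strands. Protein CDSs start ATG, end in a stop, and
contain no internal stops.

Planted features never overlap genes or each other, and planting overwrites
intergenic background rather than inserting, so coordinates remain valid.
The bases flanking each planted fragment and repeat copy are forced to
mismatch the would-be continuation of the match, and SSR flanks are forced
to break the period: without this, background occasionally continues a
match by chance and the maximal-alignment boundary genuinely differs from
the recorded truth, making exact-recovery assertions ambiguous. Noise and
divergence are substitution-only by default because edit calling assumes
colinear DNA/cDNA.

What the generator does *not* emulate: sequencing reads and chromatogram
ambiguity, assembly errors, indel divergence of transferred fragments,
recombination-mediated repeat structure, partial editing extents, and real
codon-usage bias beyond GC composition. Passing the recovery tests
therefore demonstrates correctness of the comparison logic under the stated
model, not performance on raw trace data.

## Problem sizes used by the checks

The acceptance script recomputes the published derived statistics from
their printed raw inputs (read totals, validated bp, feature bp totals, the
19 fragment lengths, edit-class counts) and measures planted-truth recovery
over five 40-kb bundles per run; the test suite additionally runs 20-seed
edit recovery, a 50-seed SSR brute-force comparison on 2-kb genomes, and
exhaustive oracles for codon classification and alignment scoring. The full
suite completes in well under a minute on one CPU.

## Known limitations

* Long-repeat and local-search detectors are seed-based: sensitivity decays
  for short or highly divergent homology (no 11-/31-mer anchor → no hit).
* The e-value constants are fixed approximations; do not compare e-values
  across tools.
* The short-repeat class (20–500 bp) is screened with the same machinery by
  lowering `min_len`, but published short-repeat counts lack a stated
  identity/maximality rule, so no equivalence is claimed.
* Cross-species shared-edit counting depends on the documented
  alignment-column rule; codon-homology matching could give slightly
  different totals.
* `mask_features` masks exons only; intron positions of masked genes remain
  searchable, matching the published masking list (protein/tRNA/rRNA genes).
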