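"""Edit calling, codon-effect classification, frequencies, cross-species
comparison — checked against independent brute-force oracles."""

import itertools
import random

import pytest

from mitokit import (
    GeneModel,
    Interval,
    align_dna_cdna,
    call_all_edits,
    call_edits,
    classify_edit,
    compare_editing_sets,
    dedupe_copies,
    editing_frequency,
    generate_bundle,
    generate_cdna,
    nonsynonymous_share,
    partition_counts,
    splice_cds,
)
from mitokit.editing import EditingSite

# Independent genetic-code oracle (standard code), hand-written rather than
# taken from the implementation's translation path.
ORACLE_CODE = {}
_BASES = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    ORACLE_CODE[_a + _b + _c] = _AAS[_i]


def _oracle_affine_global(a: str, b: str, match=1, mismatch=-1, open_=-5, ext=-2):
    """Exhaustive enumeration of all global alignments with affine gaps.

    Feasible only for tiny strings; returns the optimal score.
    """
    best = [float("-inf")]

    def rec(i, j, score, in_gap):
        if score + (max(len(a) - i, len(b) - j)) * match < best[0] - 20:
            return  # loose bound to keep enumeration quick
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, None)
        if i < len(a):
            cost = ext if in_gap == "a" else open_
            rec(i + 1, j, score + cost, "a")
        if j < len(b):
            cost = ext if in_gap == "b" else open_
            rec(i, j + 1, score + cost, "b")

    rec(0, 0, 0, None)
    return best[0]


class TestAlignment:
    def test_identical_sequences_gap_free(self):
        s = "ACGT" * 23  # 92 nt
        ga, gb, score = align_dna_cdna(s, s)
        assert ga == gb == s
        assert score == len(s)

    def test_single_substitution_one_mismatch_column(self):
        s = "ACGT" * 20
        t = s[:11] + "A" + s[12:]
        assert s[11] != "A"
        ga, gb, _ = align_dna_cdna(s, t)
        mism = sum(1 for x, y in zip(ga, gb) if x != y)
        assert "-" not in ga + gb
        assert mism == 1

    def test_score_matches_exhaustive_affine_oracle(self):
        import warnings

        rng = random.Random(42)
        for _ in range(12):
            n = rng.randint(4, 8)
            m = rng.randint(4, 8)
            a = "".join(rng.choice("ACGT") for _ in range(n))
            b = "".join(rng.choice("ACGT") for _ in range(m))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny strings trip ratio check
                _, _, score = align_dna_cdna(a, b)
            assert score == _oracle_affine_global(a, b)

    def test_length_ratio_warning(self):
        with pytest.warns(UserWarning, match="ratio"):
            align_dna_cdna("ACGTACGTACGT", "ACG")


class TestClassify:
    @pytest.mark.parametrize(
        "codon,pos,direction,expected",
        [
            ("TCT", 1, "U2C", ("CCT", "S", "P", "nonsynonymous")),
            ("GTG", 2, "U2C", ("GCG", "V", "A", "nonsynonymous")),
            ("ACC", 3, "C2U", ("ACT", "T", "T", "synonymous")),
        ],
    )
    def test_documented_cases(self, codon, pos, direction, expected):
        assert classify_edit(codon, pos, direction) == expected

    def test_non_editable_base_errors(self):
        with pytest.raises(ValueError, match="not editable"):
            classify_edit("AAA", 1, "C2U")

    def test_exhaustive_against_translate_and_compare_oracle(self):
        """All 384 (codon, pos, direction) combinations: the 96 with an
        editable base agree with brute-force translate-and-compare; the
        other 288 raise."""
        n_checked = n_rejected = 0
        for codon in ORACLE_CODE:
            for pos in (1, 2, 3):
                for direction, (src, dst) in (
                    ("C2U", ("C", "T")),
                    ("U2C", ("T", "C")),
                ):
                    if codon[pos - 1] != src:
                        with pytest.raises(ValueError):
                            classify_edit(codon, pos, direction)
                        n_rejected += 1
                        continue
                    edited, ref_aa, ed_aa, effect = classify_edit(
                        codon, pos, direction
                    )
                    oracle_edited = codon[: pos - 1] + dst + codon[pos:]
                    assert edited == oracle_edited
                    assert ref_aa == ORACLE_CODE[codon]
                    assert ed_aa == ORACLE_CODE[oracle_edited]
                    oracle_effect = (
                        "synonymous"
                        if ORACLE_CODE[codon] == ORACLE_CODE[oracle_edited]
                        else "nonsynonymous"
                    )
                    assert effect == oracle_effect
                    n_checked += 1
        assert n_checked == 96 and n_rejected == 288


class TestCallEdits:
    GENE = GeneModel("g1", "g1", "protein", [Interval(101, 160, "+")])

    def test_identical_sequences_no_edits(self):
        cds = "ATG" + "CAT" * 18 + "TAA"
        res = call_edits(cds, cds, gene=None, gene_id="g")
        assert res.sites == [] and res.discrepancies == []

    def test_planted_c_to_t_position_and_codon_context(self):
        # C at cds position 22 -> codon 8, codon position 1
        cds = "ATG" + "AAA" * 6 + "CGT" + "AAA" * 11 + "TAA"
        assert cds[21] == "C"
        cdna = cds[:21] + "T" + cds[22:]
        gene = GeneModel("g1", "g1", "protein",
                         [Interval(101, 100 + len(cds), "+")])
        res = call_edits(cds, cdna, gene=gene)
        (site,) = res.sites
        assert (site.cds_pos, site.direction) == (22, "C2U")
        assert (site.codon_index, site.codon_pos) == (8, 1)
        assert site.ref_codon == "CGT" and site.edited_codon == "TGT"
        assert site.genomic_pos == 122
        assert res.discrepancies == []

    def test_g_to_a_mismatch_is_discrepancy_not_edit(self):
        cds = "ATG" + "GGG" * 10 + "TAA"
        cdna = cds[:10] + "A" + cds[11:]
        res = call_edits(cds, cdna, gene=None, gene_id="g")
        assert res.sites == []
        assert len(res.discrepancies) == 1
        d = res.discrepancies[0]
        assert (d.dna_base, d.cdna_base) == ("G", "A")

    def test_minus_strand_genomic_projection(self):
        # gene on - strand: genomic position counts back from exon end
        from mitokit import Genome

        cds = "ATG" + "CCC" * 5 + "TAA"
        genome = Genome("g", "A" * 10 + str(__import__("Bio.Seq", fromlist=["reverse_complement"]).reverse_complement(cds)) + "A" * 10)
        gene = GeneModel("m", "m", "protein", [Interval(11, 10 + len(cds), "-")])
        assert splice_cds(genome, gene) == cds
        cdna = cds[:3] + "T" + cds[4:]
        res = call_edits(splice_cds(genome, gene), cdna, gene=gene)
        (site,) = res.sites
        assert site.cds_pos == 4
        assert site.genomic_pos == gene.exons[0].end - 3


class TestFrequency:
    def test_zero(self):
        assert editing_frequency(0, 300) == 0.0

    def test_reported_per_gene_frequencies(self):
        # counts first confirmed by the inverse oracle round(freq*len/100)
        assert round(7.111 * 225 / 100) == 16
        assert round(6.924 * 621 / 100) == 43
        assert editing_frequency(16, 225) == 7.111
        assert editing_frequency(43, 621) == 6.924

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            editing_frequency(1, 0)


class TestDedupe:
    def _ann(self):
        from mitokit import AnnotationSet

        return AnnotationSet(
            "g",
            [
                GeneModel("rps19-1", "rps19-1", "protein", [Interval(1, 30, "+")]),
                GeneModel("rps19-2", "rps19-2", "protein", [Interval(101, 130, "+")]),
                GeneModel("sdh3-a", "sdh3-a", "protein", [Interval(201, 230, "+")]),
                GeneModel("sdh3-b", "sdh3-b", "protein", [Interval(301, 330, "+")]),
            ],
        )

    def test_identical_copies_counted_once(self):
        sites = [
            EditingSite("rps19-1", 5, "C2U"),
            EditingSite("rps19-2", 5, "C2U"),
        ]
        cds = {"rps19-1": "ACGT" * 5, "rps19-2": "ACGT" * 5}
        out = dedupe_copies(sites, self._ann(), cds)
        assert [s.gene_id for s in out] == ["rps19-1"]

    def test_divergent_ab_copies_both_retained(self):
        sites = [
            EditingSite("sdh3-a", 5, "C2U"),
            EditingSite("sdh3-b", 5, "C2U"),
        ]
        out = dedupe_copies(sites, self._ann(), None)
        assert len(out) == 2

    def test_no_duplicates_unchanged(self):
        sites = [EditingSite("sdh3-a", 5, "C2U")]
        assert dedupe_copies(sites, self._ann(), None) == sites


class TestPartition:
    def test_reported_totals_round_to_87_percent(self):
        assert nonsynonymous_share(612, 58, 30) == 87.0

    def test_partitioned_only_variant(self):
        assert nonsynonymous_share(612, 58, 30, of_partitioned_only=True) == 91.0

    def test_partition_counts(self):
        sites = [
            EditingSite("a", 1, "C2U", effect="nonsynonymous"),
            EditingSite("a", 2, "C2U", effect="synonymous"),
            EditingSite("b", 1, "C2U", effect="unpartitioned"),
        ]
        assert partition_counts(sites) == {
            "nonsynonymous": 1, "synonymous": 1, "unpartitioned": 1
        }


class TestCompare:
    def test_species_against_itself_all_shared(self):
        cds = {"g": "ACGT" * 10}
        sites = [EditingSite("g", 4, "C2U"), EditingSite("g", 10, "C2U")]
        s = compare_editing_sets(sites, cds, sites, cds)
        assert (s.n_shared, s.n_unique_a, s.n_unique_b) == (2, 0, 0)

    def test_disjoint_positions_nothing_shared(self):
        cds = {"g": "C" * 30}
        a = [EditingSite("g", 1, "C2U")]
        b = [EditingSite("g", 20, "C2U")]
        s = compare_editing_sets(a, cds, b, cds)
        assert (s.n_shared, s.n_unique_a, s.n_unique_b) == (0, 1, 1)

    def test_toy_overlap_by_hand(self):
        cds = {"g": "C" * 30}
        a = [EditingSite("g", 4, "C2U"), EditingSite("g", 10, "C2U")]
        b = [EditingSite("g", 10, "C2U"), EditingSite("g", 13, "C2U")]
        s = compare_editing_sets(a, cds, b, cds)
        assert (s.n_shared, s.n_unique_a, s.n_unique_b) == (1, 1, 1)

    def test_symmetry(self):
        cds_a = {"g": "C" * 30, "h": "CT" * 15}
        cds_b = {"g": "C" * 30, "h": "CT" * 15, "only_b": "C" * 12}
        a = [EditingSite("g", 4, "C2U"), EditingSite("h", 2, "U2C")]
        b = [EditingSite("g", 4, "C2U"), EditingSite("g", 7, "C2U")]
        fwd = compare_editing_sets(a, cds_a, b, cds_b)
        rev = compare_editing_sets(b, cds_b, a, cds_a)
        assert fwd.n_shared == rev.n_shared
        assert (fwd.n_unique_a, fwd.n_unique_b) == (rev.n_unique_b, rev.n_unique_a)


class TestRecovery:
    def test_exact_recovery_on_noise_free_bundle(self, bundle):
        res = call_all_edits(bundle.mt, bundle.mt_ann, bundle.cdna)
        called = {s.key for s in res.sites}
        planted = {tuple(e) for e in bundle.truth.planted_edits}
        assert called == planted
        assert res.discrepancies == []
        # pseudogene edits are unpartitioned, protein edits never are
        for s in res.sites:
            cat = bundle.mt_ann.by_id(s.gene_id).category
            if cat == "pseudogene":
                assert s.effect == "unpartitioned"
            else:
                assert s.effect in ("synonymous", "nonsynonymous")

    def test_noise_robustness_precision_and_recall(self):
        """0.5% substitution noise: non-C/T mismatches are never called as
        edits, and planted edits stay called unless noise hits them."""
        for seed in (21, 22, 23):
            b = generate_bundle(seed=seed, noise_rate=0.005)
            clean = generate_bundle(seed=seed, noise_rate=0.0)
            res = call_all_edits(b.mt, b.mt_ann, b.cdna)
            planted = {tuple(e) for e in b.truth.planted_edits}
            called = {s.key for s in res.sites}
            # every planted edit recovered (noise skips planted positions)
            assert planted <= called
            # extra calls only at noise positions that mimic editing chemistry
            for gid, pos, direction in called - planted:
                cds = splice_cds(clean.mt, clean.mt_ann.by_id(gid))
                assert (cds[pos - 1], direction) in (("C", "C2U"), ("T", "U2C"))

    def test_premrna_amplicon_calls_against_unspliced_reference(self, bundle):
        from mitokit.core import premrna

        gene = next(
            g for g in bundle.mt_ann
            if len(g.exons) > 1 and not g.trans_spliced and g.category == "protein"
        )
        pre = premrna(bundle.mt, gene)
        # edit a C in the first exon region of the pre-mRNA amplicon
        pos0 = pre.index("C", 10)
        amplicon = pre[:pos0] + "T" + pre[pos0 + 1 :]
        res = call_all_edits(
            bundle.mt, bundle.mt_ann, {gene.gene_id: amplicon},
            premrna_genes={gene.gene_id},
        )
        (site,) = res.sites
        assert site.direction == "C2U"
        # exon 1 maps back into spliced CDS coordinates with codon context
        assert site.cds_pos == pos0 + 1
        assert site.codon_index is not None
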