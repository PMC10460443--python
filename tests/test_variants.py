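"""Variant records, normalization, caller consensus, SBS classification,
clonality QC, catalog construction and SBS7 collapse."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import sigcrypt as sc
from sigcrypt.schemas import reverse_complement
from sigcrypt.variants import (
    ClassificationError,
    MalformedInputError,
    ReferenceGenome,
    VariantRecord,
    build_catalog,
    classify_sbs,
    collapse_to_sbs7,
    intersect_callers,
    merge_adjacent_snvs,
    normalize_variant,
    rank_mutated_genes,
    vaf_clonality_filter,
)

from conftest import sparse_catalog


def V(pos, ref, alt, sample="s", vaf=0.5, callers=()):
    return VariantRecord("chr1", pos, ref, alt, vaf, sample,
                         frozenset(callers))


class TestVariantRecord:
    def test_class_assignment(self):
        assert V(5, "A", "T").variant_class == "SNV"
        assert V(5, "AC", "GT").variant_class == "DBS"
        assert V(5, "A", "AT").variant_class == "INS"
        assert V(5, "ATT", "A").variant_class == "DEL"

    @pytest.mark.parametrize(
        "ref,alt,vaf",
        [("A", "A", 0.5), ("", "A", 0.5), ("A", "N", 0.5), ("A", "T", 1.2)],
    )
    def test_invalid_records_rejected(self, ref, alt, vaf):
        with pytest.raises(MalformedInputError):
            VariantRecord("chr1", 5, ref, alt, vaf)


class TestNormalization:
    # contig with a tandem AC repeat: positions 4-9 hold ACACAC
    genome = ReferenceGenome({"chr1": "TTTACACACGGG"})

    def test_left_and_right_aligned_deletions_match(self):
        left = V(3, "TAC", "T")  # delete AC, leftmost representation
        right = V(7, "CAC", "C")  # same event, right-aligned
        n_left = normalize_variant(left, self.genome)
        n_right = normalize_variant(right, self.genome)
        assert n_left.key == n_right.key
        assert len(intersect_callers([n_left], [n_right])) == 1

    def test_shared_prefix_and_suffix_trimmed(self):
        padded = V(4, "ACA", "ATA")  # embedded SNV C>T at pos 5
        n = normalize_variant(padded, self.genome)
        assert (n.pos, n.ref, n.alt) == (5, "C", "T")

    def test_snv_untouched(self):
        v = V(5, "C", "G")
        assert normalize_variant(v, self.genome) is v


class TestIntersectCallers:
    def test_consensus_semantics(self):
        a = [V(5, "C", "T", callers=["m2"]), V(9, "C", "A", callers=["m2"])]
        b = [V(5, "C", "T", callers=["s2"])]
        out = intersect_callers(a, b)
        assert [v.pos for v in out] == [5]  # only-one-caller variant dropped
        assert out[0].callers == frozenset({"m2", "s2"})
        assert out[0].vaf == a[0].vaf  # VAF from the primary caller

    def test_membership_commutative(self):
        a = [V(5, "C", "T"), V(9, "C", "A")]
        b = [V(5, "C", "T"), V(12, "G", "A")]
        keys_ab = {v.key for v in intersect_callers(a, b)}
        keys_ba = {v.key for v in intersect_callers(b, a)}
        assert keys_ab == keys_ba

    def test_conflicting_ref_alleles_raise(self):
        with pytest.raises(MalformedInputError, match="chr1:5"):
            intersect_callers([V(5, "C", "T")], [V(5, "G", "T")])


class TestClonalityFilter:
    def test_centered_sample_passes(self):
        records = [V(i, "C", "T", vaf=0.5) for i in range(1, 61)]
        assert vaf_clonality_filter(records).status == "pass"

    def test_subclonal_sample_fails(self):
        records = [V(i, "C", "T", vaf=0.25) for i in range(1, 61)]
        res = vaf_clonality_filter(records)
        assert res.status == "fail"
        assert res.frac_below_03 == 1.0

    def test_too_few_variants_is_indeterminate_not_fail(self):
        records = [V(i, "C", "T", vaf=0.25) for i in range(1, 10)]
        assert vaf_clonality_filter(records).status == "indeterminate"

    def test_clonal_beta_draws_pass_almost_surely(self):
        # 500 VAFs ~ Beta(50,50) per seed: the filter should accept
        # essentially every clonal sample.
        passes = 0
        n_seeds = 200
        for seed in range(n_seeds):
            vafs = sc.simulate_vaf(500, clonal=True, seed=seed)
            recs = [V(i + 1, "C", "T", vaf=float(x))
                    for i, x in enumerate(vafs)]
            passes += vaf_clonality_filter(recs).status == "pass"
        assert passes / n_seeds > 0.99

    def test_nonclonal_mixture_fails(self):
        fails = 0
        n_seeds = 100
        for seed in range(n_seeds):
            vafs = sc.simulate_vaf(500, clonal=False, seed=seed)
            recs = [V(i + 1, "C", "T", vaf=float(x))
                    for i, x in enumerate(vafs)]
            fails += vaf_clonality_filter(recs).status == "fail"
        assert fails / n_seeds > 0.95


class TestClassifySbs:
    def test_pyrimidine_reference_direct(self):
        assert classify_sbs(V(2, "C", "A"), "ACA") == "A[C>A]A"

    def test_purine_reference_reverse_complemented(self):
        assert classify_sbs(V(2, "G", "T"), "TGT") == "A[C>A]A"

    def test_full_enumeration_hits_each_channel_twice(self):
        from collections import Counter

        hits = Counter()
        for five, mid, three in product("ACGT", repeat=3):
            for alt in "ACGT":
                if alt == mid:
                    continue
                hits[classify_sbs(V(2, mid, alt), five + mid + three)] += 1
        assert len(hits) == 96
        assert set(hits.values()) == {2}

    def test_strand_symmetry(self):
        for five, mid, three in product("ACGT", repeat=3):
            for alt in "ACGT":
                if alt == mid:
                    continue
                fwd = classify_sbs(V(2, mid, alt), five + mid + three)
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                rev = classify_sbs(
                    V(2, comp[mid], comp[alt]),
                    reverse_complement(five + mid + three),
                )
                assert fwd == rev

    def test_context_errors(self):
        with pytest.raises(ClassificationError):
            classify_sbs(V(2, "C", "A"), "ANA")
        with pytest.raises(ClassificationError):
            classify_sbs(V(2, "C", "A"), "ATA")  # middle base mismatch


class TestBuildCatalog:
    genome = ReferenceGenome({"chr1": "GGACAGG"})

    def test_empty_input_gives_zero_catalog(self):
        cat = build_catalog([], self.genome, "SBS96")
        assert cat.totals.sum() == 0

    def test_identical_snvs_count_into_one_channel(self):
        variants = [V(4, "C", "T") for _ in range(10)]
        cat = build_catalog(variants, self.genome, "SBS96")
        assert cat.df.loc["A[C>T]A", "s"] == 10
        assert cat.totals["s"] == 10

    def test_out_of_schema_variants_reported_not_dropped(self):
        variants = [V(4, "C", "T"), V(4, "CA", "C")]
        cat = build_catalog(variants, self.genome, "SBS96")
        assert cat.totals["s"] == 1
        assert len(cat.unclassified) == 1
        assert cat.unclassified.iloc[0]["variant_class"] == "DEL"

    def test_locus_outside_reference_raises(self):
        with pytest.raises(KeyError, match="chr1:400"):
            build_catalog([V(400, "C", "T")], self.genome, "SBS96")

    def test_channel_conservation(self):
        rng = np.random.default_rng(0)
        variants = [V(4, "C", alt) for alt in rng.choice(list("AGT"), 30)]
        cat = build_catalog(variants, self.genome, "SBS96")
        assert cat.totals.sum() + len(cat.unclassified) == len(variants)


class TestCollapseSbs7:
    def test_cpg_context_routed_to_cpg_category(self):
        cat = sparse_catalog({"s": {"A[C>T]G": 7}}, "SBS96")
        out = collapse_to_sbs7(cat)
        assert out.df.loc["C>T at CpG", "s"] == 7
        assert out.df.loc["C>T other", "s"] == 0

    def test_non_cpg_c_to_t(self):
        cat = sparse_catalog({"s": {"A[C>T]A": 5}}, "SBS96")
        out = collapse_to_sbs7(cat)
        assert out.df.loc["C>T other", "s"] == 5

    def test_column_sums_preserved_on_random_catalog(self, sbs96):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.poisson(4.0, size=(96, 5)),
            index=list(sbs96.labels),
            columns=[f"s{i}" for i in range(5)],
        )
        cat = sc.MutationCatalog(df, sbs96)
        out = collapse_to_sbs7(cat)
        assert (out.totals == cat.totals).all()

    def test_wrong_schema_rejected(self):
        cat = sparse_catalog({"s": {"1:Del:C:0": 1}}, "ID83")
        with pytest.raises(sc.schemas.SchemaError):
            collapse_to_sbs7(cat)


class TestDbsMerging:
    def test_adjacent_snvs_become_one_dbs(self):
        merged, dbs = merge_adjacent_snvs([V(5, "C", "T"), V(6, "G", "A")])
        assert len(merged) == 1 and len(dbs) == 1
        assert dbs[0].variant_class == "DBS"
        assert (dbs[0].ref, dbs[0].alt) == ("CG", "TA")

    def test_distant_snvs_untouched(self):
        merged, dbs = merge_adjacent_snvs([V(5, "C", "T"), V(9, "G", "A")])
        assert len(merged) == 2 and not dbs


class TestGeneRanking:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "consequence"])

    def test_most_recurrent_gene_ranked_first(self):
        rows = [(f"s{i}", "Recur", "missense") for i in range(4)]
        rows += [("s0", "Single", "missense")]
        groups = {f"s{i}": "HFD" for i in range(4)}
        tables, _ = rank_mutated_genes(self._table(rows), groups, n=2)
        assert tables["HFD"].iloc[0]["gene"] == "Recur"

    def test_identical_tables_give_full_overlap(self):
        rows = [("a1", g, "missense") for g in "ABCDEFGHIJ"]
        rows += [("b1", g, "missense") for g in "ABCDEFGHIJ"]
        groups = {"a1": "HFD", "b1": "SD"}
        _, overlap = rank_mutated_genes(self._table(rows), groups, n=10)
        assert overlap == 10

    def test_constructed_nine_of_ten_overlap(self):
        shared = [f"G{i}" for i in range(9)]
        rows = [("a1", g, "missense") for g in shared + ["OnlyHFD"]]
        rows += [("b1", g, "missense") for g in shared + ["OnlySD"]]
        groups = {"a1": "HFD", "b1": "SD"}
        _, overlap = rank_mutated_genes(self._table(rows), groups, n=10)
        assert overlap == 9
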