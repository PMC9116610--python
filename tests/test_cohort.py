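"""Cohort screen: consequence classes, MAF, Fisher burden, filters."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from bmzone.cohort import (
    PLOF_TERMS,
    CohortDataset,
    classify_consequence,
    cohort_maf,
    compound_het_candidates,
    constraint_flags,
    fisher_burden_test,
    gene_burden,
    high_penetrance_filter,
    read_cohort_vcf,
    stratified_burden,
)
from bmzone.simulate import gen_cohort, toy_cohort_config


def exact_fisher_p(table) -> float:
    """Oracle: two-sided Fisher p by enumerating the conditional distribution."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = sum(
        (p for x in range(max(0, c1 - r2), min(r1, c1) + 1)
         if (p := prob(x)) <= p_obs),
        Fraction(0),
    )
    return float(total)


class TestConsequenceClassification:
    @pytest.mark.parametrize("term", sorted(PLOF_TERMS))
    def test_seven_plof_terms(self, term):
        assert classify_consequence(term).value == "pLoF"

    @pytest.mark.parametrize(
        "term, expected",
        [
            ("missense_variant", "missense"),
            ("synonymous_variant", "synonymous"),
            ("intron_variant", "other"),
            ("upstream_gene_variant,intron_variant", "other"),
            # any pLoF member of a multi-term annotation wins
            ("missense_variant,frameshift_variant", "pLoF"),
            ("stop_gained&splice_region_variant", "pLoF"),
        ],
    )
    def test_multi_term_and_fallback(self, term, expected):
        assert classify_consequence(term).value == expected

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            classify_consequence("  ")


class TestCohortMaf:
    def test_het_counting(self):
        g = np.array([1, 1, 1] + [0] * 97)
        assert cohort_maf(g) == pytest.approx(3 / 200)

    def test_single_hom_hits_boundary(self):
        # 1 homozygote in 100 samples gives exactly 0.01: fails strict < 0.01
        g = np.array([2] + [0] * 99)
        assert cohort_maf(g) == pytest.approx(0.01)
        assert not cohort_maf(g) < 0.01

    def test_folding(self):
        assert cohort_maf(np.array([2, 2, 2])) == 0.0

    def test_missing_excluded_from_denominator(self):
        g = np.array([1, -1, 0, 0])
        assert cohort_maf(g) == pytest.approx(1 / 6)

    def test_all_missing_is_nan(self):
        assert np.isnan(cohort_maf(np.array([-1, -1])))


class TestFisherBurden:
    def test_cross_product_arithmetic(self):
        out = fisher_burden_test([[10, 90], [2, 98]], cmle=False)
        assert out["or_point"] == pytest.approx((10 * 98) / (90 * 2))

    def test_symmetric_table(self):
        out = fisher_burden_test([[7, 93], [7, 93]], cmle=False)
        assert out["or_point"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_zero_cell_haldane(self):
        out = fisher_burden_test([[5, 95], [0, 100]])
        want = (5.5 * 100.5) / (95.5 * 0.5)
        assert out["or_point"] == pytest.approx(want)
        assert out["p_value"] == pytest.approx(
            exact_fisher_p([[5, 95], [0, 100]]), rel=1e-9
        )
        assert out["ci_low"] <= out["or_point"] <= out["ci_high"]

    @pytest.mark.parametrize("seed", range(20))
    def test_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 120, size=(2, 2))
        if t.sum() == 0 or t.sum() > 500:
            t = np.array([[3, 50], [1, 60]])
        out = fisher_burden_test(t.tolist(), cmle=False)
        assert out["p_value"] == pytest.approx(exact_fisher_p(t), rel=1e-9)

    def test_cmle_interval_reported(self):
        out = fisher_burden_test([[10, 90], [2, 98]], cmle=True)
        assert out["ci_cmle_low"] <= out["or_cmle"] <= out["ci_cmle_high"]


def tiny_dataset(genotypes, consequences=None, canonical=None, lof=None,
                 gnomad=None, statuses=None, genes=None):
    n_var, n_samp = genotypes.shape
    samples = [f"S{i}" for i in range(n_samp)]
    statuses = statuses or ["affected"] * (n_samp // 2) + ["unaffected"] * (
        n_samp - n_samp // 2
    )
    variants = pd.DataFrame(
        {
            "gene": genes or ["G1"] * n_var,
            "variant_id": [f"1:{i + 1}:A:T" for i in range(n_var)],
            "consequence": consequences or ["frameshift_variant"] * n_var,
            "canonical": canonical if canonical is not None else [True] * n_var,
            "lof_confidence": lof or ["HC"] * n_var,
            "gnomad_hom_count": gnomad if gnomad is not None else [0] * n_var,
        }
    )
    return CohortDataset(
        variants=variants,
        genotypes=genotypes.astype(np.int8),
        samples=samples,
        phenotype=pd.Series(statuses, index=samples),
    )


class TestBurdenFilters:
    def test_noncanonical_and_common_variants_excluded(self):
        g = np.zeros((3, 300), dtype=np.int8)
        g[0, :2] = 2           # rare canonical: qualifies
        g[1, :2] = 2           # non-canonical: excluded
        g[2, :150] = 1         # common (MAF 0.25): excluded
        ds = tiny_dataset(g, canonical=[True, False, True])
        b = gene_burden(ds, cmle=False)
        assert b.loc[0, "aff_carriers"] == 2
        assert b.loc[0, "unaff_carriers"] == 0

    def test_relaxing_maf_never_removes_qualifying_variants(self):
        ds, _ = gen_cohort(toy_cohort_config(), seed=4)
        tight = ds.qualifying_mask(maf_max=0.005)
        loose = ds.qualifying_mask(maf_max=0.05)
        assert not np.any(tight & ~loose)

    def test_missing_genotypes_are_noncarriers(self):
        g = np.full((1, 10), -1, dtype=np.int8)
        g[0, 0] = 2
        ds = tiny_dataset(g)
        b = gene_burden(ds, cmle=False)
        assert b.loc[0, "aff_carriers"] == 1
        assert b.loc[0, "unaff_carriers"] == 0


class TestStratifiedBurden:
    def test_single_gene_tier_equals_gene_row(self):
        ds, truth = gen_cohort(toy_cohort_config(), seed=6)
        burden = gene_burden(ds, cmle=False).set_index("gene")
        tiers = {g: ("high" if g == "BMG001" else "none")
                 for g in truth.gene_roles}
        strat = stratified_burden(ds, tiers, cmle=False).set_index("tier")
        for col in ["aff_carriers", "unaff_carriers", "or_point", "p_value"]:
            assert strat.loc["high", col] == burden.loc["BMG001", col]

    def test_all_row_pools_every_gene(self):
        ds, truth = gen_cohort(toy_cohort_config(), seed=6)
        strat = stratified_burden(ds, truth.tiers, cmle=False).set_index("tier")
        n = len(ds.samples)
        assert (
            strat.loc["all", ["aff_carriers", "aff_noncarriers",
                              "unaff_carriers", "unaff_noncarriers"]].sum()
            == n
        )

    def test_missing_tier_rejected(self):
        ds, _ = gen_cohort(toy_cohort_config(), seed=6)
        with pytest.raises(ValueError, match="tier"):
            stratified_burden(ds, {}, cmle=False)


class TestConstraintFlags:
    def test_thresholds(self):
        df = pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "pli": [0.95, 0.1, 0.5],
                "loeuf": [0.5, 0.15, 0.5],
            }
        )
        out = constraint_flags(df).set_index("gene")
        assert out.loc["A", "pli_intolerant"] and not out.loc["A", "loeuf_intolerant"]
        assert out.loc["B", "loeuf_intolerant"] and not out.loc["B", "pli_intolerant"]
        assert not out.loc["C", "pli_intolerant"]

    def test_nonpositive_loeuf_rejected(self):
        df = pd.DataFrame({"gene": ["A"], "pli": [0.5], "loeuf": [0.0]})
        with pytest.raises(ValueError):
            constraint_flags(df)


class TestHighPenetranceFilter:
    def base_genotypes(self, n=300):
        g = np.zeros((2, n), dtype=np.int8)
        return g

    def test_pass_and_prioritized(self):
        g = self.base_genotypes()
        g[0, 0] = g[0, 1] = g[1, 2] = 2  # three affected homozygotes
        ds = tiny_dataset(g)
        (v,) = high_penetrance_filter(ds)
        assert v.passes and v.prioritized and v.n_affected_hom == 3

    def test_unaffected_hom_fails(self):
        g = self.base_genotypes()
        g[0, 0] = 2
        g[0, 200] = 2  # unaffected homozygote
        ds = tiny_dataset(g)
        (v,) = high_penetrance_filter(ds)
        assert not v.passes and "unaffected hom present" in v.reasons

    def test_gnomad_hom_count_fails(self):
        g = self.base_genotypes()
        g[0, 0] = 2
        ds = tiny_dataset(g, gnomad=[2, 0])
        (v,) = high_penetrance_filter(ds)
        assert not v.passes
        assert any("gnomad" in r for r in v.reasons)

    def test_lc_variants_do_not_qualify(self):
        g = self.base_genotypes()
        g[0, 0] = 2
        ds = tiny_dataset(g, lof=["LC", "LC"])
        assert high_penetrance_filter(ds) == []


class TestCompoundHet:
    def make_ds(self):
        g = np.zeros((3, 200), dtype=np.int8)
        g[0, 0] = g[1, 0] = 1   # sample 0 het at v1+v2
        g[0, 1] = g[1, 1] = 1   # sample 1 het at v1+v2
        return tiny_dataset(
            g, consequences=["frameshift_variant", "stop_gained",
                             "synonymous_variant"]
        )

    def test_without_phase_only_possible(self):
        ds = self.make_ds()
        out = compound_het_candidates(ds)
        assert set(out["phase"]) == {"possible"}

    def test_phase_confirms_trans_and_drops_cis(self):
        ds = self.make_ds()
        phase = {
            ("S0", "1:1:A:T", "1:2:A:T"): "trans",
            ("S1", "1:1:A:T", "1:2:A:T"): "cis",
        }
        out = compound_het_candidates(ds, phase=phase)
        assert out["sample"].tolist() == ["S0"]
        assert out["phase"].tolist() == ["confirmed"]

    def test_requires_a_plof_member(self):
        g = np.zeros((2, 200), dtype=np.int8)
        g[0, 0] = g[1, 0] = 1
        ds = tiny_dataset(
            g, consequences=["missense_variant", "missense_variant"], lof=["NA", "NA"]
        )
        assert compound_het_candidates(ds).empty


class TestVcfRoundTrip:
    def test_toy_fixture_loads_and_matches_regeneration(self, toy_cohort_dir):
        ds_file = read_cohort_vcf(
            toy_cohort_dir / "cohort.vcf", toy_cohort_dir / "phenotype.tsv"
        )
        ds_mem, _ = gen_cohort(toy_cohort_config(), seed=17)
        assert np.array_equal(ds_file.genotypes, ds_mem.genotypes)
        cols = ["gene", "variant_id", "consequence", "canonical",
                "lof_confidence", "gnomad_hom_count"]
        assert ds_file.variants[cols].equals(
            ds_mem.variants[cols].reset_index(drop=True)
        )
        assert (ds_file.phenotype.loc[ds_mem.samples]
                == ds_mem.phenotype.loc[ds_mem.samples]).all()

    def test_burden_identical_from_vcf_and_memory(self, toy_cohort_dir):
        ds_file = read_cohort_vcf(
            toy_cohort_dir / "cohort.vcf", toy_cohort_dir / "phenotype.tsv"
        )
        ds_mem, _ = gen_cohort(toy_cohort_config(), seed=17)
        pd.testing.assert_frame_equal(
            gene_burden(ds_file, cmle=False), gene_burden(ds_mem, cmle=False)
        )
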