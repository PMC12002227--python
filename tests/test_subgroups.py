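"""Phenotype subgroup association, clinical comparisons, protein-region tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chdburden.case_control import fet_burden
from chdburden.records import InputError, VARIANT_COLUMNS
from chdburden.subgroups import (
    ProteinRegion,
    cysteine_altering,
    feature_2x2,
    phenotype_permutation_test,
    rank_sum,
    region_class_enrichment,
    subgroup_meta,
)

from conftest import make_variant, variant_frame


def fisher_two_sided_oracle(a, b, c, d):
    """Brute force: sum point probabilities <= observed over the support."""
    r1, K = a + b, a + c
    M = a + b + c + d
    denom = math.comb(M, r1)

    def point(k):
        return math.comb(K, k) * math.comb(M - K, r1 - k) / denom

    p_obs = point(a)
    total = 0.0
    for k in range(max(0, K - (M - r1)), min(K, r1) + 1):
        pk = point(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


class TestFeature2x2:
    def test_kabuki_feeding_difficulty_example(self):
        # 2/7 undiagnosed vs 15/18 diagnosed probands with feeding difficulty
        p, (p1, p2) = feature_2x2(2, 5, 15, 3)
        assert p == pytest.approx(1.7e-2, abs=5e-4)
        assert round(100 * p1) == 29
        assert round(100 * p2) == 83

    def test_balanced_table_uninformative(self):
        p, _ = feature_2x2(5, 5, 5, 5)
        assert p == 1.0

    def test_all_zero_table_rejected(self):
        with pytest.raises(InputError):
            feature_2x2(0, 0, 0, 0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(120):
            a, b, c, d = (int(x) for x in rng.integers(0, 31, size=4))
            if a + b + c + d == 0:
                continue
            p, _ = feature_2x2(a, b, c, d)
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-7, abs=1e-12)

    def test_two_sided_at_least_directional_one_sided(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if min(a + b, c + d) == 0:
                continue
            p2, _ = feature_2x2(a, b, c, d)
            p_greater = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            p_less = stats.fisher_exact([[a, b], [c, d]], alternative="less")[1]
            assert p2 >= min(p_greater, p_less) - 1e-12


class TestRankSum:
    def test_identical_groups_exact_p_one(self):
        assert rank_sum([1.0, 2.0, 3.0], [1.5, 2.5, 0.5]) > 0.5

    def test_fully_separated_small_groups(self):
        # most extreme of C(6,3) = 20 orderings, two-sided
        assert rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        p_exact = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        assert rank_sum(x, y) == pytest.approx(p_exact, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            rank_sum([], [1.0])


class TestPhenotypePermutation:
    def test_planted_association_reaches_lower_bound(self):
        genes = np.repeat(["A", "B"], 50)
        pheno = np.repeat(["x", "y"], 50)  # perfectly aligned
        p = phenotype_permutation_test(genes, pheno, n_perm=499, seed=1)
        assert p == pytest.approx(1 / 500)

    def test_p_within_declared_bounds(self):
        rng = np.random.default_rng(24)
        genes = rng.choice(["A", "B", "C"], 60)
        pheno = rng.choice(["x", "y"], 60)
        p = phenotype_permutation_test(genes, pheno, n_perm=199, seed=2)
        assert 1 / 200 <= p <= 1.0

    def test_invariant_to_category_renaming(self):
        rng = np.random.default_rng(25)
        genes = rng.choice(["A", "B"], 40)
        pheno = rng.choice(["x", "y", "z"], 40)
        p1 = phenotype_permutation_test(genes, pheno, n_perm=299, seed=3)
        renamed = np.array([{"x": "u", "y": "v", "z": "w"}[v] for v in pheno])
        p2 = phenotype_permutation_test(genes, renamed, n_perm=299, seed=3)
        assert p1 == p2

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(26)
        ps = []
        for rep in range(40):
            genes = rng.choice(["A", "B"], 80)
            pheno = rng.choice(["x", "y"], 80)
            ps.append(phenotype_permutation_test(genes, pheno, n_perm=199, seed=rep))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_category_rejected(self):
        with pytest.raises(InputError):
            phenotype_permutation_test(["A"] * 10, list("xyxyxyxyxy"), n_perm=100, seed=0)


class TestRegionEnrichment:
    def test_cysteine_predicate(self):
        assert cysteine_altering("C", "R")
        assert cysteine_altering("G", "C")
        assert not cysteine_altering("G", "A")
        assert not cysteine_altering(None, "C")

    def test_toy_region_matches_hand_table(self):
        region = ProteinRegion("NOTCH1", "EGF-like 5", 1, 100)
        case = variant_frame(
            [make_variant(pos=100 + i, protein_pos=10 + i, aa_ref="C", aa_alt="R") for i in range(8)]
            + [make_variant(pos=200 + i, protein_pos=20 + i, aa_ref="G", aa_alt="A") for i in range(2)]
        )
        ctrl = variant_frame([make_variant(pos=300, protein_pos=50, aa_ref="C", aa_alt="Y")])
        out = region_class_enrichment(case, ctrl, [region], case_an=10, ctrl_an=1000)
        row = out[out.region == "EGF-like 5"].iloc[0]
        fold_hand, p_hand = fet_burden(8, 10, 1, 1000)
        assert row.case_hits == 8 and row.ctrl_hits == 1
        assert row.fold == pytest.approx(fold_hand)
        assert row.p == pytest.approx(p_hand)

    def test_records_without_protein_pos_skipped(self):
        region = ProteinRegion("NOTCH1", "EGF-like 1", 1, 50)
        case = variant_frame([make_variant(protein_pos=None, aa_ref=None, aa_alt=None)])
        out = region_class_enrichment(case, variant_frame([]), [region], case_an=10, ctrl_an=100)
        assert out.attrs["n_skipped"] == 1
        assert out[out.region == "EGF-like 1"].iloc[0].case_hits == 0

    def test_region_bounds_validated(self):
        with pytest.raises(InputError):
            ProteinRegion("G", "bad", 10, 5)


class TestSubgroupMeta:
    def _setup(self, rng, n_genes=20, strong_gene="G0001", strong_pheno="TOF"):
        genes = [f"G{i + 1:04d}" for i in range(n_genes)]
        phenos = ["CTD", "TOF", "LVO", "ASD"]
        mut = pd.DataFrame(
            {
                "gene": genes,
                "mu_synonymous": 3e-5,
                "mu_T-mis": 4e-5,
                "mu_D-mis": 2e-5,
                "mu_LOF": 1e-5,
            }
        )
        rows = []
        for g in genes:
            for ph in phenos:
                n_dnm = int(rng.poisson(0.05))
                ac = int(rng.poisson(0.5))
                if g == strong_gene and ph == strong_pheno:
                    n_dnm += 8
                    ac += 15
                rows.append(
                    {"gene": g, "fclass": "LOF", "cardiac_subtype": ph, "n_dnm": n_dnm, "case_ac": ac + n_dnm}
                )
        counts = pd.DataFrame(rows)
        controls = pd.DataFrame(
            {
                "gene": genes * 2,
                "fclass": ["LOF"] * n_genes + ["D-mis"] * n_genes,
                "ctrl_ac": 2,
                "ctrl_an": 50000,
            }
        )
        n_trios = {ph: 900 for ph in phenos}
        case_an = {ph: 2 * 1800 for ph in phenos}
        return counts, mut, controls, genes, n_trios, case_an

    def test_planted_cell_is_top_ranked(self):
        rng = np.random.default_rng(31)
        counts, mut, controls, genes, n_trios, case_an = self._setup(rng)
        out = subgroup_meta(counts, mut, controls, genes, n_trios, case_an, seed=5)
        top = out.iloc[0]
        assert (top.gene, top.phenotype) == ("G0001", "TOF")
        assert top.significant

    def test_zero_variant_gene_has_unit_pvalues(self):
        rng = np.random.default_rng(32)
        counts, mut, controls, genes, n_trios, case_an = self._setup(rng)
        counts.loc[counts.gene == "G0009", ["n_dnm", "case_ac"]] = 0
        out = subgroup_meta(counts, mut, controls, genes, n_trios, case_an, seed=5)
        sub = out[out.gene == "G0009"]
        assert (sub["p_dnm"] == 1.0).all()
        assert (sub["p_cc"] == 1.0).all()

    def test_subgroup_counts_sum_to_total(self, medium_cohort, loose_thresholds):
        """Tallies over a disjoint exhaustive phenotype partition conserve totals."""
        from chdburden.filters import aggregate_counts, classify_frame, filter_very_rare

        variants = classify_frame(medium_cohort.variants.drop(columns=["fclass"]))
        kept = filter_very_rare(variants, loose_thresholds)
        genes = medium_cohort.truth["gene"].tolist()
        total, _ = aggregate_counts(kept, genes)
        by_pheno, _ = aggregate_counts(kept, genes, phenotypes=medium_cohort.phenotypes)
        # parental records carry no proband phenotype; compare proband streams
        for col in ("n_dnm", "case_ac", "n_unphased"):
            assert by_pheno[col].sum() == total[col].sum()
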