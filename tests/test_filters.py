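"""Functional classification, rarity filtering, territory harmonization, tallies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chdburden.filters import (
    aggregate_counts,
    classify_frame,
    classify_variant,
    filter_very_rare,
    harmonize_territory,
)
from chdburden.records import FilterThresholds, InputError, VariantRecord

from conftest import make_variant, variant_frame


@pytest.mark.parametrize(
    "consequence, metasvm, expected",
    [
        ("synonymous", None, "synonymous"),
        ("missense", "D", "D-mis"),
        ("missense", "T", "T-mis"),
        ("missense", None, "T-mis"),
        ("stopgain", None, "LOF"),
        ("frameshift", None, "LOF"),
        ("canonical-splice", None, "LOF"),
        ("inframe-indel", None, "other"),
        ("other", None, "other"),
    ],
)
def test_classify_variant_total_over_vocabulary(consequence, metasvm, expected):
    assert classify_variant(consequence, metasvm) == expected


def test_classify_variant_rejects_unknown_consequence():
    with pytest.raises(InputError, match="splice_donor"):
        classify_variant("splice_donor")


class TestVeryRareFilter:
    def test_population_frequency_above_threshold_removed(self):
        df = variant_frame([make_variant(maf_bravo=2e-5)])
        assert len(filter_very_rare(df)) == 0

    def test_singleton_allele_in_full_cohort_kept(self):
        # AC 1 / AN 23110 = 4.3e-5 <= 1.3e-4
        df = variant_frame([make_variant(cohort_ac=1, cohort_an=23110)])
        assert len(filter_very_rare(df)) == 1

    def test_cohort_frequency_above_threshold_removed(self):
        df = variant_frame([make_variant(cohort_ac=4, cohort_an=23110)])
        assert len(filter_very_rare(df)) == 0

    def test_empty_input(self):
        assert len(filter_very_rare(variant_frame([]))) == 0

    def test_missing_population_frequency_treated_as_absent(self):
        df = variant_frame([make_variant(maf_bravo=np.nan, maf_esp=np.nan)])
        assert len(filter_very_rare(df)) == 1

    def test_zero_cohort_an_is_error(self):
        df = variant_frame([make_variant(cohort_ac=0, cohort_an=0)])
        with pytest.raises(InputError):
            filter_very_rare(df)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e-4),
                st.floats(0, 1e-4),
                st.integers(1, 5),
            ),
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_order_preserving(self, rows):
        df = variant_frame(
            [
                make_variant(pos=1_000_000 + i, maf_bravo=b, maf_esp=e, cohort_ac=ac)
                for i, (b, e, ac) in enumerate(rows)
            ]
        )
        once = filter_very_rare(df)
        twice = filter_very_rare(once)
        pd.testing.assert_frame_equal(once, twice)
        assert list(once.index) == sorted(once.index)


class TestHarmonizeTerritory:
    def _iv(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])

    def test_identical_sets_retain_all_records(self):
        iv = self._iv([("chr1", 1_000_000, 1_010_000, "G0001")])
        df = variant_frame([make_variant(pos=1_000_100)])
        cov, kept = harmonize_territory(iv, iv.copy(), df)
        assert len(kept) == 1
        assert cov.fractions["callable_fraction_cases"].iloc[0] == 1.0

    def test_case_only_exon_records_removed(self):
        case = self._iv(
            [("chr1", 1_000_000, 1_005_000, "G0001"), ("chr1", 1_008_000, 1_009_000, "G0001")]
        )
        ctrl = self._iv([("chr1", 1_000_000, 1_005_000, "G0001")])
        df = variant_frame([make_variant(pos=1_008_500)])
        cov, kept = harmonize_territory(case, ctrl, df)
        assert len(kept) == 0
        assert cov.fractions["callable_fraction_cases"].iloc[0] == pytest.approx(5000 / 6000)

    def test_interval_intersection_and_membership(self):
        case = self._iv([("chr1", 100, 200, "G0001")])
        ctrl = self._iv([("chr1", 150, 250, "G0001")])
        # 1-based pos 141 is 0-based 140, outside [150, 200)
        df = variant_frame([make_variant(pos=141), make_variant(pos=151)])
        cov, kept = harmonize_territory(case, ctrl, df)
        assert cov.shared_intervals[["start", "end"]].values.tolist() == [[150, 200]]
        assert kept["pos"].tolist() == [151]

    def test_malformed_interval_rejected(self):
        bad = self._iv([("chr1", 200, 200, "G0001")])
        with pytest.raises(InputError):
            harmonize_territory(bad, bad, variant_frame([]))

    def test_matches_brute_force_membership_scan(self):
        rng = np.random.default_rng(4)
        case = self._iv(
            [("chr1", int(s), int(s + rng.integers(1, 50)), "G0001") for s in rng.choice(500, 8, replace=False)]
        )
        ctrl = self._iv(
            [("chr1", int(s), int(s + rng.integers(1, 50)), "G0001") for s in rng.choice(500, 8, replace=False)]
        )
        records = variant_frame([make_variant(pos=int(p)) for p in rng.integers(1, 560, 120)])
        cov, kept = harmonize_territory(case, ctrl, records)

        def in_any(p0, iv):
            return any(r.start <= p0 < r.end for r in iv.itertuples())

        expected = [
            r.pos for r in records.itertuples() if in_any(r.pos - 1, case) and in_any(r.pos - 1, ctrl)
        ]
        assert kept["pos"].tolist() == expected


class TestAggregateCounts:
    def test_single_de_novo_lof(self):
        df = classify_frame(variant_frame([make_variant(consequence="stopgain", metasvm=None)]))
        counts, rejects = aggregate_counts(df, ["G0001"])
        row = counts[(counts.gene == "G0001") & (counts.fclass == "LOF")].iloc[0]
        assert row.n_dnm == 1 and row.case_ac == 1
        assert len(rejects) == 0

    def test_duplicate_allele_same_individual_counted_once(self):
        v = make_variant()
        df = classify_frame(variant_frame([v, dict(v)]))
        counts, _ = aggregate_counts(df, ["G0001"])
        assert counts["case_ac"].sum() == 1

    def test_unknown_gene_reported_in_rejects(self):
        df = classify_frame(variant_frame([make_variant(gene="NOT_ON_PANEL")]))
        counts, rejects = aggregate_counts(df, ["G0001"])
        assert len(counts) == 0
        assert rejects["reason"].tolist() == ["gene_not_in_panel"]

    def test_mixed_records_match_independent_tally(self):
        rows = [
            make_variant(pos=1, gene="G0001", consequence="stopgain", metasvm=None, origin="de_novo"),
            make_variant(pos=2, gene="G0001", consequence="missense", metasvm="D", origin="transmitted"),
            make_variant(pos=3, gene="G0001", consequence="missense", metasvm="D", origin="untransmitted_parental", sample_id="F00001-F"),
            make_variant(pos=4, gene="G0002", consequence="synonymous", metasvm=None, origin="unphased", sample_id="S00001-P"),
            make_variant(pos=5, gene="G0002", consequence="missense", metasvm="T", origin="de_novo"),
            make_variant(pos=6, gene="G0002", consequence="frameshift", metasvm=None, origin="transmitted"),
        ]
        df = classify_frame(variant_frame(rows))
        counts, _ = aggregate_counts(df, ["G0001", "G0002"])
        tally = {}
        for r in rows:
            from chdburden.filters import classify_variant as cv

            key = (r["gene"], cv(r["consequence"], r["metasvm"]))
            d = tally.setdefault(key, {"n_dnm": 0, "case_ac": 0, "T": 0, "U": 0})
            if r["origin"] == "de_novo":
                d["n_dnm"] += 1
                d["case_ac"] += 1
            elif r["origin"] == "transmitted":
                d["T"] += 1
                d["case_ac"] += 1
            elif r["origin"] == "untransmitted_parental":
                d["U"] += 1
            else:
                d["case_ac"] += 1
        for (gene, fclass), exp in tally.items():
            row = counts[(counts.gene == gene) & (counts.fclass == fclass)].iloc[0]
            for k, v in exp.items():
                assert row[k] == v, (gene, fclass, k)

    def test_totals_conserve_records(self, medium_cohort, loose_thresholds):
        df = classify_frame(medium_cohort.variants.drop(columns=["fclass"]))
        kept = filter_very_rare(df, loose_thresholds)
        genes = medium_cohort.truth["gene"].tolist()
        counts, rejects = aggregate_counts(kept, genes)
        n_dedup = len(kept.drop_duplicates(["chrom", "pos", "ref", "alt", "sample_id"]))
        assert counts["case_ac"].sum() + counts["U"].sum() == n_dedup - len(rejects)
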