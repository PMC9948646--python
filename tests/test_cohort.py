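"""Cohort statistics: binning, odds ratios, tests, summaries, silhouettes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import silhouette_samples

from gramscreen import (
    ContingencyTable,
    DrugRecord,
    bin_drugs,
    bonferroni,
    box_summary,
    collapse_to_alogp,
    mann_whitney,
    odds_ratio,
    probability_curve,
    quadrant_table,
    r_squared,
    silhouette,
    supplementary_checks,
)


def rec(nr=1.0, cc20=40.0, alogp=2.0, psa=50.0, qed=0.6, pscore=10.0, i=0):
    return DrugRecord(id=f"d{i}", alogp=alogp, psa=psa, qed=qed,
                      pscore=pscore, normrate=nr, cc20=cc20)


class TestBinning:
    def test_normrate_edges_half_open(self):
        records = [rec(nr=v, i=i) for i, v in enumerate([1.0, 1.25, 1.5, 2.0])]
        groups, _ = bin_drugs(records, "normrate")
        assert [len(g) for g in groups.values()] == [1, 1, 2]
        assert records[1] in groups["[1.25, 1.5)"]

    def test_cc20_boundary_is_nontoxic(self):
        records = [rec(cc20=v, i=i) for i, v in enumerate([5.0, 10.0, 50.0])]
        groups, _ = bin_drugs(records, "cc20")
        assert records[2] in groups["[50, inf)"]
        assert records[1] in groups["[10, 50)"]

    def test_missing_cc20_excluded_and_counted(self):
        records = [rec(i=i) for i in range(5)]
        records += [rec(cc20=None, i=9)]
        groups, excluded = bin_drugs(records, "cc20")
        assert sum(len(g) for g in groups.values()) == 5
        assert len(excluded) == 1

    def test_unknown_axis(self):
        with pytest.raises(ValueError):
            bin_drugs([rec()], "molecular_weight")

    def test_quadrants_threshold_inclusive_low(self):
        records = [rec(alogp=3.0, psa=75.0, i=0), rec(alogp=3.1, psa=76.0, i=1)]
        groups, _ = bin_drugs(records, "alogp_psa_quadrant")
        assert records[0] in groups["low_alogp_low_psa"]
        assert records[1] in groups["high_alogp_high_psa"]


class TestOddsRatio:
    def test_published_headline_table(self):
        """The published quadrant counts give OR 10.8, Woolf CI (4.1, 28.2)."""
        r = odds_ratio(ContingencyTable(58, 34, 6, 38))
        assert r.oratio == pytest.approx(10.80, abs=0.005)
        assert r.ci_low == pytest.approx(4.14, abs=0.01)
        assert r.ci_high == pytest.approx(28.19, abs=0.05)
        assert r.odds_exposed == pytest.approx(1.71, abs=0.005)
        assert r.odds_unexposed == pytest.approx(0.16, abs=0.005)

    def test_published_cytotoxicity_table(self):
        r = odds_ratio(ContingencyTable(69, 21, 25, 19))
        assert r.oratio == pytest.approx(2.50, abs=0.005)

    def test_symmetric_table_is_null(self):
        r = odds_ratio(ContingencyTable(7, 7, 7, 7))
        assert r.oratio == 1.0
        assert r.ci_low < 1.0 < r.ci_high

    def test_zero_cell_flags(self):
        r = odds_ratio(ContingencyTable(5, 0, 3, 4))
        assert math.isinf(r.oratio)
        assert "infinite_or" in r.flags and "ci_undefined" in r.flags

    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force(self, cells):
        """OR matches (a*d)/(b*c) and the point estimate lies in its CI."""
        a, b, c, d = cells
        r = odds_ratio(ContingencyTable(a, b, c, d))
        assert r.oratio == pytest.approx((a * d) / (b * c), rel=1e-12)
        assert r.ci_low <= r.oratio <= r.ci_high

    def test_ci_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        t = sm.stats.Table2x2(np.array([[58, 34], [6, 38]]))
        r = odds_ratio(ContingencyTable(58, 34, 6, 38))
        lo, hi = t.oddsratio_confint(0.05)
        assert r.ci_low == pytest.approx(lo, rel=1e-6)
        assert r.ci_high == pytest.approx(hi, rel=1e-6)


class TestQuadrantPipeline:
    def test_published_odds_reconstruction(self):
        """All four per-quadrant odds of the published bilayer-activity
        table are reproduced from per-drug records, and counts conserve."""
        # rebuild a library matching the printed quadrant counts
        spec = {  # quadrant -> (n_active, n_inactive)
            ("low", "low"): (6, 38), ("low", "high"): (32, 61),
            ("high", "low"): (99, 72), ("high", "high"): (58, 34),
        }
        records, i = [], 0
        for (a_lvl, p_lvl), (n_act, n_inact) in spec.items():
            alogp = 2.0 if a_lvl == "low" else 4.0
            psa = 50.0 if p_lvl == "low" else 90.0
            for nr, n in ((1.5, n_act), (1.0, n_inact)):
                records += [rec(nr=nr, alogp=alogp, psa=psa, i=i + j)
                            for j in range(n)]
                i += n
        assert len(records) == 400
        table = quadrant_table(records, lambda r: r.normrate >= 1.25)
        assert (table.a, table.b, table.c, table.d) == (58, 34, 6, 38)
        # per-quadrant odds as printed
        from gramscreen import quadrant_groups
        odds = {}
        for name, grp in quadrant_groups(records).items():
            n_act = sum(r.normrate >= 1.25 for r in grp)
            odds[name] = n_act / (len(grp) - n_act)
        assert odds["low_alogp_low_psa"] == pytest.approx(0.16, abs=0.005)
        assert odds["low_alogp_high_psa"] == pytest.approx(0.52, abs=0.005)
        assert odds["high_alogp_low_psa"] == pytest.approx(1.38, abs=0.005)
        assert odds["high_alogp_high_psa"] == pytest.approx(1.71, abs=0.005)

    def test_alogp_marginal_collapse(self):
        # published bottom-table cytotoxicity counts collapsed over PSA
        cells = {"low_alogp_low_psa": (25, 19), "low_alogp_high_psa": (59, 34),
                 "high_alogp_low_psa": (129, 41), "high_alogp_high_psa": (69, 21)}
        t = collapse_to_alogp(cells)
        assert (t.a, t.b, t.c, t.d) == (198, 62, 84, 53)
        assert odds_ratio(t).oratio == pytest.approx(2.0, abs=0.02)


class TestProbabilityCurve:
    def test_overall_fraction_from_published_counts(self):
        """282 of 397 drugs with CC20 information fall below 50 µM."""
        records, i = [], 0
        for n_tox, n_non in ((25, 19), (59, 34), (129, 41), (69, 21)):
            records += [rec(cc20=20.0, i=(i := i + 1)) for _ in range(n_tox)]
            records += [rec(cc20=70.0, i=(i := i + 1)) for _ in range(n_non)]
        groups = {"all": records}
        _, overall = probability_curve(groups, lambda r: r.cc20 < 50)
        assert overall == pytest.approx(282 / 397, rel=1e-9)
        assert overall == pytest.approx(0.71, abs=0.005)

    def test_all_events_true(self):
        groups, _ = bin_drugs([rec(nr=v, cc20=10.0, i=i)
                               for i, v in enumerate([1.0, 1.3, 1.6])],
                              "normrate")
        per_bin, overall = probability_curve(groups, lambda r: r.cc20 < 50)
        assert overall == 1.0
        assert all(p == 1.0 for p in per_bin.values())

    def test_empty_bin_reported_missing(self):
        groups, _ = bin_drugs([rec(nr=1.0)], "normrate")
        per_bin, _ = probability_curve(groups, lambda r: r.cc20 < 50)
        assert per_bin["[1.5, inf)"] is None


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(2 / 6, rel=1e-12)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.pvalue == 1.0

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(0.5, size=6)
            ours = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_shifted_samples_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 60)
        y = rng.normal(1.2, 1, 60)
        res = mann_whitney(x, y)
        assert res.method == "asymptotic"
        assert res.pvalue < 1e-3
        # tie-free normal-approximation tail formula as independent check
        u = res.statistic
        n1, n2 = 60, 60
        z = (u - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert res.pvalue == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-6)

    def test_bonferroni(self):
        assert bonferroni([0.01, 0.4], 3) == [0.03, 1.0]
        assert bonferroni([0.02, 0.03]) == [0.04, 0.06]


class TestBoxSummary:
    def test_interpolated_quartiles(self):
        s = box_summary(np.arange(1, 101))
        assert s.q1 == pytest.approx(25.75)
        assert s.q3 == pytest.approx(75.25)
        assert s.outliers == ()
        assert (s.whisker_low, s.whisker_high) == (1.0, 100.0)

    def test_single_value(self):
        s = box_summary([4.2])
        assert s.q1 == s.median == s.q3 == 4.2
        assert s.whisker_low == s.whisker_high == 4.2

    def test_outlier_flagged_and_whisker_snapped(self):
        s = box_summary([1, 2, 3, 4, 100])
        assert s.outliers == (100.0,)
        assert s.whisker_high == 4.0


class TestSilhouette:
    def test_tight_distant_clusters(self):
        pts = np.array([[0, 0], [0, 0.1], [10, 10], [10, 10.1]])
        res = silhouette(pts, [0, 0, 1, 1], standardize=False)
        assert res.overall > 0.95

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(120, 2))
        res = silhouette(pts, rng.integers(0, 2, 120))
        assert abs(res.overall) < 0.1

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(2, 1, (30, 3))])
        labels = np.array([0] * 25 + [1] * 30)
        ours = silhouette(pts, labels, standardize=False)
        ref = silhouette_samples(pts, labels, metric="euclidean")
        np.testing.assert_allclose(ours.scores, ref, rtol=1e-10)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [1.0], [2.0], [9.0]])
        res = silhouette(pts, [0, 0, 0, 1], standardize=False)
        assert res.scores[3] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 2)), [0, 0, 0, 0])


class TestRSquared:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)
        assert r_squared(x, -x) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(5)
        assert r_squared(rng.normal(size=3000), rng.normal(size=3000)) < 0.01

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(r_squared([1, 1, 1], [1, 2, 3]))


class TestSupplementaryChecks:
    def test_runs_on_synthetic_library(self):
        from gramscreen import simulate_drug_library

        drugs = simulate_drug_library(400, seed=0)
        records = [DrugRecord(id=d.id, alogp=d.alogp, psa=d.psa, qed=d.qed,
                              pscore=d.pscore, normrate=d.normrate,
                              cc20=d.cc20) for d in drugs]
        out = supplementary_checks(records)
        assert 0 <= out["pct_cc20_lt50_high_potency"] <= 100
        assert 0 <= out["pct_cc20_lt50_potent_low_qed"] <= 100
        # potent drugs are likelier cytotoxic than the library average
        _, overall = probability_curve({"all": records},
                                       lambda r: r.cc20 < 50)
        assert out["pct_cc20_lt50_high_potency"] > 100 * overall
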