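"""Concordance, Spearman correlation, KM/log-rank and cohort summaries."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from psmaquant import (
    SurvivalRecord,
    assess_cohort,
    concordance,
    correlation_screen,
    km_fit,
    logrank,
    pearson,
    spearman,
    summarize_cohort,
)


def brute_force_spearman(x, y):
    """Independent oracle: average-rank both columns, Pearson on the ranks."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks
    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestConcordance:
    def test_fixture_tlp_vs_mtv_is_total(self, fixture_cohort):
        records, _ = fixture_cohort
        calls = assess_cohort(records).calls
        res = concordance([c.tlp_response for c in calls], [c.mtv_response for c in calls])
        assert (res.n_agree, res.n_total) == (17, 17)
        assert res.fraction == 1.0

    def test_fixture_imaging_vs_psa(self, fixture_cohort):
        records, _ = fixture_cohort
        calls = assess_cohort(records).calls
        res = concordance([c.tlp_response for c in calls], [c.psa_response for c in calls])
        assert (res.n_agree, res.n_total) == (12, 17)
        assert res.fraction == pytest.approx(12 / 17)

    def test_self_concordance_is_one(self):
        res = concordance(["PR", "SD", "PD", "SD"], ["PR", "SD", "PD", "SD"])
        assert res.fraction == 1.0

    def test_cross_table_structure(self, fixture_cohort):
        records, _ = fixture_cohort
        result = assess_cohort(records)
        calls = result.calls
        res = concordance([c.tlp_response for c in calls], [c.psa_response for c in calls])
        table = res.cross_table
        assert int(table.values.sum()) == res.n_total
        assert int(np.trace(table.values)) == res.n_agree
        # marginals equal the per-method frequency tables
        assert list(table.sum(axis=1)) == list(result.frequencies["tlp_n"])
        assert list(table.sum(axis=0)) == list(result.frequencies["psa_n"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance(["PR"], ["PR", "SD"])


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self, rng):
        x = rng.uniform(0, 100, 20)
        assert spearman(x, np.exp(x / 30.0)).r == pytest.approx(1.0)
        assert spearman(x, -np.sqrt(x + 1)).r == pytest.approx(-1.0)

    def test_fixture_baselines_match_brute_force_oracle(self, fixture_cohort):
        records, _ = fixture_cohort
        tlp = [r.tlp_pre for r in records]
        for other in ([r.mtv_pre for r in records], [r.psa_pre for r in records]):
            assert spearman(tlp, other).r == pytest.approx(brute_force_spearman(tlp, other), abs=1e-12)

    def test_ties_handled_with_average_ranks(self):
        x = [1, 2, 2, 3, 4, 4, 4, 5]
        y = [3, 1, 4, 4, 6, 6, 7, 9]
        assert spearman(x, y).r == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_rank_invariance(self, rng):
        x = rng.uniform(0, 10, 15)
        y = rng.uniform(0, 10, 15)
        assert spearman(x, y).r == pytest.approx(
            spearman(sps.rankdata(x), sps.rankdata(y)).r, abs=1e-12)

    def test_constant_vector_reported_undefined(self):
        res = spearman([1.0] * 5, [1, 2, 3, 4, 5])
        assert not res.defined and math.isnan(res.p)

    def test_exact_permutation_p_small_n(self):
        # n=4, perfect monotone: only 2 of 4! = 24 pairings reach |r| = 1
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(2 / 24)

    def test_large_n_p_matches_t_approximation(self, rng):
        x = rng.uniform(0, 1, 30)
        y = x + rng.uniform(0, 1, 30)
        assert spearman(x, y).p == pytest.approx(float(sps.spearmanr(x, y).pvalue))

    def test_pearson_reported_alongside(self, fixture_cohort):
        records, _ = fixture_cohort
        res = pearson([r.tlp_pre for r in records], [r.mtv_pre for r in records])
        assert res.r > 0.9  # burden measures are strongly linearly related


class TestCorrelationScreen:
    def test_identical_covariate_has_unit_correlation(self, rng):
        d = rng.uniform(-50, 50, 17)
        out = correlation_screen({"cov": d}, {"delta_tlp": d})
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_pairwise_complete_n(self, rng):
        cov = rng.uniform(0, 10, 17)
        cov[3] = cov[8] = cov[11] = cov[15] = np.nan  # 13/17 complete
        out = correlation_screen({"pfs": cov}, {"delta_tlp": rng.uniform(-50, 50, 17)})
        assert int(out.loc[0, "n"]) == 13

    def test_too_few_pairs_undefined(self, rng):
        cov = np.full(17, np.nan)
        cov[:2] = [1.0, 2.0]
        out = correlation_screen({"cov": cov}, {"d": rng.uniform(-50, 50, 17)})
        assert math.isnan(out.loc[0, "r"]) and int(out.loc[0, "n"]) == 2

    def test_null_covariates_control_type_one_error(self, rng):
        # independent covariates at n = 17: ~5% of raw p-values below 0.05
        n_cells, n_sig, r_sum = 0, 0, 0.0
        for _ in range(400):
            out = correlation_screen({"c": rng.normal(size=17)}, {"d": rng.normal(size=17)})
            n_cells += 1
            n_sig += int(out.loc[0, "p"] < 0.05)
            r_sum += out.loc[0, "r"]
        assert n_sig / n_cells == pytest.approx(0.05, abs=0.03)
        assert abs(r_sum / n_cells) < 0.05


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        est = km_fit([SurvivalRecord(time=t, event=True) for t in (1, 2, 3, 4, 5)])
        for t, s in [(1, 0.8), (2, 0.6), (3, 0.4), (4, 0.2), (5, 0.0)]:
            assert est.survival_at(t) == pytest.approx(s)
        assert est.median == pytest.approx(3.0)

    def test_all_censored_median_not_reached(self):
        est = km_fit([SurvivalRecord(time=t, event=False) for t in (5, 10, 15)])
        assert est.median is None and not est.median_reached

    def test_hand_computed_product_limit_with_censoring(self):
        # times (event): 2(d), 4(c), 5(d), 7(d), 8(c), 10(d)
        # S(2) = 5/6; S(5) = 5/6 * 3/4 = 0.625; S(7) = 0.625 * 2/3 = 0.41667;
        # S(10) = 0.41667 * 0 = 0
        records = [SurvivalRecord(2, True), SurvivalRecord(4, False),
                   SurvivalRecord(5, True), SurvivalRecord(7, True),
                   SurvivalRecord(8, False), SurvivalRecord(10, True)]
        est = km_fit(records)
        assert est.survival_at(2) == pytest.approx(5 / 6)
        assert est.survival_at(5) == pytest.approx(5 / 8)
        assert est.survival_at(7) == pytest.approx(5 / 12)
        assert est.survival_at(10) == pytest.approx(0.0)
        assert est.median == pytest.approx(7.0)  # earliest t with S <= 0.5

    def test_median_recovers_exponential_closed_form(self, rng):
        lam = 0.08
        times = rng.exponential(1.0 / lam, size=500)
        est = km_fit([SurvivalRecord(time=t, event=True) for t in times])
        assert est.median == pytest.approx(math.log(2) / lam, rel=0.15)
        lo, hi = est.median_ci
        assert lo is not None and hi is not None and lo < est.median < hi

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord(time=-1.0, event=True)


class TestLogrank:
    def test_identical_groups_null(self):
        g = [SurvivalRecord(t, True) for t in (1, 3, 5, 8, 13)]
        res = logrank(g, list(g))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_symmetric_in_group_order(self, rng):
        a = [SurvivalRecord(t, bool(e)) for t, e in
             zip(rng.exponential(10, 30), rng.integers(0, 2, 30))]
        b = [SurvivalRecord(t, bool(e)) for t, e in
             zip(rng.exponential(5, 30), rng.integers(0, 2, 30))]
        assert logrank(a, b).statistic == pytest.approx(logrank(b, a).statistic)

    def test_no_events_undefined(self):
        a = [SurvivalRecord(5, False)]
        b = [SurvivalRecord(7, False)]
        res = logrank(a, b)
        assert not res.defined

    def test_type_one_error_near_nominal(self, rng):
        # equal hazards: rejection rate ~5% at alpha = 0.05
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            a = [SurvivalRecord(t, True) for t in rng.exponential(10, 25)]
            b = [SurvivalRecord(t, True) for t in rng.exponential(10, 25)]
            rejections += int(logrank(a, b).p < 0.05)
        assert rejections / n_rep == pytest.approx(0.05, abs=0.035)


class TestSummaries:
    def test_fixture_medians_and_ranges(self, fixture_cohort):
        records, _ = fixture_cohort
        table = summarize_cohort(records).set_index(["variable", "timepoint"])
        assert table.loc[("tlp", "pre"), "median"] == pytest.approx(3685)
        assert table.loc[("tlp", "pre"), "min"] == pytest.approx(723)
        assert table.loc[("tlp", "pre"), "max"] == pytest.approx(13679)
        assert table.loc[("psa", "pre"), "median"] == pytest.approx(152)
        assert table.loc[("tlp", "post"), "median"] == pytest.approx(2289)

    def test_single_record_degenerates_to_its_values(self):
        from psmaquant import PatientRecord
        rec = PatientRecord(patient_id="p", tlp_pre=5, tlp_post=4,
                            mtv_pre=3, mtv_post=2, psa_pre=1, psa_post=1)
        table = summarize_cohort([rec]).set_index(["variable", "timepoint"])
        row = table.loc[("tlp", "pre")]
        assert row["median"] == row["min"] == row["max"] == 5
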