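"""Design-based estimation: point estimates, paired-selection variance,
stratified weighting, confidence limits, threshold decisions."""

import numpy as np
import pytest

from ceskit.estimation import (
    CoverageSurvey,
    UndefinedEstimateError,
    confidence_limits,
    kish_paired_variance,
    point_estimate,
    stratified_estimate,
)
from ceskit.frame import FrameConfig, generate_frame, true_coverage
from ceskit.samplers import (
    RESPONSE_NO,
    RESPONSE_NOT_SURE,
    RESPONSE_YES,
    pss_survey,
    slqas_survey,
)


def _responses(n_yes, n_no, n_not_sure=0):
    return np.array(
        [RESPONSE_YES] * n_yes + [RESPONSE_NO] * n_no
        + [RESPONSE_NOT_SURE] * n_not_sure,
        dtype=np.int8,
    )


class TestPointEstimate:
    @pytest.mark.parametrize(
        "n_valid,n_yes,pct",
        [
            (1783, 1477, 83),   # Batie PSS, albendazole + ivermectin
            (473, 249, 53),     # Gracias EPI, albendazole
            (1851, 1359, 73),   # Machinga EPI
            (444, 258, 58),     # San Juan PSS
            (1581, 1212, 77),   # Zomba PSS
            (1198, 316, 26),    # Amuru PSS, praziquantel
        ],
    )
    def test_whole_percent_estimates_from_counts(self, n_valid, n_yes, pct):
        resp = _responses(n_yes, n_valid - n_yes, n_not_sure=37)
        nv, nt, p = point_estimate(resp)
        assert (nv, nt) == (n_valid, n_yes)
        assert round(100 * p) == pct

    def test_not_sure_excluded_from_both_sides(self):
        nv, nt, p = point_estimate(_responses(6, 2, 4))
        assert (nv, nt, p) == (8, 6, 0.75)

    def test_all_not_sure_is_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            point_estimate(_responses(0, 0, 5))


class TestKishPairedVariance:
    def test_hand_computed_four_cluster_example(self):
        # r = 28/40 = 0.7; deviations (1,-1,2,-2); v = (4+16)/1600
        se, deff, v = kish_paired_variance([8, 6, 9, 5], [10, 10, 10, 10])
        assert v == pytest.approx(0.0125, abs=1e-12)
        assert se == pytest.approx(np.sqrt(0.0125), abs=1e-12)
        assert deff == pytest.approx(0.0125 / (0.7 * 0.3 / 40), abs=1e-9)

    def test_identical_clusters_give_zero_variance(self):
        se, deff, v = kish_paired_variance([7, 7, 7, 7], [10, 10, 10, 10])
        assert v == 0.0 and se == 0.0

    def test_odd_cluster_count_collapses_final_triple(self):
        # independent recomputation of the collapsed-stratum formula
        y = np.array([8.0, 6.0, 9.0, 5.0, 7.0])
        x = np.full(5, 10.0)
        r = y.sum() / x.sum()
        z = y - r * x
        expected = 1.5 * ((z[2:] - z[2:].mean()) ** 2).sum() + (z[0] - z[1]) ** 2
        expected /= x.sum() ** 2
        se, _, v = kish_paired_variance(y, x)
        assert v == pytest.approx(expected, abs=1e-12)

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError):
            kish_paired_variance([5.0], [10.0])

    def test_tracks_empirical_variance_across_frames(self):
        # pooled over frames, the mean estimated variance matches the
        # empirical sampling variance of the PSS estimate
        from ceskit.design import sampling_fraction

        v_means, emp_vars = [], []
        for fs in range(12):
            cfg = FrameConfig(n_psus=250, coverage_icc=0.1, mean_coverage=0.7,
                              seed=400 + fs)
            fr = generate_frame(cfg)
            f = sampling_fraction(600, 30, float(fr.hh_size.mean()), 50, 0.0)
            rng = np.random.default_rng(800 + fs)
            ph, vv = [], []
            for _ in range(60):
                present, proxy = fr.redraw_presence(rng)
                s = pss_survey(fr, f=f, seed=int(rng.integers(2**31)),
                               present=present, proxy_available=proxy)
                est = CoverageSurvey(s).fit()["alb"]
                ph.append(est.p_hat)
                vv.append(est.se**2)
            v_means.append(np.mean(vv))
            emp_vars.append(np.var(ph, ddof=1))
        ratio = np.mean(v_means) / np.mean(emp_vars)
        assert 0.8 < ratio < 1.25


class TestStratifiedEstimate:
    def test_equal_strata_reduce_to_common_value(self):
        p, se = stratified_estimate([0.6, 0.6, 0.6], [19, 19, 19],
                                    [1 / 3, 1 / 3, 1 / 3])
        assert p == pytest.approx(0.6)

    def test_degenerate_within_stratum_variance(self):
        p, se = stratified_estimate([1.0, 0.0], [19, 19], [0.5, 0.5])
        assert p == 0.5 and se == 0.0

    def test_hand_computed_two_stratum_example(self):
        p, se = stratified_estimate([0.8, 0.5], [19, 19], [0.6, 0.4])
        v = 0.36 * (0.16 / 18) + 0.16 * (0.25 / 18)
        assert p == pytest.approx(0.68, abs=1e-12)
        assert se == pytest.approx(np.sqrt(v), abs=1e-9)
        assert se == pytest.approx(0.07363, abs=1e-4)

    def test_single_stratum_degrades_to_srs(self):
        p, se = stratified_estimate([0.7], [50], [1.0])
        assert p == 0.7
        assert se**2 == pytest.approx(0.7 * 0.3 / 49, abs=1e-12)

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            stratified_estimate([0.5, 0.5], [19, 1], [0.5, 0.5])


class TestConfidenceLimits:
    def test_zero_se_collapses_to_point(self):
        assert confidence_limits(0.42, 0.0) == (0.42, 0.42, 0.42)

    def test_wald_arithmetic(self):
        lo, hi, l1 = confidence_limits(0.7, 0.05, 0.95)
        assert lo == pytest.approx(0.7 - 1.959964 * 0.05, abs=1e-5)
        assert hi == pytest.approx(0.7 + 1.959964 * 0.05, abs=1e-5)
        assert l1 == pytest.approx(0.7 - 1.644854 * 0.05, abs=1e-5)

    def test_truncation_at_zero(self):
        lo, hi, l1 = confidence_limits(0.02, 0.05)
        assert lo == 0.0 and l1 == 0.0 and hi < 1.0


class TestDecisions:
    def _fit(self, sample_frame, **fit_kwargs):
        s = pss_survey(sample_frame, f=0.3, seed=30)
        return CoverageSurvey(s).fit(**fit_kwargs)["alb"]

    def test_threshold_on_rounded_point_estimate(self, grid_frame):
        est = self._fit(grid_frame, threshold=0.65)
        assert est.threshold_met == (est.percent >= 65)
        assert est.lower_cl_meets_threshold == (est.lower_cl1 >= 0.65)

    def test_reported_at_ci_endpoint_validates(self, grid_frame):
        est = self._fit(grid_frame)
        for endpoint in est.ci2:
            est2 = self._fit(grid_frame, reported=endpoint)
            assert est2.reported_validated
        inside = (est.ci2[0] + est.ci2[1]) / 2
        assert self._fit(grid_frame, reported=inside).reported_validated
        assert not self._fit(grid_frame, reported=est.ci2[1] + 0.01).reported_validated


class TestCoverageSurveyModel:
    def test_dataframe_roundtrip_matches_sample_fit(self, grid_frame):
        s = pss_survey(grid_frame, f=0.3, seed=31)
        direct = CoverageSurvey(s).fit()["alb"]
        via_df = CoverageSurvey.from_dataframe(s.records, design="pss").fit()["alb"]
        assert via_df.p_hat == pytest.approx(direct.p_hat, abs=1e-12)
        assert via_df.se == pytest.approx(direct.se, abs=1e-12)
        assert via_df.deff == pytest.approx(direct.deff, abs=1e-12)

    def test_slqas_requires_weights(self, default_frame):
        s = slqas_survey(default_frame, seed=32)
        with pytest.raises(ValueError, match="stratum_weights"):
            CoverageSurvey(s)

    def test_summary_contains_key_figures(self, default_frame):
        s = slqas_survey(default_frame, seed=33)
        res = CoverageSurvey(s, stratum_weights=default_frame.sa_populations()).fit(
            threshold=0.65, reported=0.8
        )
        text = res.summary()
        est = res["alb"]
        assert str(est.percent) in text
        assert "slqas" in text

    def test_ci_nominal_coverage_under_pss(self):
        # two-sided 95% CIs should cover census truth ~95% of the time,
        # pooled across frames to average out frame-conditional effects
        from ceskit.design import sampling_fraction

        hits = []
        for fs in range(10):
            cfg = FrameConfig(n_psus=250, coverage_icc=0.1, mean_coverage=0.7,
                              seed=500 + fs)
            fr = generate_frame(cfg)
            truth = true_coverage(fr, "alb")
            f = sampling_fraction(600, 30, float(fr.hh_size.mean()), 50, 0.0)
            rng = np.random.default_rng(900 + fs)
            for _ in range(100):
                present, proxy = fr.redraw_presence(rng)
                s = pss_survey(fr, f=f, seed=int(rng.integers(2**31)),
                               present=present, proxy_available=proxy)
                est = CoverageSurvey(s).fit()["alb"]
                hits.append(est.ci2[0] <= truth <= est.ci2[1])
        assert np.mean(hits) == pytest.approx(0.95, abs=0.02)

    def test_deff_matches_kish_approximation_for_constant_take(self):
        # equal one-segment PSUs with f=1: every cluster takes the whole
        # PSU of m individuals; DEFF should approach 1 + (m-1) * ICC
        from conftest import make_grid_frame

        rho = 0.1
        m = 10 * 4  # 10 households of 4
        deffs = []
        for fs in range(8):
            fr = make_grid_frame(n_psus=120, hh_per_psu=10, hh_size=4,
                                 coverage_icc=rho, seed=600 + fs)
            rng = np.random.default_rng(700 + fs)
            for _ in range(250):
                s = pss_survey(fr, f=1.0, seed=int(rng.integers(2**31)))
                deffs.append(CoverageSurvey(s).fit()["alb"].deff)
        expected = 1 + (m - 1) * rho
        assert np.nanmean(deffs) == pytest.approx(expected, rel=0.25)
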