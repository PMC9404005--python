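"""Retention factors, DP-RTC, and LSS extrapolation to 100% aqueous phase."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromlogd.errors import (
    FitQualityWarning,
    LowPointCountWarning,
    RetentionDomainError,
    SingularDesignError,
)
from chromlogd.retention import (
    Mode,
    RetentionMeasurement,
    average_replicates,
    dp_rtc_correct,
    fit_lss,
    read_retention_table,
    retention_factor,
)


def _line_measurements(log_kw, s, phis, t_0=1.0, cid="X1", mode=Mode.IS):
    return [
        RetentionMeasurement(cid, mode, phi, t_0 * (1 + 10 ** (log_kw - s * phi)), t_0)
        for phi in phis
    ]


def _lss_oracle(phis, logk):
    """Closed-form simple-regression formulas, independent of fit_lss."""
    x, y = np.asarray(phis), np.asarray(logk)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    se_intercept = math.sqrt(
        np.sum(resid**2) / (n - 2) * (1 / n + x.mean() ** 2 / sxx)
    ) if n > 2 else float("nan")
    return intercept, slope, se_intercept


class TestRetentionFactor:
    @pytest.mark.parametrize(
        "t_r, t_0, expected",
        [(5.0, 1.0, 4.0), (1.0, 1.0, 0.0), (2.5, 1.25, 1.0)],
    )
    def test_standard_definition(self, t_r, t_0, expected):
        assert retention_factor(t_r, t_0) == pytest.approx(expected, abs=1e-15)

    def test_as_printed_denominator_switch(self):
        assert retention_factor(5.0, 1.0, denominator="tr") == pytest.approx(0.8)

    def test_unretained_solute_rejected(self):
        with pytest.raises(RetentionDomainError, match="unretained"):
            retention_factor(0.9, 1.0)

    def test_nonpositive_dead_time_rejected(self):
        with pytest.raises(RetentionDomainError):
            retention_factor(5.0, 0.0)


class TestDpRtc:
    @pytest.mark.parametrize(
        "obs, nom, t, expected",
        [
            ((2, 10), (2, 10), 5, 5),    # identity map
            ((2, 10), (3, 11), 5, 6),    # pure shift
            ((2, 10), (4, 20), 5, 10),   # pure scale
        ],
    )
    def test_reference_cases(self, obs, nom, t, expected):
        assert dp_rtc_correct(t, obs, nom) == pytest.approx(expected, abs=1e-12)

    def test_anchors_reproduced_exactly(self):
        obs, nom = (2.37, 9.81), (2.50, 10.00)
        assert dp_rtc_correct(obs[0], obs, nom) == pytest.approx(nom[0], abs=1e-12)
        assert dp_rtc_correct(obs[1], obs, nom) == pytest.approx(nom[1], abs=1e-12)

    def test_coincident_anchors_rejected(self):
        with pytest.raises(SingularDesignError):
            dp_rtc_correct(5.0, (3.0, 3.0), (2.0, 4.0))

    @settings(derandomize=True, max_examples=100)
    @given(
        o1=st.floats(0.5, 5), o2=st.floats(6, 30),
        n1=st.floats(0.5, 5), n2=st.floats(6, 30),
        t=st.floats(0.1, 40),
    )
    def test_composition_with_inverse_is_identity(self, o1, o2, n1, n2, t):
        forward = dp_rtc_correct(t, (o1, o2), (n1, n2))
        back = dp_rtc_correct(forward, (n1, n2), (o1, o2))
        assert back == pytest.approx(t, abs=1e-12 * max(1.0, abs(t)))


class TestFitLss:
    def test_noiseless_line_recovered_exactly(self):
        fit = fit_lss(_line_measurements(2.0, 3.0, [0.1, 0.2, 0.3, 0.4]))
        assert fit.log_kw == pytest.approx(2.0, abs=1e-12)
        assert fit.s == pytest.approx(3.0, abs=1e-12)
        assert fit.r2 == 1.0
        assert fit.n_points == 4

    def test_two_points_saturated_fit_warns(self):
        with pytest.warns(LowPointCountWarning):
            fit = fit_lss(_line_measurements(1.5, 2.0, [0.2, 0.5]))
        assert fit.r2 == 1.0  # saturated-fit convention
        assert fit.log_kw == pytest.approx(1.5, abs=1e-10)

    def test_noisy_fit_below_gate_warns(self):
        deviations = (0.1, -0.1, 0.1, -0.1, 0.1, -0.1)  # gross scatter on log k
        ms = [
            RetentionMeasurement(
                "X1", Mode.IS, phi, 1 + 10 ** (1.0 - 2.0 * phi + eps), 1.0
            )
            for phi, eps in zip((0.1, 0.2, 0.3, 0.4, 0.5, 0.6), deviations)
        ]
        with pytest.warns(FitQualityWarning):
            fit_lss(ms, r2_gate=0.99)

    def test_seeded_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(1)
        true_kw, true_s, t_0 = 1.5, 2.5, 1.0
        phis = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        ms = [
            RetentionMeasurement(
                "X1", Mode.IS, phi,
                t_0 * (1 + 10 ** (true_kw - true_s * phi)) + rng.normal(0, 0.01),
                t_0,
            )
            for phi in phis
        ]
        fit = fit_lss(ms, r2_gate=0.0)
        logk = [np.log10((m.t_r - m.t_0) / m.t_0) for m in ms]
        _, _, se_int = _lss_oracle(phis, logk)
        assert abs(fit.log_kw - true_kw) < 3 * se_int

    def test_mixed_compounds_rejected(self):
        ms = _line_measurements(2, 3, [0.1, 0.2]) + _line_measurements(
            2, 3, [0.3, 0.4], cid="X2"
        )
        with pytest.raises(ValueError, match="one compound"):
            fit_lss(ms)

    def test_dead_time_solute_rejected(self):
        ms = _line_measurements(2.0, 3.0, [0.1, 0.2, 0.3]) + [
            RetentionMeasurement("X1", Mode.IS, 0.8, 1.0, 1.0)  # k = 0
        ]
        with pytest.raises(RetentionDomainError, match="X1"):
            fit_lss(ms)

    def test_single_phi_level_rejected(self):
        ms = [
            RetentionMeasurement("X1", Mode.IS, 0.3, 5.0, 1.0),
            RetentionMeasurement("X1", Mode.IS, 0.3, 5.1, 1.0),
        ]
        with pytest.raises(SingularDesignError):
            fit_lss(ms)

    @settings(derandomize=True, max_examples=100)
    @given(
        log_kw=st.floats(0.5, 4), s=st.floats(1, 6),
        noise=st.lists(st.floats(-0.02, 0.02), min_size=5, max_size=5),
    )
    def test_matches_closed_form_oracle(self, log_kw, s, noise):
        phis = [0.1, 0.25, 0.4, 0.55, 0.7]
        ms = [
            RetentionMeasurement(
                "X1", Mode.IP, phi, 1 + 10 ** (log_kw - s * phi + eps), 1.0
            )
            for phi, eps in zip(phis, noise)
        ]
        fit = fit_lss(ms, r2_gate=0.0)
        logk = [np.log10(m.t_r - 1.0) for m in ms]
        intercept, slope, _ = _lss_oracle(phis, logk)
        assert fit.log_kw == pytest.approx(intercept, abs=1e-10)
        assert fit.s == pytest.approx(-slope, abs=1e-10)

    def test_point_on_fitted_line_leaves_fit_unchanged(self):
        rng = np.random.default_rng(3)
        ms = [
            RetentionMeasurement(
                "X1", Mode.IS, phi, 1 + 10 ** (2.0 - 3.0 * phi + rng.normal(0, 0.05)), 1.0
            )
            for phi in (0.1, 0.2, 0.3, 0.4)
        ]
        fit = fit_lss(ms, r2_gate=0.0)
        extra_phi = 0.55
        extra = RetentionMeasurement(
            "X1", Mode.IS, extra_phi,
            1 + 10 ** (fit.log_kw - fit.s * extra_phi), 1.0,
        )
        refit = fit_lss(ms + [extra], r2_gate=0.0)
        assert refit.log_kw == pytest.approx(fit.log_kw, abs=1e-10)
        assert refit.s == pytest.approx(fit.s, abs=1e-10)


class TestReplicatesAndIO:
    def test_replicates_averaged_per_condition(self):
        ms = [
            RetentionMeasurement("X1", Mode.IS, 0.2, t_r, 1.0)
            for t_r in (5.0, 5.2, 5.1)
        ] + [RetentionMeasurement("X1", Mode.IS, 0.3, 4.0, 1.0)]
        avg = average_replicates(ms)
        assert len(avg) == 2
        assert avg[0].t_r == pytest.approx(5.1)
        assert avg[1].t_r == 4.0

    def test_read_retention_table_applies_dp_rtc(self, tmp_path):
        p = tmp_path / "ret.csv"
        p.write_text(
            "compound_id,mode,phi,t_r,t_0,ref1_obs,ref1_nom,ref2_obs,ref2_nom\n"
            "X1,IS,0.3,5.0,1.0,2,4,10,20\n"  # pure scale x2
        )
        (m,) = read_retention_table(p)
        assert m.t_r == pytest.approx(10.0)
        assert m.mode is Mode.IS

    def test_read_retention_table_plain(self, tmp_path):
        p = tmp_path / "ret.csv"
        p.write_text("compound_id,mode,phi,t_r,t_0\nX1,IP,0.3,5.0,1.0\n")
        (m,) = read_retention_table(p)
        assert m.t_r == 5.0 and m.phi == 0.3
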