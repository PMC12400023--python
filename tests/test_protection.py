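import math

import numpy as np
import pytest

from hdrskit.actionspectra import erythema_weights, ppd_weights, ssr_weights
from hdrskit.protection import (
    CalibrationModel,
    VolunteerResult,
    aggregate_panel,
    apply_calibration,
    calibration_factor,
    check_standard_acceptance,
    compute_spf,
    compute_uvapf,
    panel_statistic,
)
from hdrskit.spectral import Spectrum


def _flat(grid, level):
    return Spectrum(grid, np.full_like(grid, float(level)), "absorbance")


class TestActionSpectra:
    def test_erythema_unity_below_298(self, grid):
        w = erythema_weights(grid)
        assert np.all(w[grid <= 298.0] == 1.0)
        assert np.all(w[grid > 298.0] < 1.0)

    def test_all_weights_nonnegative_and_bounded(self, grid):
        for fn in (erythema_weights, ppd_weights, ssr_weights):
            w = fn(grid)
            assert np.all(w > 0) and np.all(w <= 1.0)


class TestProtectionFactors:
    @pytest.mark.parametrize("level,expected", [(0.0, 1.0), (1.0, 10.0), (math.log10(2), 2.0)])
    def test_flat_absorber_closed_forms(self, grid, weighting, level, expected):
        a = _flat(grid, level)
        assert compute_spf(a, weighting) == pytest.approx(expected)
        assert compute_uvapf(a, weighting) == pytest.approx(expected)

    def test_uvapf_ignores_uvb(self, grid, weighting):
        vals = np.where(grid < 320.0, 3.0, 1.0)
        a = Spectrum(grid, vals, "absorbance")
        assert compute_uvapf(a, weighting) == pytest.approx(10.0)

    def test_monotone_in_absorbance(self, grid, weighting, smooth_absorbance):
        a = smooth_absorbance(seed=4)
        bumped = a.with_values(a.values + 0.05)
        assert compute_spf(bumped, weighting) > compute_spf(a, weighting)
        assert compute_uvapf(bumped, weighting) > compute_uvapf(a, weighting)

    def test_negative_absorbance_clipped_at_integration(self, grid, weighting):
        a = Spectrum(grid, np.full_like(grid, -0.04), "absorbance")
        assert compute_spf(a, weighting) == pytest.approx(1.0)

    def test_fine_grid_trapezoid_oracle(self, weighting, smooth_absorbance):
        """1 nm summation agrees with an independent 0.1 nm trapezoidal
        evaluation to better than 2 % for smooth spectra (the residual is
        quadrature discretization error, largest for high-SPF spectra
        whose weighted transmission is sharply peaked)."""
        from hdrskit.actionspectra import erythema_weights, ssr_weights

        for seed in range(5):
            a = smooth_absorbance(seed=seed)
            spf = compute_spf(a, weighting)
            fine = np.arange(290.0, 400.0001, 0.1)
            a_fine = np.interp(fine, a.wavelengths, a.values)
            e, s = erythema_weights(fine), ssr_weights(fine)
            num = np.trapezoid(e * s, fine)
            den = np.trapezoid(e * s * 10.0 ** (-np.maximum(a_fine, 0.0)), fine)
            assert spf == pytest.approx(num / den, rel=2e-2)


class TestCalibration:
    def test_identity_configuration(self):
        cal = CalibrationModel(c_led=1.0, bias_b=0.0)
        for pf in (1.0, 7.3, 60.0):
            assert apply_calibration(pf, cal) == pytest.approx(pf)

    def test_base_case_pf_one(self):
        cal = CalibrationModel(c_led=0.9, bias_b=0.164)
        assert apply_calibration(1.0, cal) == pytest.approx(math.exp(0.164))

    def test_power_law_two_evaluations_agree(self):
        """Direct power-law evaluation matches a log-domain evaluation."""
        cal = CalibrationModel(c_led=0.9174, bias_b=0.164)
        direct = apply_calibration(50.0, cal)
        log_domain = math.exp(0.9174 * math.log(50.0) + 0.164)
        assert direct == pytest.approx(log_domain, rel=1e-12)

    def test_multiplication_factor_consistency(self):
        cal = CalibrationModel(c_led=0.9174, bias_b=0.164)
        pf = 37.0
        assert calibration_factor(pf, cal) * pf == pytest.approx(
            apply_calibration(pf, cal)
        )

    def test_multiplicative_mode(self):
        cal = CalibrationModel(c_led=0.87, bias_b=0.0, mode="multiplicative")
        assert apply_calibration(10.0, cal) == pytest.approx(8.7)

    def test_domain_errors(self):
        cal = CalibrationModel()
        with pytest.raises(ValueError):
            apply_calibration(0.5, cal)
        with pytest.raises(ValueError):
            CalibrationModel(c_led=2.5)


class TestPanelAggregation:
    def test_zero_variance_panel(self):
        stat = panel_statistic([20.0] * 10)
        assert stat.value == pytest.approx(20.0)
        assert stat.c_stat_pct == pytest.approx(0.0)
        assert not stat.flagged

    def test_geometric_mean(self):
        stat = panel_statistic([10.0, 40.0])
        assert stat.value == pytest.approx(20.0)

    def test_order_invariance(self):
        vals = [12.0, 30.0, 22.0, 18.0, 26.0]
        a = panel_statistic(vals)
        b = panel_statistic(vals[::-1])
        assert a.value == b.value and a.c_stat_pct == b.c_stat_pct

    def test_c_stat_against_bootstrap_oracle(self):
        """t-based CI half-width agrees with a bootstrap-t evaluation of
        the mean ln PF within Monte-Carlo error."""
        rng = np.random.default_rng(123)
        ln_vals = rng.normal(math.log(25.0), 0.25, size=10)
        vals = np.exp(ln_vals)
        stat = panel_statistic(vals)
        # nonparametric bootstrap of the studentized mean
        n = len(ln_vals)
        boots = []
        mean, sd = ln_vals.mean(), ln_vals.std(ddof=1)
        for _ in range(4000):
            sample = rng.choice(ln_vals, size=n, replace=True)
            ssd = sample.std(ddof=1)
            if ssd > 0:
                boots.append((sample.mean() - mean) / (ssd / math.sqrt(n)))
        q = np.quantile(np.abs(boots), 0.95)
        hw_boot = q * sd / math.sqrt(n)
        c_boot = 100.0 * (math.exp(hw_boot) - 1.0)
        assert stat.c_stat_pct == pytest.approx(c_boot, rel=0.25)

    def test_flagging_threshold(self):
        spread = np.exp(np.linspace(-0.5, 0.5, 6))
        stat = panel_statistic(10.0 * spread)
        assert stat.flagged  # wide dispersion with n = 6 exceeds 17 %

    def test_aggregate_requires_two(self):
        with pytest.raises(ValueError):
            aggregate_panel([VolunteerResult("v1", 10.0, 5.0)])


class TestStandardAcceptance:
    @pytest.mark.parametrize(
        "standard,value,expected",
        [("P5", 32.0, True), ("P8", 49.6, True), ("P5", 23.7, True), ("P5", 23.6, False)],
    )
    def test_published_ranges(self, standard, value, expected):
        check = check_standard_acceptance(value, standard)
        assert check.passed is expected

    def test_margin_sign(self):
        assert check_standard_acceptance(32.0, "P5").margin > 0
        assert check_standard_acceptance(40.0, "P5").margin < 0

    def test_unknown_standard(self):
        with pytest.raises(KeyError):
            check_standard_acceptance(30.0, "P99")

    def test_user_supplied_table(self):
        check = check_standard_acceptance(16.0, "S2", table={"S2": (10.0, 20.0)})
        assert check.passed
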