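import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from quenchbind.quenching import (
    DEFAULT_TAU0,
    EmissionSpectrum,
    Mechanism,
    TitrationCurve,
    analyze_titration,
    classify_mechanism,
    extract_titration,
    fit_double_log,
    fit_stern_volmer,
    subtract_blank,
)

Q_GRID = np.array([0, 20, 40, 60, 80, 100, 120, 160, 200.0]) * 1e-6
WL = np.arange(300.0, 501.0, 1.0)


def gaussian_spectrum(q, center, amplitude, temperature=297.0, sigma=25.0):
    return EmissionSpectrum(
        temperature=temperature,
        quencher_conc=q,
        wavelengths=WL,
        intensities=amplitude * np.exp(-((WL - center) ** 2) / (2 * sigma**2)),
    )


class TestExtractTitration:
    def test_single_gaussian_identity(self):
        spectra = [gaussian_spectrum(0.0, 340.0, 1000.0)]
        curve, peaks = extract_titration(spectra)
        assert curve.f0 == pytest.approx(1000.0)
        assert peaks[0].lambda_max == 340.0
        assert peaks[0].shift == "none"

    def test_blue_shift_reported_at_all_positive_q(self):
        spectra = [
            gaussian_spectrum(q, 340.0 - 5.0 * q / Q_GRID[-1], 1000.0 / (1 + 1e4 * q))
            for q in Q_GRID
        ]
        curve, peaks = extract_titration(spectra)
        # centers move 340 -> 335 nm; every quenched spectrum reads blue
        for p in peaks:
            if p.quencher_conc >= 80e-6:  # shift beyond the 1 nm grid step
                assert p.shift == "blue"
        assert all(p.shift in ("blue", "none") for p in peaks)

    def test_secondary_peak_dominates(self):
        # when a second band at 480 nm exceeds the primary, F is read there
        it = 500.0 * np.exp(-((WL - 340.0) ** 2) / (2 * 25.0**2))
        it += 800.0 * np.exp(-((WL - 480.0) ** 2) / (2 * 10.0**2))
        s = EmissionSpectrum(297.0, 0.0, WL, it)
        curve, peaks = extract_titration([s])
        assert peaks[0].lambda_max == 480.0
        assert curve.f0 == pytest.approx(800.0)

    def test_missing_zero_quencher_errors(self):
        with pytest.raises(ValueError, match="zero-quencher"):
            extract_titration([gaussian_spectrum(1e-5, 340.0, 900.0)])

    def test_mismatched_grid_errors(self):
        other = EmissionSpectrum(297.0, 1e-5, WL[:-1], np.ones(WL.size - 1))
        with pytest.raises(ValueError, match="wavelength grid"):
            extract_titration([gaussian_spectrum(0.0, 340.0, 1000.0), other])

    def test_subtract_blank_clips_at_zero(self):
        sample = gaussian_spectrum(0.0, 340.0, 100.0)
        blank = gaussian_spectrum(0.0, 360.0, 150.0)
        corrected = subtract_blank(sample, blank)
        assert np.all(corrected.intensities >= 0)


class TestSternVolmer:
    def test_noiseless_recovery_to_machine_precision(self):
        f0 = 1000.0
        f = f0 / (1 + 1.2e4 * Q_GRID)
        curve = TitrationCurve.from_points(297.0, Q_GRID, f)
        ksv, kq, r2, intercept = fit_stern_volmer(curve, tau0=1e-8)
        assert ksv == pytest.approx(1.2e4, rel=1e-9)
        assert kq == pytest.approx(1.2e12, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-9)

    def test_unquenched_curve_flags_degenerate(self):
        curve = TitrationCurve.from_points(297.0, Q_GRID, np.full(Q_GRID.size, 500.0))
        with pytest.warns(UserWarning, match="degenerate"):
            ksv, *_ = fit_stern_volmer(curve)
        assert ksv == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_five_percent(self, rng):
        f0 = 1000.0
        f = f0 / (1 + 1.2e4 * Q_GRID) + rng.normal(0, 0.01 * f0, Q_GRID.size)
        curve = TitrationCurve.from_points(297.0, Q_GRID, f, f0=f0)
        ksv, _, r2, _ = fit_stern_volmer(curve)
        assert ksv == pytest.approx(1.2e4, rel=0.05)
        assert r2 >= 0.98

    def test_bad_background_warns_on_intercept(self):
        f0 = 1000.0
        f = f0 / (1.2 + 1.2e4 * Q_GRID)  # offset baseline -> intercept 1.2
        curve = TitrationCurve.from_points(297.0, Q_GRID, f, f0=f0)
        with pytest.warns(UserWarning, match="intercept"):
            fit_stern_volmer(curve)

    def test_kq_tau0_identity(self):
        f0 = 1000.0
        f = f0 / (1 + 3.3e3 * Q_GRID)
        curve = TitrationCurve.from_points(297.0, Q_GRID, f)
        for tau0 in (1e-8, 2.5e-9, 1e-7):
            ksv, kq, *_ = fit_stern_volmer(curve, tau0=tau0)
            assert kq == ksv / tau0  # exact, not approximate


class TestMechanism:
    @pytest.mark.parametrize(
        "kq,expected",
        [
            (1.2e12, Mechanism.STATIC),
            (1.0e9, Mechanism.NOT_STATIC),
            (2.0e10, Mechanism.NOT_STATIC),  # strict inequality at the boundary
            (2.0e10 + 1, Mechanism.STATIC),
        ],
    )
    def test_threshold_rule(self, kq, expected):
        assert classify_mechanism(kq) is expected

    def test_negative_kq_rejected(self):
        with pytest.raises(ValueError):
            classify_mechanism(-1.0)


class TestDoubleLog:
    def test_noiseless_recovery_to_machine_precision(self):
        f0, ka, n = 1000.0, 4.13e4, 1.16
        f = np.where(Q_GRID > 0, f0 / (1 + ka * np.where(Q_GRID > 0, Q_GRID, 1) ** n), f0)
        curve = TitrationCurve.from_points(297.0, Q_GRID, f)
        ka_hat, n_hat, r2 = fit_double_log(curve)
        assert ka_hat == pytest.approx(ka, rel=1e-9)
        assert n_hat == pytest.approx(n, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_single_site_hyperbolic(self):
        f0 = 1.0
        f = f0 / (1 + 5e3 * Q_GRID)
        curve = TitrationCurve.from_points(297.0, Q_GRID, f)
        _, n_hat, _ = fit_double_log(curve)
        assert n_hat == pytest.approx(1.0, rel=1e-9)

    def test_log_base_invariance_of_result(self):
        # natural-log axes change the intercept but KA = base**intercept
        # undoes it: the fitted (ka, n) are base-independent
        f0 = 1000.0
        f = np.where(Q_GRID > 0, f0 / (1 + 2e4 * np.where(Q_GRID > 0, Q_GRID, 1) ** 1.1), f0)
        curve = TitrationCurve.from_points(297.0, Q_GRID, f)
        ka10, n10, _ = fit_double_log(curve, log_base=10.0)
        kae, ne, _ = fit_double_log(curve, log_base=np.e)
        assert kae == pytest.approx(ka10, rel=1e-9)
        assert ne == pytest.approx(n10, rel=1e-9)

    def test_points_above_f0_rejected_with_warning(self):
        f0 = 1000.0
        f = f0 / (1 + 3e4 * Q_GRID)
        f[1] = f0 * 1.01  # one bad point
        curve = TitrationCurve.from_points(297.0, Q_GRID, f, f0=f0)
        with pytest.warns(UserWarning, match="rejected"):
            ka, n, _ = fit_double_log(curve)
        assert ka > 0 and n > 0

    def test_too_few_usable_points_errors(self):
        q = np.array([0.0, 1e-5, 2e-5])
        f = np.array([100.0, 120.0, 130.0])  # both positive-q points >= f0
        curve = TitrationCurve.from_points(297.0, q, f)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="fewer than 3"):
                fit_double_log(curve)


class TestAnalyzeTitration:
    def test_joint_analysis_invariants(self):
        f0 = 1000.0
        f = np.where(Q_GRID > 0, f0 / (1 + 4.13e4 * np.where(Q_GRID > 0, Q_GRID, 1) ** 1.16), f0)
        res = analyze_titration(TitrationCurve.from_points(297.0, Q_GRID, f))
        assert res.kq == res.ksv / res.tau0
        assert 0 <= res.r2_sv <= 1 and 0 <= res.r2_dl <= 1
        assert res.ka > 0 and res.n > 0
        assert res.mechanism is Mechanism.STATIC

    @given(ksv=st.floats(1e3, 1e5), tau0=st.sampled_from([1e-9, 1e-8, 1e-7]))
    def test_kq_identity_property(self, ksv, tau0):
        f0 = 1000.0
        f = f0 / (1 + ksv * Q_GRID)
        res = analyze_titration(
            TitrationCurve.from_points(297.0, Q_GRID, f), tau0=tau0
        )
        assert res.kq == res.ksv / res.tau0

    def test_default_tau0_links_table_constants(self):
        # Ksv = 1.20e4 with the 1e-8 s lifetime convention gives Kq = 1.20e12
        assert 1.20e4 / DEFAULT_TAU0 == pytest.approx(1.20e12)
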