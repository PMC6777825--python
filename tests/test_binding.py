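"""Schellman relation: forward prediction, fitting, single-point inversion, selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from dsfbind import binding
from dsfbind.binding import (
    DoseSeries,
    SchellmanInfeasibleError,
    estimate_kd_single_point,
    fit_dose_series,
    predict_tm,
    select_reporting_estimate,
)
from dsfbind.constants import R_KCAL
from dsfbind.synthetic import LigandSpec, simulate_dose_series


def tm_by_root_finding(L, kd, dh0, t0):
    """Independent oracle: solve the implicit shift equation numerically."""

    def eq(tm):
        return (tm - t0) - tm * t0 * R_KCAL * math.log1p(L / kd) / dh0

    return brentq(eq, t0 - 1e-9, t0 + 60.0)


class TestPredictTm:
    def test_zero_concentration_returns_t0_exactly(self):
        assert predict_tm(0.0, 30.9, 72.1, 326.2) == 326.2

    def test_closed_form_matches_root_finding_oracle(self):
        for L, kd, dh0, t0 in [
            (300.0, 30.9, 72.1, 326.2),
            (10000.0, 3570.0, 72.1, 326.2),
            (1.0, 131.0, 40.0, 320.0),
        ]:
            assert predict_tm(L, kd, dh0, t0) == pytest.approx(
                tm_by_root_finding(L, kd, dh0, t0), abs=1e-9
            )

    def test_reference_shift_value(self):
        # 300 μM at Kd 30.9 μM, ΔH0 72.1, T0 326.2 K → ΔTm ≈ 7.11 K
        tm = predict_tm(300.0, 30.9, 72.1, 326.2)
        assert tm == pytest.approx(333.305, abs=2e-3)
        assert tm - 326.2 == pytest.approx(7.105, abs=2e-3)

    def test_residual_identity(self):
        tm = predict_tm(500.0, 55.0, 80.0, 326.2)
        lhs = tm - 326.2
        rhs = tm * 326.2 * R_KCAL * math.log1p(500.0 / 55.0) / 80.0
        assert abs(lhs - rhs) <= 1e-10

    def test_infeasible_shift_raises(self):
        with pytest.raises(SchellmanInfeasibleError):
            predict_tm(1e12, 1e-6, 10.0, 326.2)

    def test_shift_increasing_in_log_concentration_with_softplus_shape(self):
        # ΔTm(ln L) inherits the softplus shape of ln(1 + L/Kd): strictly
        # increasing, convex below Kd, approaching a near-constant slope per
        # decade far above Kd
        conc = np.logspace(0, 4, 40)
        dtm = predict_tm(conc, 30.9, 72.1, 326.2) - 326.2
        assert np.all(np.diff(dtm) > 0)
        low = conc < 30.9
        assert np.all(np.diff(dtm, 2)[: low.sum() - 2] > 0)
        decade = np.diff(dtm)[-10:]
        assert decade.std() / decade.mean() < 0.1


class TestSinglePoint:
    def test_reference_inversion(self):
        # ΔTm = 8.7 K at 300 μM with the fixed (T0, ΔH0) → Kd ≈ 17.6 μM, preferred window
        est = estimate_kd_single_point(8.7, 300.0)
        assert est.kd_app_um == pytest.approx(17.63, rel=1e-3)
        assert est.window == binding.PREFERRED
        assert est.usable

    def test_monotone_decreasing_in_shift_and_divergent_at_zero(self):
        shifts = [0.5, 1.0, 3.0, 6.0, 9.0]
        kds = [estimate_kd_single_point(s, 300.0).kd_app_um for s in shifts]
        assert all(a > b for a, b in zip(kds, kds[1:]))
        assert estimate_kd_single_point(1e-8, 300.0).kd_app_um > 1e9

    @given(
        kd=st.floats(1.0, 5000.0),
        dh0=st.floats(40.0, 110.0),
        logl=st.floats(0.0, 4.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_exact_inverse_of_predict_tm(self, kd, dh0, logl):
        L = 10.0**logl
        t0 = 326.1
        dtm = predict_tm(L, kd, dh0, t0) - t0
        est = estimate_kd_single_point(dtm, L, t0_k=t0, dh0_kcal=dh0)
        assert est.kd_app_um == pytest.approx(kd, rel=1e-9)

    @pytest.mark.parametrize(
        "dtm,expected",
        [
            (-2.0, binding.DESTABILIZED),
            (0.5, binding.BELOW_FLOOR),
            (1.5, binding.OUT_OF_RANGE),
            (3.0, binding.ACCEPTABLE),
            (9.0, binding.PREFERRED),
            (14.0, binding.OUT_OF_RANGE),
        ],
    )
    def test_window_classification(self, dtm, expected):
        est = estimate_kd_single_point(dtm, 10000.0)
        assert est.window == expected
        if dtm <= 0:
            assert est.kd_app_um is None

    def test_robust_to_enthalpy_misspecification_within_preferred_window(self):
        # an estimate taken from the 6–11 K window stays near the truth even
        # when the assumed 72.1 kcal/mol enthalpy is off by ±20%: within a
        # factor 2 through most of the window, degrading to ~2.1 only at the
        # extreme 11 K edge
        kd_true = 30.9
        for dh0_true in (0.8 * 72.1, 72.1, 1.2 * 72.1):
            for L in np.logspace(1.5, 4, 12):
                dtm = predict_tm(L, kd_true, dh0_true, 326.1) - 326.1
                est = estimate_kd_single_point(dtm, L)  # assumes 72.1
                if est.window == binding.PREFERRED:
                    ratio = est.kd_app_um / kd_true
                    assert 0.45 < ratio < 2.1
                    if dtm <= 9.5:
                        assert 0.5 < ratio < 2.0


class TestFitDoseSeries:
    def test_noiseless_recovery_exact(self, glu_like):
        series = simulate_dose_series(
            glu_like, 326.2, np.logspace(0, 4, 8), n_reps=1, tm_noise_sd=0.0, seed=0
        )
        fit = fit_dose_series(series, 326.2)
        assert fit.converged
        assert fit.kd_app_um == pytest.approx(422.0, rel=1e-6)
        assert fit.dh0_kcal == pytest.approx(72.1, rel=1e-6)

    def test_noisy_median_within_standard_error_band(self, gln_like):
        concs = [0.1, 0.3, 1, 3, 10, 30, 100, 300]
        kds = [
            fit_dose_series(
                simulate_dose_series(gln_like, 326.2, concs, n_reps=6, tm_noise_sd=0.3, seed=s),
                326.2,
            ).kd_app_um
            for s in range(50)
        ]
        assert abs(np.median(kds) - 30.9) < 5.8

    def test_point_order_invariance(self, gln_like):
        series = simulate_dose_series(
            gln_like, 326.2, [1, 10, 100, 1000], n_reps=1, tm_noise_sd=0.0, seed=0
        )
        perm = np.array([2, 0, 3, 1])
        shuffled = DoseSeries(
            ligand_id=series.ligand_id,
            concentrations_um=series.concentrations_um[perm],
            mean_tm_k=series.mean_tm_k[perm],
        )
        f1 = fit_dose_series(series, 326.2)
        f2 = fit_dose_series(shuffled, 326.2)
        assert f1.kd_app_um == f2.kd_app_um
        assert f1.dh0_kcal == f2.dh0_kcal

    def test_flat_series_refused(self):
        series = DoseSeries(
            ligand_id="x",
            concentrations_um=np.array([1.0, 10.0, 100.0, 1000.0]),
            mean_tm_k=np.full(4, 326.25),
        )
        with pytest.raises(ValueError, match="flat"):
            fit_dose_series(series, 326.2)

    def test_too_few_points_rejected(self):
        series = DoseSeries(
            ligand_id="x",
            concentrations_um=np.array([1.0, 10.0, 100.0]),
            mean_tm_k=np.array([326.2, 327.0, 329.0]),
        )
        with pytest.raises(ValueError, match=">= 4"):
            fit_dose_series(series, 326.2)


class TestSelection:
    def _est(self, dtm, conc):
        return estimate_kd_single_point(dtm, conc, ligand_id="lig")

    def test_preferred_window_at_lowest_concentration_wins(self):
        # low dose already in 6–11 K; higher doses overshoot
        ests = [self._est(8.0, 100.0), self._est(12.5, 1000.0), self._est(14.0, 10000.0)]
        chosen = select_reporting_estimate(ests)
        assert chosen.concentration_um == 100.0
        assert chosen.usable

    def test_highest_acceptable_concentration_when_it_reaches_preferred(self):
        ests = [self._est(0.5, 100.0), self._est(3.0, 1000.0), self._est(9.0, 10000.0)]
        chosen = select_reporting_estimate(ests)
        assert chosen.concentration_um == 10000.0
        assert chosen.window == binding.PREFERRED

    def test_acceptable_fallback(self):
        ests = [self._est(0.5, 100.0), self._est(3.0, 1000.0), self._est(5.0, 10000.0)]
        chosen = select_reporting_estimate(ests)
        assert chosen.concentration_um == 10000.0
        assert chosen.window == binding.ACCEPTABLE

    def test_all_negative_shifts_excluded_as_destabilized(self):
        ests = [self._est(-0.5, 100.0), self._est(-1.2, 1000.0), self._est(-2.0, 10000.0)]
        chosen = select_reporting_estimate(ests)
        assert not chosen.usable
        assert "destabilized" in chosen.selection_reason
        assert chosen.kd_app_um is None

    def test_mixed_ligands_rejected(self):
        a = estimate_kd_single_point(8.0, 100.0, ligand_id="a")
        b = estimate_kd_single_point(8.0, 100.0, ligand_id="b")
        with pytest.raises(ValueError, match="mixed ligand"):
            select_reporting_estimate([a, b])
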