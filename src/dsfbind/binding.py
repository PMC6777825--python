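"""Thermodynamic link between ligand concentration and melting-point elevation.

For a protein that unfolds reversibly, binding of a ligand L with apparent
dissociation constant Kd_app raises the apparent melting temperature Tm above
the ligand-free value T0 according to the Schellman relation

    ΔTm = Tm − T0 = (Tm · T0 · R / ΔH0) · ln(1 + [L]/Kd_app)

where ΔH0 is the van 't Hoff enthalpy of unfolding at T0 and R the gas
constant.  Because the right-hand side contains Tm, the relation is implicit,
but it rearranges to the closed form

    Tm = T0 / (1 − T0 · R · ln(1 + [L]/Kd_app) / ΔH0)

valid while the denominator stays positive (shifts beyond that point are
outside the model).  This module provides the relation in three forms:

* :func:`predict_tm` — forward evaluation (closed form);
* :func:`fit_dose_series` — nonlinear least squares for (Kd_app, ΔH0) with T0
  fixed, on replicate-averaged Tm values across a concentration series;
* :func:`estimate_kd_single_point` — exact inversion of one ΔTm at one
  concentration, substituting fixed (T0, ΔH0);

plus :func:`select_reporting_estimate`, the rule that picks which
concentration's single-point estimate a ligand is reported at (shifts of
6–11 K preferred, 2–11 K acceptable, destabilized and sub-1-K ligands
excluded).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import (
    DEFAULT_DH0_KCAL,
    DEFAULT_T0_SINGLE_K,
    DELTA_TM_ACCEPTABLE_MIN_K,
    DELTA_TM_FLOOR_K,
    DELTA_TM_MAX_K,
    DELTA_TM_PREFERRED_MIN_K,
    R_KCAL,
)

__all__ = [
    "SchellmanInfeasibleError",
    "DoseSeries",
    "SchellmanFit",
    "SinglePointEstimate",
    "predict_tm",
    "delta_tm",
    "fit_dose_series",
    "estimate_kd_single_point",
    "classify_window",
    "select_reporting_estimate",
]

# window labels
PREFERRED = "preferred"
ACCEPTABLE = "acceptable"
BELOW_FLOOR = "below_floor"
DESTABILIZED = "destabilized"
OUT_OF_RANGE = "out_of_range"


class SchellmanInfeasibleError(ValueError):
    """The requested shift lies outside the validity of the Schellman form.

    Raised when 1 − T0·R·ln(1+[L]/Kd)/ΔH0 ≤ 0, i.e. the predicted stabilization
    would diverge.
    """


@dataclass(frozen=True)
class DoseSeries:
    """Replicate-averaged apparent Tm (kelvin) across a ligand titration."""

    ligand_id: str
    concentrations_um: np.ndarray
    mean_tm_k: np.ndarray
    sem_tm_k: np.ndarray | None = None
    n_replicates: int | None = None
    # generator ground truth, retained for parameter-recovery tests
    kd_true_um: float | None = None
    dh0_true: float | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_um, dtype=float)
        tm = np.asarray(self.mean_tm_k, dtype=float)
        if conc.shape != tm.shape or conc.ndim != 1:
            raise ValueError("concentrations and mean Tm must be 1-D and equal length")
        if np.any(conc <= 0):
            raise ValueError("dose-series concentrations must be > 0")
        if len(np.unique(conc)) != len(conc):
            raise ValueError("dose-series concentrations must be distinct")
        object.__setattr__(self, "concentrations_um", conc)
        object.__setattr__(self, "mean_tm_k", tm)
        if self.sem_tm_k is not None:
            object.__setattr__(self, "sem_tm_k", np.asarray(self.sem_tm_k, dtype=float))

    def __len__(self) -> int:
        return len(self.concentrations_um)


@dataclass(frozen=True)
class SchellmanFit:
    """Result of fitting (Kd_app, ΔH0) with T0 fixed."""

    ligand_id: str
    kd_app_um: float
    dh0_kcal: float
    t0_k: float
    se_kd_um: float
    se_dh0_kcal: float
    converged: bool
    residual_rms_k: float
    n_points: int


@dataclass(frozen=True)
class SinglePointEstimate:
    """Kd_app inverted from a single (concentration, ΔTm) observation."""

    ligand_id: str
    concentration_um: float
    delta_tm_k: float
    kd_app_um: float | None
    window: str
    usable: bool
    selection_reason: str | None = None

    @property
    def pkd(self) -> float | None:
        """−log10 of Kd_app expressed in mol·L⁻¹."""
        if self.kd_app_um is None:
            return None
        return -math.log10(self.kd_app_um * 1e-6)


def predict_tm(
    concentration_um: float | np.ndarray,
    kd_app_um: float,
    dh0_kcal: float,
    t0_k: float,
) -> float | np.ndarray:
    """Apparent Tm (K) at ligand concentration [L] under the Schellman relation.

    Closed form Tm = T0 / (1 − T0·R·ln(1+[L]/Kd)/ΔH0).  Returns T0 exactly at
    [L] = 0.  Raises :class:`SchellmanInfeasibleError` if the denominator is
    non-positive for any requested concentration.
    """
    if kd_app_um <= 0 or dh0_kcal <= 0 or t0_k <= 0:
        raise ValueError("kd_app, dh0 and t0 must all be positive")
    conc = np.asarray(concentration_um, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    denom = 1.0 - t0_k * R_KCAL * np.log1p(conc / kd_app_um) / dh0_kcal
    if np.any(denom <= 0):
        raise SchellmanInfeasibleError(
            "T0*R*ln(1+[L]/Kd)/dH0 >= 1: predicted shift exceeds model validity "
            f"(max ln-term {np.max(t0_k * R_KCAL * np.log1p(conc / kd_app_um) / dh0_kcal):.3f})"
        )
    tm = t0_k / denom
    return float(tm) if np.isscalar(concentration_um) else tm


def delta_tm(
    concentration_um: float | np.ndarray,
    kd_app_um: float,
    dh0_kcal: float,
    t0_k: float,
) -> float | np.ndarray:
    """Predicted thermal shift Tm − T0 in kelvin."""
    tm = predict_tm(concentration_um, kd_app_um, dh0_kcal, t0_k)
    return tm - t0_k


def _residuals(log_params: np.ndarray, conc: np.ndarray, tm_obs: np.ndarray, t0: float) -> np.ndarray:
    kd = math.exp(log_params[0])
    dh0 = math.exp(log_params[1])
    denom = 1.0 - t0 * R_KCAL * np.log1p(conc / kd) / dh0
    # infeasible region: smooth, large penalty so the optimizer retreats
    bad = denom <= 1e-9
    denom = np.where(bad, 1e-9, denom)
    resid = t0 / denom - tm_obs
    resid = np.where(bad, 1e6 * (1.0 + np.abs(resid)), resid)
    return resid


def fit_dose_series(series: DoseSeries, t0_k: float, min_points: int = 4) -> SchellmanFit:
    """Least-squares fit of (Kd_app, ΔH0) to mean Tm vs concentration, T0 fixed.

    The fit is unweighted on the replicate-averaged Tm values.  Positivity of
    both parameters is enforced by optimizing in log space; initialization is a
    small multistart (Kd0 at the concentration nearest half-maximal shift, ΔH0
    starting from 40, 70 and 100 kcal·mol⁻¹) with the best residual kept.
    Standard errors come from the Jacobian-based covariance at the optimum via
    the delta method.
    """
    if t0_k <= 0:
        raise ValueError("t0 must be positive")
    if len(series) < min_points:
        raise ValueError(f"need >= {min_points} distinct concentrations, got {len(series)}")
    order = np.argsort(series.concentrations_um)
    conc = series.concentrations_um[order]
    tm = series.mean_tm_k[order]

    shifts = tm - t0_k
    if np.max(shifts) < 0.5:
        raise ValueError(
            "series is flat (max observed shift "
            f"{np.max(shifts):.2f} K < 0.5 K); refusing to fit"
        )

    # Kd0: concentration whose shift is nearest half of the maximal shift
    half = 0.5 * np.max(shifts)
    kd0 = float(conc[int(np.argmin(np.abs(shifts - half)))])
    best = None
    for dh0_start in (40.0, 70.0, 100.0):
        x0 = np.array([math.log(kd0), math.log(dh0_start)])
        res = least_squares(_residuals, x0, args=(conc, tm, t0_k), method="lm")
        if best is None or res.cost < best.cost:
            best = res

    kd = math.exp(best.x[0])
    dh0 = math.exp(best.x[1])
    n = len(conc)
    dof = n - 2
    rss = float(np.sum(best.fun**2))
    residual_rms = math.sqrt(rss / n)
    # covariance in log space; delta-method back-transform
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
        se_log = np.sqrt(np.diag(cov))
        se_kd = kd * se_log[0]
        se_dh0 = dh0 * se_log[1]
        cov_ok = np.all(np.isfinite(se_log))
    except np.linalg.LinAlgError:
        se_kd = se_dh0 = float("nan")
        cov_ok = False
    converged = bool(best.success) and cov_ok and residual_rms < 1e5
    return SchellmanFit(
        ligand_id=series.ligand_id,
        kd_app_um=kd,
        dh0_kcal=dh0,
        t0_k=t0_k,
        se_kd_um=se_kd,
        se_dh0_kcal=se_dh0,
        converged=converged,
        residual_rms_k=residual_rms,
        n_points=n,
    )


def classify_window(delta_tm_k: float) -> str:
    """Assign a ΔTm to its reporting window.

    Negative shifts mark destabilization; below 1 K is under the reporting
    floor; 2–11 K is acceptable with the 6–11 K sub-range preferred; the rest
    (1–2 K or above 11 K) is out of range.
    """
    if delta_tm_k < 0:
        return DESTABILIZED
    if delta_tm_k < DELTA_TM_FLOOR_K:
        return BELOW_FLOOR
    if DELTA_TM_PREFERRED_MIN_K <= delta_tm_k <= DELTA_TM_MAX_K:
        return PREFERRED
    if DELTA_TM_ACCEPTABLE_MIN_K <= delta_tm_k <= DELTA_TM_MAX_K:
        return ACCEPTABLE
    return OUT_OF_RANGE


def estimate_kd_single_point(
    delta_tm_k: float,
    concentration_um: float,
    t0_k: float = DEFAULT_T0_SINGLE_K,
    dh0_kcal: float = DEFAULT_DH0_KCAL,
    ligand_id: str = "",
) -> SinglePointEstimate:
    """Invert the Schellman relation at one concentration.

    With Tm = T0 + ΔTm the relation solves exactly for

        Kd_app = [L] / (exp(ΔTm·ΔH0 / (R·Tm·T0)) − 1)

    Non-positive shifts yield no estimate; they are classified (destabilized /
    below the floor), not raised.
    """
    if concentration_um <= 0:
        raise ValueError("concentration must be positive")
    if t0_k <= 0 or dh0_kcal <= 0:
        raise ValueError("t0 and dh0 must be positive")
    window = classify_window(delta_tm_k)
    kd: float | None = None
    if delta_tm_k > 0:
        tm = t0_k + delta_tm_k
        expo = delta_tm_k * dh0_kcal / (R_KCAL * tm * t0_k)
        kd = concentration_um / math.expm1(expo)
    return SinglePointEstimate(
        ligand_id=ligand_id,
        concentration_um=concentration_um,
        delta_tm_k=delta_tm_k,
        kd_app_um=kd,
        window=window,
        usable=window in (PREFERRED, ACCEPTABLE),
    )


def select_reporting_estimate(
    estimates: Sequence[SinglePointEstimate],
) -> SinglePointEstimate:
    """Pick the single-point estimate a ligand is reported at.

    Among a ligand's estimates across concentrations: adopt the lowest
    concentration whose shift falls in the preferred 6–11 K window; failing
    that, the highest concentration in the acceptable 2–11 K window; otherwise
    the ligand is unusable (destabilized or below the reporting floor).  The
    applied rule is recorded in ``selection_reason``.
    """
    if not estimates:
        raise ValueError("no estimates to select from")
    ligands = {e.ligand_id for e in estimates}
    if len(ligands) > 1:
        raise ValueError(f"mixed ligand ids in selection: {sorted(ligands)}")

    preferred = [e for e in estimates if e.window == PREFERRED]
    if preferred:
        chosen = min(preferred, key=lambda e: e.concentration_um)
        return dataclasses.replace(
            chosen, selection_reason="lowest concentration with shift in preferred 6-11 K window"
        )
    acceptable = [e for e in estimates if e.window == ACCEPTABLE]
    if acceptable:
        chosen = max(acceptable, key=lambda e: e.concentration_um)
        return dataclasses.replace(
            chosen, selection_reason="highest concentration with shift in acceptable 2-11 K window"
        )
    if all(e.delta_tm_k < 0 for e in estimates):
        reason = "excluded: destabilized (all shifts negative)"
    elif all(e.window in (BELOW_FLOOR, DESTABILIZED) for e in estimates):
        reason = "excluded: all shifts below 1 K reporting floor or negative"
    else:
        reason = "excluded: no shift in the 2-11 K window"
    worst = max(estimates, key=lambda e: e.concentration_um)
    return dataclasses.replace(worst, kd_app_um=None, usable=False, selection_reason=reason)
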