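"""Apparent-Tm calling from raw fluorescence melt curves.

The apparent melting temperature of a transition is defined as the temperature
of the maximum of the smoothed first derivative dFluorescence/dT.  Curves with
two resolvable derivative maxima are biphasic; for binding analysis the
second (right-side) transition is the one that tracks ligand concentration,
so the rightmost retained peak is adopted.

Peak retention is explicit and configurable, since vendor melt-analysis
software does not disclose its rules: a local maximum of the derivative is
kept if its prominence is at least ``prominence_frac`` of the global
derivative maximum, it clears a robust noise floor (a multiple of the MAD of
the derivative), and it is at least ``min_separation`` away from a larger
peak.  Peak positions are refined off-grid by a quadratic fit through the
three samples around each maximum.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter

from .constants import CELSIUS_OFFSET

__all__ = [
    "MeltCurve",
    "DerivativeCurve",
    "TmCall",
    "ReplicateSummary",
    "differentiate",
    "call_tm",
    "summarize_replicates",
    "group_and_summarize",
]

BUFFER_LIGAND = "buffer"


@dataclass(frozen=True)
class MeltCurve:
    """One well's fluorescence-vs-temperature trace with ligand annotation."""

    well_id: str
    ligand_id: str
    concentration_um: float
    temperature_c: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        temp = np.asarray(self.temperature_c, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        if temp.ndim != 1 or temp.shape != fluo.shape:
            raise ValueError("temperature and fluorescence must be 1-D and equal length")
        if len(temp) < 50:
            raise ValueError(f"melt curve needs >= 50 points, got {len(temp)}")
        if np.any(np.diff(temp) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature_c", temp)
        object.__setattr__(self, "fluorescence", fluo)

    @property
    def is_buffer(self) -> bool:
        return self.concentration_um == 0 or self.ligand_id == BUFFER_LIGAND

    @property
    def grid_step_c(self) -> float:
        return float(np.median(np.diff(self.temperature_c)))


@dataclass(frozen=True)
class DerivativeCurve:
    temperature_c: np.ndarray
    dfdt: np.ndarray


@dataclass(frozen=True)
class TmCall:
    """Detected transitions of one melt curve and the adopted apparent Tm.

    ``peaks`` lists (temperature °C, prominence as a fraction of the global
    derivative maximum), sorted by temperature.  ``adopted_tm_c`` is the
    rightmost retained peak, or None when no transition was found
    (``qc_flags`` then contains ``"no_transition"``).
    """

    well_id: str
    ligand_id: str
    concentration_um: float
    peaks: tuple[tuple[float, float], ...]
    biphasic: bool
    adopted_tm_c: float | None
    delta_tm_k: float | None = None
    qc_flags: tuple[str, ...] = ()

    @property
    def usable(self) -> bool:
        return self.adopted_tm_c is not None and "boundary" not in self.qc_flags


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate-averaged apparent Tm for one (ligand, concentration) group."""

    ligand_id: str
    concentration_um: float
    mean_tm_k: float
    sem_tm_k: float | None
    n: int


def differentiate(curve: MeltCurve, smooth_window_c: float = 1.0) -> DerivativeCurve:
    """Smoothed first derivative of fluorescence with respect to temperature.

    Uses a local quadratic (Savitzky–Golay) filter of width ``smooth_window_c``
    evaluated with its analytic first derivative, so a linear ramp
    differentiates to an exact constant over the whole grid.
    """
    step = curve.grid_step_c
    npts = int(round(smooth_window_c / step))
    if npts < 3:
        raise ValueError(
            f"smoothing window {smooth_window_c} °C spans {npts} grid steps; need >= 3"
        )
    window = npts + 1 if npts % 2 == 0 else npts
    if window >= len(curve.temperature_c):
        raise ValueError("smoothing window exceeds curve span")
    dfdt = savgol_filter(
        curve.fluorescence, window_length=window, polyorder=2, deriv=1, delta=step, mode="interp"
    )
    # drop the half-window margins: edge values come from polynomial
    # extrapolation with inflated noise variance
    half = window // 2
    return DerivativeCurve(temperature_c=curve.temperature_c[half:-half], dfdt=dfdt[half:-half])


def _refine_peak(temp: np.ndarray, dfdt: np.ndarray, i: int) -> float:
    """Quadratic (three-point) refinement of a derivative maximum position."""
    if i == 0 or i == len(temp) - 1:
        return float(temp[i])
    y0, y1, y2 = dfdt[i - 1], dfdt[i], dfdt[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep grid point
        return float(temp[i])
    offset = 0.5 * (y0 - y2) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    step = temp[i + 1] - temp[i]
    return float(temp[i] + offset * step)


def call_tm(
    curve: MeltCurve,
    prominence_frac: float = 0.10,
    min_separation_c: float = 2.0,
    t0_ref_c: float | None = None,
    smooth_window_c: float = 1.0,
    noise_floor_mads: float = 6.0,
    peak_floor_mads: float = 8.0,
) -> TmCall:
    """Call transition peaks on a melt curve and adopt the apparent Tm.

    The fluorescence noise level is estimated robustly from second differences
    of the raw trace (insensitive to smooth baselines, transitions and quench)
    and propagated through the derivative filter to a derivative-scale noise
    s.d. σ_f.  A curve whose global derivative maximum is below
    ``noise_floor_mads``·σ_f carries no detectable transition.  A local
    maximum is retained when its prominence is at least ``prominence_frac``
    times the global derivative maximum *and* at least ``peak_floor_mads``·σ_f
    (the absolute floor keeps stray noise bumps from masquerading as a second
    transition, which matters because the rightmost peak is the one adopted).
    Peaks closer than ``min_separation_c`` are merged, keeping the higher.
    A curve is biphasic when two or more peaks survive; the rightmost retained
    peak is adopted as the apparent Tm.  If ``t0_ref_c`` is given,
    ``delta_tm_k`` is the adopted Tm minus that reference.

    Returns a no-transition call (``adopted_tm_c`` is None) rather than raising
    when nothing is retained.
    """
    if not 0 < prominence_frac < 1:
        raise ValueError("prominence_frac must be in (0, 1)")
    if min_separation_c <= 0:
        raise ValueError("min_separation must be positive")
    deriv = differentiate(curve, smooth_window_c=smooth_window_c)
    dfdt = deriv.dfdt
    temp = deriv.temperature_c
    step = curve.grid_step_c

    global_max = float(np.max(dfdt))
    flags: list[str] = []
    no_transition = TmCall(
        well_id=curve.well_id,
        ligand_id=curve.ligand_id,
        concentration_um=curve.concentration_um,
        peaks=(),
        biphasic=False,
        adopted_tm_c=None,
        qc_flags=("no_transition",),
    )
    if global_max <= 0:
        return no_transition

    # raw fluorescence noise from second differences, propagated through the
    # derivative filter to the derivative scale
    d2 = np.diff(curve.fluorescence, n=2)
    raw_sd = 1.4826 * float(np.median(np.abs(d2 - np.median(d2)))) / math.sqrt(6.0)
    npts = int(round(smooth_window_c / step))
    window = npts + 1 if npts % 2 == 0 else npts
    coeffs = savgol_coeffs(window, polyorder=2, deriv=1, delta=step)
    deriv_noise_sd = raw_sd * float(np.sqrt(np.sum(coeffs**2)))
    if global_max < noise_floor_mads * deriv_noise_sd:
        return no_transition

    floor = max(prominence_frac * global_max, peak_floor_mads * deriv_noise_sd)
    distance = max(1, int(round(min_separation_c / step)))
    idx, props = find_peaks(dfdt, prominence=floor, distance=distance)
    if len(idx) == 0:
        return no_transition

    if int(np.argmax(dfdt)) in (0, len(dfdt) - 1):
        flags.append("boundary")

    peaks = tuple(
        (_refine_peak(temp, dfdt, int(i)), float(p / global_max))
        for i, p in zip(idx, props["prominences"])
    )
    adopted = peaks[-1][0]
    delta = adopted - t0_ref_c if t0_ref_c is not None else None
    return TmCall(
        well_id=curve.well_id,
        ligand_id=curve.ligand_id,
        concentration_um=curve.concentration_um,
        peaks=peaks,
        biphasic=len(peaks) >= 2,
        adopted_tm_c=adopted,
        delta_tm_k=delta,
        qc_flags=tuple(flags),
    )


def summarize_replicates(calls: Sequence[TmCall]) -> ReplicateSummary:
    """Average technical replicates of one (ligand, concentration) group.

    Mean is reported in kelvin; s.e.m. = sd/√n (absent for n = 1).
    """
    if not calls:
        raise ValueError("empty replicate group")
    keys = {(c.ligand_id, c.concentration_um) for c in calls}
    if len(keys) > 1:
        raise ValueError(f"mixed (ligand, concentration) groups: {sorted(keys)}")
    if any(c.adopted_tm_c is None for c in calls):
        raise ValueError("all calls must have an adopted Tm")
    tms_k = np.array([c.adopted_tm_c + CELSIUS_OFFSET for c in calls])
    n = len(tms_k)
    sem = float(np.std(tms_k, ddof=1) / math.sqrt(n)) if n > 1 else None
    (ligand_id, conc) = next(iter(keys))
    return ReplicateSummary(
        ligand_id=ligand_id,
        concentration_um=conc,
        mean_tm_k=float(np.mean(tms_k)),
        sem_tm_k=sem,
        n=n,
    )


def group_and_summarize(calls: Iterable[TmCall]) -> list[ReplicateSummary]:
    """Group usable calls by (ligand, concentration) and summarize each group."""
    groups: dict[tuple[str, float], list[TmCall]] = defaultdict(list)
    for c in calls:
        if c.usable:
            groups[(c.ligand_id, c.concentration_um)].append(c)
    return [summarize_replicates(g) for _, g in sorted(groups.items())]
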