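"""Synthetic melt curves, plates, dose series, and response panels.

Every downstream stage of the pipeline (Tm calling, Schellman fitting,
single-point inversion, correlation) is testable against ground truth via the
generators here, which emulate the statistical structure of a thermal-shift
ligand screen on a heterodimeric receptor ligand-binding domain:

* two-state van 't Hoff unfolding transitions with dye baselines and optional
  post-transition quench, on the instrument's 25–99 °C ramp;
* biphasic curves — a ligand-insensitive first transition near 50 °C plus a
  second transition that shifts with ligand dose per the Schellman relation;
* destabilizing ligands (negative shifts) and inert ligands;
* technical-replicate noise, applied either to fluorescence (plate level) or
  to Tm directly (dose-series level) so that caller error and fit error stay
  separable;
* a single-concentration receptor-response panel following a Hill relation
  with fixed maximum.

The fluorescence model for one well is

    F(T) = [b0 + b1·T + Σᵢ Aᵢ·fᵢ(T)] · exp(−q·max(0, T − (max Tmᵢ + δ))) + ε

with fᵢ(T) = 1/(1 + exp((ΔH_vH,i/R)(1/T − 1/Tmᵢ))) evaluated in kelvin: a
logistic two-state unfolded fraction whose value at Tm is exactly ½.  The
quench term mimics dye dissociation above the last transition; its onset is
delayed by δ (default 3 °C) past the last Tm so that it cannot move the
derivative maxima.

All randomness flows from explicit integer seeds; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import binding
from .constants import CELSIUS_OFFSET, DEFAULT_BUFFER_TM_C, DEFAULT_DRFU_MAX, R_KCAL
from .meltcurve import BUFFER_LIGAND, MeltCurve
from .response import ResponsePoint

__all__ = [
    "TransitionSpec",
    "LigandSpec",
    "PlateWell",
    "PlateMap",
    "DEFAULT_GRID_C",
    "transition_fraction",
    "simulate_melt_curve",
    "simulate_dose_series",
    "simulate_plate",
    "simulate_response_panel",
    "builtin_descriptor_table",
]

#: Instrument ramp: 25 → 99 °C in 0.2 °C steps (371 points).
DEFAULT_GRID_C: np.ndarray = np.round(np.arange(25.0, 99.0 + 1e-9, 0.2), 10)

#: Default van 't Hoff enthalpy of a simulated transition (kcal·mol⁻¹).
#: Chosen steep enough that derivative-maximum Tm calling is sharp; note this
#: is a property of the simulated melt transition, distinct from the ΔH0 that
#: enters the Schellman dose-shift relation.
DEFAULT_DH_VH: float = 120.0

#: Temperature (°C) of the ligand-insensitive first transition of biphasic curves.
DEFAULT_FIRST_TM_C: float = 50.0


@dataclass(frozen=True)
class TransitionSpec:
    """One two-state unfolding transition of a simulated melt curve."""

    tm_true_c: float
    dh_vh_kcal: float = DEFAULT_DH_VH
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 25.0 <= self.tm_true_c <= 99.0:
            raise ValueError(f"tm_true must lie in [25, 99] °C, got {self.tm_true_c}")
        if self.dh_vh_kcal <= 0:
            raise ValueError("van 't Hoff enthalpy must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class LigandSpec:
    """Ground-truth behaviour of a simulated ligand.

    ``agonist`` ligands shift the second transition up per the Schellman
    relation with (kd_true_um, dh0_true).  ``destabilizer`` ligands lower Tm
    linearly in log concentration (slope ``destab_slope_k`` per decade,
    referenced to ``destab_ref_um``) — a phenomenological stand-in, since no
    thermodynamic model of the destabilization is assumed.  ``inert`` ligands
    leave the curve unchanged.
    """

    ligand_id: str
    mode: str = "agonist"
    kd_true_um: float | None = None
    dh0_true: float | None = None
    destab_slope_k: float = -1.0
    destab_ref_um: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("agonist", "destabilizer", "inert"):
            raise ValueError(f"unknown ligand mode {self.mode!r}")
        if self.mode == "agonist":
            if self.kd_true_um is None or self.kd_true_um <= 0:
                raise ValueError("agonist requires kd_true_um > 0")
            if self.dh0_true is None or self.dh0_true <= 0:
                raise ValueError("agonist requires dh0_true > 0")
        if self.mode == "destabilizer" and self.destab_slope_k >= 0:
            raise ValueError("destabilizer slope must be negative")


@dataclass(frozen=True)
class PlateWell:
    well_id: str
    ligand_id: str
    concentration_um: float


@dataclass(frozen=True)
class PlateMap:
    """Well → (ligand, concentration) assignment; buffer wells have conc 0."""

    entries: tuple[PlateWell, ...]

    def __post_init__(self) -> None:
        wells = [e.well_id for e in self.entries]
        if len(set(wells)) != len(wells):
            raise ValueError("well ids must be unique")
        if any(e.concentration_um < 0 for e in self.entries):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, float]]) -> "PlateMap":
        return cls(entries=tuple(PlateWell(*r) for r in records))

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def transition_fraction(
    temperature_c: float | np.ndarray, tm_c: float, dh_vh_kcal: float = DEFAULT_DH_VH
) -> float | np.ndarray:
    """Unfolded fraction f(T) of a two-state transition; exactly ½ at Tm."""
    t_k = np.asarray(temperature_c, dtype=float) + CELSIUS_OFFSET
    tm_k = tm_c + CELSIUS_OFFSET
    f = 1.0 / (1.0 + np.exp((dh_vh_kcal / R_KCAL) * (1.0 / t_k - 1.0 / tm_k)))
    return float(f) if np.isscalar(temperature_c) else f


def simulate_melt_curve(
    transitions: Sequence[TransitionSpec],
    baseline_intercept: float = 0.2,
    baseline_slope: float = 0.002,
    quench_rate: float = 0.01,
    quench_onset_offset_c: float = 3.0,
    noise_sd: float = 0.0,
    grid_c: np.ndarray | None = None,
    seed: int = 0,
    well_id: str = "W1",
    ligand_id: str = BUFFER_LIGAND,
    concentration_um: float = 0.0,
) -> MeltCurve:
    """Simulate one well's melt curve as baselines + logistic transitions.

    With ``noise_sd = 0`` and ``quench_rate = 0`` the derivative maximum of
    each component sits at its ``tm_true_c`` (up to the mild 1/T² skew of the
    van 't Hoff logistic, well under one grid step at realistic enthalpies).
    The quench factor turns on ``quench_onset_offset_c`` above the highest
    transition temperature — by then the transition is essentially complete,
    so dye release is mimicked without biasing the derivative maximum.
    """
    if not transitions:
        raise ValueError("at least one transition is required")
    grid = DEFAULT_GRID_C if grid_c is None else np.asarray(grid_c, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    if grid[0] < 25.0 - 1e-9 or grid[-1] > 99.0 + 1e-9:
        raise ValueError("temperature grid must lie within [25, 99] °C")
    if quench_rate < 0 or noise_sd < 0:
        raise ValueError("quench_rate and noise_sd must be >= 0")

    signal = baseline_intercept + baseline_slope * grid
    for tr in transitions:
        signal = signal + tr.amplitude * transition_fraction(grid, tr.tm_true_c, tr.dh_vh_kcal)
    t_onset = max(tr.tm_true_c for tr in transitions) + quench_onset_offset_c
    signal = signal * np.exp(-quench_rate * np.maximum(0.0, grid - t_onset))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=grid.shape)
    return MeltCurve(
        well_id=well_id,
        ligand_id=ligand_id,
        concentration_um=concentration_um,
        temperature_c=grid,
        fluorescence=signal,
    )


def _true_tm_c(ligand: LigandSpec, conc_um: float, buffer_tm_c: float) -> float:
    """Ground-truth adopted Tm (°C) of a ligand well at one concentration."""
    if conc_um == 0 or ligand.mode == "inert":
        return buffer_tm_c
    if ligand.mode == "agonist":
        t0_k = buffer_tm_c + CELSIUS_OFFSET
        return binding.predict_tm(conc_um, ligand.kd_true_um, ligand.dh0_true, t0_k) - CELSIUS_OFFSET
    # destabilizer: linear decrease in log10 concentration
    return buffer_tm_c + ligand.destab_slope_k * math.log10(1.0 + conc_um / ligand.destab_ref_um)


def simulate_dose_series(
    ligand: LigandSpec,
    t0_k: float,
    concentrations_um: Sequence[float],
    n_reps: int = 4,
    tm_noise_sd: float = 0.3,
    seed: int = 0,
) -> binding.DoseSeries:
    """Replicate Tm observations across a titration, noise applied to Tm.

    Per replicate, Tm = (Schellman-predicted Tm for agonists) + Gaussian noise;
    replicates are averaged into the returned series.  Ground-truth (Kd, ΔH0)
    are stored on the series for recovery tests.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("dose-series concentrations must be > 0")
    if t0_k <= 0:
        raise ValueError("t0 must be positive")
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    buffer_tm_c = t0_k - CELSIUS_OFFSET
    mean_tm = np.empty_like(conc)
    sem_tm = np.empty_like(conc)
    for i, c in enumerate(conc):
        true_tm_k = _true_tm_c(ligand, float(c), buffer_tm_c) + CELSIUS_OFFSET
        reps = true_tm_k + rng.normal(0.0, tm_noise_sd, size=n_reps)
        mean_tm[i] = reps.mean()
        sem_tm[i] = reps.std(ddof=1) / math.sqrt(n_reps) if n_reps > 1 else 0.0
    return binding.DoseSeries(
        ligand_id=ligand.ligand_id,
        concentrations_um=conc,
        mean_tm_k=mean_tm,
        sem_tm_k=sem_tm,
        n_replicates=n_reps,
        kd_true_um=ligand.kd_true_um,
        dh0_true=ligand.dh0_true,
    )


def simulate_plate(
    plate_map: PlateMap,
    ligand_specs: Sequence[LigandSpec],
    buffer_tm_c: float = DEFAULT_BUFFER_TM_C,
    biphasic: bool = True,
    first_tm_c: float = DEFAULT_FIRST_TM_C,
    first_amplitude: float = 0.6,
    noise_sd: float = 0.002,
    quench_rate: float = 0.01,
    grid_c: np.ndarray | None = None,
    seed: int = 0,
) -> list[MeltCurve]:
    """Simulate every well of a plate, noise applied to fluorescence.

    Buffer wells (concentration 0) carry a single transition at
    ``buffer_tm_c``.  Agonist wells carry the Schellman-shifted second
    transition plus, when ``biphasic`` is on, a fixed ligand-insensitive first
    transition near 50 °C.  Destabilizer and inert wells stay monophasic.
    """
    specs = {s.ligand_id: s for s in ligand_specs}
    missing = sorted(
        {e.ligand_id for e in plate_map if e.concentration_um > 0 and e.ligand_id not in specs}
    )
    if missing:
        raise KeyError(f"plate map references unknown ligand(s): {missing}")
    root = np.random.default_rng(seed)
    curves = []
    for entry in plate_map:
        well_seed = int(root.integers(0, 2**31 - 1))
        if entry.concentration_um == 0 or entry.ligand_id == BUFFER_LIGAND:
            transitions = [TransitionSpec(tm_true_c=buffer_tm_c)]
        else:
            spec = specs[entry.ligand_id]
            tm_c = _true_tm_c(spec, entry.concentration_um, buffer_tm_c)
            transitions = [TransitionSpec(tm_true_c=tm_c)]
            if biphasic and spec.mode == "agonist":
                transitions.insert(
                    0, TransitionSpec(tm_true_c=first_tm_c, amplitude=first_amplitude)
                )
        curves.append(
            simulate_melt_curve(
                transitions,
                noise_sd=noise_sd,
                quench_rate=quench_rate,
                grid_c=grid_c,
                seed=well_seed,
                well_id=entry.well_id,
                ligand_id=entry.ligand_id if entry.concentration_um > 0 else BUFFER_LIGAND,
                concentration_um=entry.concentration_um,
            )
        )
    return curves


def simulate_response_panel(
    ec50s_mm: Mapping[str, float],
    drfu_max: float = DEFAULT_DRFU_MAX,
    concentrations_mm: Sequence[float] = (10.0,),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[ResponsePoint]:
    """Single-concentration receptor responses under a fixed-maximum Hill relation.

    ΔRFU = ΔRFUmax·[L]/(EC50+[L]) plus Gaussian noise; noise may push values
    negative, exercising the downstream negative-response exclusion rule.
    """
    if drfu_max <= 0:
        raise ValueError("drfu_max must be positive")
    rng = np.random.default_rng(seed)
    points = []
    for ligand_id, ec50 in ec50s_mm.items():
        for conc in concentrations_mm:
            drfu = drfu_max * conc / (ec50 + conc)
            if noise_sd > 0:
                drfu += rng.normal(0.0, noise_sd)
            points.append(ResponsePoint(ligand_id=ligand_id, concentration_mm=float(conc), drfu=float(drfu)))
    return points


# ---------------------------------------------------------------------------
# Amino-acid side-chain descriptors from standard published scales:
#   hydrophobicity — Fauchère & Pliška side-chain π (octanol/water logP);
#   hydration      — Wolfenden vapor→water transfer free energy (kcal/mol);
#   polarity       — Grantham polarity;
#   hydropathy     — Kyte & Doolittle index;
#   charge         — formal side-chain charge at pH 7 (His treated neutral);
#   volume         — Zamyatnin residue volume (Å³).
# Proline is omitted: its secondary amine has no side-chain hydration value
# and it is excluded from the affinity regressions in any case.
_DESCRIPTORS = {
    #                   hphob   hydr    pol  hpath  chg    vol
    "glycine":         ( 0.00,   2.39,  9.0, -0.4,   0,   60.1),
    "l-alanine":       ( 0.31,   1.94,  8.1,  1.8,   0,   88.6),
    "l-arginine":      (-1.01, -19.92, 10.5, -4.5,   1,  173.4),
    "l-asparagine":    (-0.60,  -9.68, 11.6, -3.5,   0,  114.1),
    "l-aspartate":     (-0.77, -10.95, 13.0, -3.5,  -1,  111.1),
    "l-cysteine":      ( 1.54,  -1.24,  5.5,  2.5,   0,  108.5),
    "l-glutamine":     (-0.22,  -9.38, 10.5, -3.5,   0,  143.8),
    "l-glutamate":     (-0.64, -10.20, 12.3, -3.5,  -1,  138.4),
    "l-histidine":     ( 0.13, -10.27, 10.4, -3.2,   0,  153.2),
    "l-isoleucine":    ( 1.80,   2.15,  5.2,  4.5,   0,  166.7),
    "l-leucine":       ( 1.70,   2.28,  4.9,  3.8,   0,  166.7),
    "l-lysine":        (-0.99,  -9.52, 11.3, -3.9,   1,  168.6),
    "l-methionine":    ( 1.23,  -1.48,  5.7,  1.9,   0,  162.9),
    "l-phenylalanine": ( 1.79,  -0.76,  5.2,  2.8,   0,  189.9),
    "l-serine":        (-0.04,  -5.06,  9.2, -0.8,   0,   89.0),
    "l-threonine":     ( 0.26,  -4.88,  8.6, -0.7,   0,  116.1),
    "l-tryptophan":    ( 2.25,  -5.88,  5.4, -0.9,   0,  227.8),
    "l-tyrosine":      ( 0.96,  -6.11,  6.2, -1.3,   0,  193.6),
    "l-valine":        ( 1.22,   1.99,  5.9,  4.2,   0,  140.0),
}

DESCRIPTOR_COLUMNS = ("hydrophobicity", "hydration", "polarity", "hydropathy", "charge", "volume")


def builtin_descriptor_table() -> pd.DataFrame:
    """Physicochemical side-chain descriptors for the proteinogenic l-amino acids.

    Returns a DataFrame indexed by ligand id with the six columns documented
    in the module source (standard published scales).
    """
    df = pd.DataFrame.from_dict(_DESCRIPTORS, orient="index", columns=DESCRIPTOR_COLUMNS)
    df = df.astype(float)
    df.index.name = "ligand_id"
    return df
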