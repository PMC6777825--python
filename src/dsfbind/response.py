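"""Single-concentration receptor-response analysis.

Full dose-response titration of the intact receptor is impractical for
low-affinity ligands, so the half-maximal concentration is estimated from a
single response measurement by inverting a Hill relation (coefficient 1) with
the maximal response fixed:

    ΔRFU = ΔRFUmax · [L] / (EC50 + [L])   ⇒   EC50 = [L]·(ΔRFUmax − ΔRFU)/ΔRFU

Responses at or below zero are excluded; responses at or above the fixed
maximum cannot yield a finite estimate and are flagged saturated.  p-scales
are on a molar basis throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ResponsePoint", "EC50Estimate", "estimate_ec50", "to_p_scale"]

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6}


@dataclass(frozen=True)
class ResponsePoint:
    """Baseline-subtracted maximal receptor response to one ligand dose."""

    ligand_id: str
    concentration_mm: float
    drfu: float

    def __post_init__(self) -> None:
        if self.concentration_mm <= 0:
            raise ValueError("response concentration must be positive")


@dataclass(frozen=True)
class EC50Estimate:
    ligand_id: str
    ec50_est_mm: float | None
    status: str  # ok | negative_excluded | saturated
    pec50: float | None

    @property
    def usable(self) -> bool:
        return self.status == "ok"


def to_p_scale(value: float, unit: str = "M") -> float:
    """−log10 of a concentration expressed in mol·L⁻¹ (units: M, mM, uM)."""
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown concentration unit {unit!r}")
    if value <= 0:
        raise ValueError("p-scale requires a positive concentration")
    return -math.log10(value * _UNIT_TO_MOLAR[unit])


def estimate_ec50(point: ResponsePoint, drfu_max: float = 104.3) -> EC50Estimate:
    """Invert the fixed-maximum Hill relation at one concentration.

    Non-positive responses → ``negative_excluded``; responses at or above
    ``drfu_max`` → ``saturated``; otherwise an estimate with its molar-basis
    pEC50.  Degenerate inputs are statuses, not exceptions.
    """
    if drfu_max <= 0:
        raise ValueError("drfu_max must be positive")
    if point.drfu <= 0:
        return EC50Estimate(point.ligand_id, None, "negative_excluded", None)
    if point.drfu >= drfu_max:
        return EC50Estimate(point.ligand_id, None, "saturated", None)
    ec50 = point.concentration_mm * (drfu_max - point.drfu) / point.drfu
    return EC50Estimate(point.ligand_id, ec50, "ok", to_p_scale(ec50, "mM"))
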