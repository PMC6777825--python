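"""Binding-vs-response correlation and descriptor (QSAR) regression.

Two association analyses close the pipeline:

* :func:`correlate_binding_response` — does thermal stabilization of the
  isolated ligand-binding domain track activation of the intact receptor?
  Either raw (ΔTm at a shared concentration vs ΔRFU) or p-scaled
  (pKd from the adopted single-point estimates vs pEC50, usable entries only).
* :func:`qsar_search` — classical QSAR: ordinary least squares of pKd on
  every subset of one or two physicochemical side-chain descriptors, each
  model judged by its overall F test.  Enumeration is capped at two terms
  (standard practice at n ≈ 15); the number of models tried is reported but
  no multiplicity correction is applied, matching classical usage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .binding import SinglePointEstimate
from .response import EC50Estimate, ResponsePoint

__all__ = [
    "CorrelationResult",
    "QSARFit",
    "QSARSearchResult",
    "pearson_r",
    "correlate_binding_response",
    "qsar_search",
]

logger = logging.getLogger(__name__)

MODE_RAW = "dTm_vs_dRFU"
MODE_P = "pKd_vs_pEC50"


@dataclass(frozen=True)
class CorrelationResult:
    mode: str
    n: int
    r: float
    pairs: tuple[str, ...]
    exclusions: Mapping[str, str]
    x: tuple[float, ...] = ()
    y: tuple[float, ...] = ()


@dataclass(frozen=True)
class QSARFit:
    terms: tuple[str, ...]
    coefficients: Mapping[str, float]
    intercept: float
    r: float
    s: float
    f_statistic: float
    p_value: float
    n: int
    significant: bool


@dataclass(frozen=True)
class QSARSearchResult:
    fits: tuple[QSARFit, ...]
    n_models_tried: int
    skipped: tuple[tuple[str, ...], ...] = ()

    def __iter__(self):
        return iter(self.fits)

    @property
    def any_significant(self) -> bool:
        return any(f.significant for f in self.fits)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(x, y).statistic)


def correlate_binding_response(
    binding_estimates: Sequence[SinglePointEstimate],
    responses: Sequence[ResponsePoint] | Sequence[EC50Estimate],
    mode: str = MODE_P,
    concentration_mm: float = 10.0,
) -> CorrelationResult:
    """Correlate per-ligand binding readouts with receptor-response readouts.

    Ligands are inner-joined on their id.  In raw mode, the ΔTm observed at
    ``concentration_mm`` is paired with the ΔRFU at that same concentration
    (destabilized ligands contribute their negative shifts).  In p-scale
    mode, pKd from usable adopted estimates is paired with pEC50 from
    status-ok estimates; everything else is excluded with a recorded reason.
    """
    exclusions: dict[str, str] = {}
    if mode == MODE_RAW:
        xmap: dict[str, float] = {}
        for e in binding_estimates:
            if abs(e.concentration_um - concentration_mm * 1000.0) < 1e-6:
                xmap[e.ligand_id] = e.delta_tm_k
        ymap = {
            p.ligand_id: p.drfu
            for p in responses
            if isinstance(p, ResponsePoint) and abs(p.concentration_mm - concentration_mm) < 1e-9
        }
    elif mode == MODE_P:
        xmap = {}
        for e in binding_estimates:
            if e.usable and e.pkd is not None:
                xmap[e.ligand_id] = e.pkd
            else:
                exclusions[e.ligand_id] = e.selection_reason or f"binding window {e.window}"
        ymap = {}
        for est in responses:
            if not isinstance(est, EC50Estimate):
                raise TypeError("p-scale mode requires EC50Estimate responses")
            if est.usable:
                ymap[est.ligand_id] = est.pec50
            else:
                exclusions.setdefault(est.ligand_id, f"response {est.status}")
    else:
        raise ValueError(f"unknown correlation mode {mode!r}")

    shared = sorted(set(xmap) & set(ymap))
    for lig in sorted((set(xmap) | set(ymap)) - set(shared)):
        exclusions.setdefault(lig, "missing partner measurement")
    if not shared:
        raise ValueError("no ligands shared between binding and response tables")
    x = [xmap[l] for l in shared]
    y = [ymap[l] for l in shared]
    r = pearson_r(x, y)
    for lig, reason in exclusions.items():
        logger.info("correlation %s: excluded %s (%s)", mode, lig, reason)
    return CorrelationResult(
        mode=mode, n=len(shared), r=r, pairs=tuple(shared), exclusions=exclusions,
        x=tuple(x), y=tuple(y),
    )


def qsar_search(
    pkd: Mapping[str, float],
    descriptors: pd.DataFrame,
    max_terms: int = 2,
    alpha: float = 0.05,
    cond_threshold: float = 1e8,
) -> QSARSearchResult:
    """Enumerate OLS models of pKd on 1- and 2-descriptor subsets.

    Each model reports the multiple correlation coefficient r, the standard
    error of estimate s, the overall F statistic with its p-value, and a
    significance flag at ``alpha``.  Subsets whose design matrix is
    near-collinear (condition number above ``cond_threshold``) are skipped
    with a log entry.  Fits are ranked by r, descending.
    """
    ligands = sorted(set(pkd) & set(descriptors.index))
    n = len(ligands)
    if n < 6:
        raise ValueError(f"need >= 6 ligands with complete data, got {n}")
    sub = descriptors.loc[ligands]
    if sub.isna().any().any():
        raise ValueError("descriptor table has missing cells for analyzed ligands")
    y = np.array([pkd[l] for l in ligands])

    fits: list[QSARFit] = []
    skipped: list[tuple[str, ...]] = []
    n_tried = 0
    cols = list(descriptors.columns)
    for k in range(1, max_terms + 1):
        for terms in itertools.combinations(cols, k):
            X = sub.loc[:, list(terms)].to_numpy()
            design = sm.add_constant(X)
            if np.linalg.cond(design) > cond_threshold:
                skipped.append(terms)
                logger.info("qsar: skipping collinear subset %s", terms)
                continue
            n_tried += 1
            res = sm.OLS(y, design).fit()
            coefs = {t: float(c) for t, c in zip(terms, res.params[1:])}
            fits.append(
                QSARFit(
                    terms=terms,
                    coefficients=coefs,
                    intercept=float(res.params[0]),
                    r=float(np.sqrt(max(res.rsquared, 0.0))),
                    s=float(np.sqrt(res.scale)),
                    f_statistic=float(res.fvalue),
                    p_value=float(res.f_pvalue),
                    n=n,
                    significant=bool(res.f_pvalue < alpha),
                )
            )
    fits.sort(key=lambda f: f.r, reverse=True)
    logger.info("qsar: %d models tried, %d skipped", n_tried, len(skipped))
    return QSARSearchResult(fits=tuple(fits), n_models_tried=n_tried, skipped=tuple(skipped))
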