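"""End-to-end runner: melt curves → Tm/ΔTm → Kd → EC50 → association.

Stage order mirrors the assay workflow: call apparent Tm per well, establish
T0 from buffer-only wells (or a fixed value), summarize technical replicates,
fit full dose series where enough concentrations exist, invert single-point
estimates and apply the adoption rules, analyze the response panel, then
correlate and run the descriptor regression.  Stages degrade gracefully:
absent optional inputs mark their report sections absent, and per-ligand
failures are recorded, not fatal.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import binding, meltcurve, response as response_mod
from .association import MODE_P, MODE_RAW, correlate_binding_response, qsar_search
from .config import PipelineConfig
from .constants import CELSIUS_OFFSET
from .meltcurve import MeltCurve, TmCall

__all__ = ["run_pipeline", "write_report"]

logger = logging.getLogger(__name__)


def _call_all(curves: Sequence[MeltCurve], config: PipelineConfig) -> list[TmCall]:
    calls = []
    for curve in curves:
        calls.append(
            meltcurve.call_tm(
                curve,
                prominence_frac=config.prominence_frac,
                min_separation_c=config.min_separation_c,
                smooth_window_c=config.smooth_window_c,
                noise_floor_mads=config.noise_floor_mads,
                peak_floor_mads=config.peak_floor_mads,
            )
        )
    return calls


def _t0_from_calls(calls: Sequence[TmCall], config: PipelineConfig) -> float:
    if config.t0_source == "fixed":
        return config.t0_fixed_k
    buffer_tms = [
        c.adopted_tm_c for c in calls
        if c.usable and (c.concentration_um == 0 or c.ligand_id == meltcurve.BUFFER_LIGAND)
    ]
    if not buffer_tms:
        raise ValueError("no usable buffer-only wells to establish T0; use t0_source='fixed'")
    return float(np.mean(buffer_tms)) + CELSIUS_OFFSET


def run_pipeline(
    config: PipelineConfig,
    curves: Sequence[MeltCurve],
    response_points: Sequence[response_mod.ResponsePoint] | None = None,
    descriptor_table: pd.DataFrame | None = None,
    response_concentration_mm: float = 10.0,
) -> dict:
    """Run every applicable stage and return a JSON-serializable report."""
    if not curves:
        raise ValueError("at least a melt table is required")
    report: dict = {"seed": config.seed, "stages": {}}

    calls = _call_all(curves, config)
    t0_k = _t0_from_calls(calls, config)
    report["t0_K"] = round(t0_k, 4)
    report["stages"]["tm_calls"] = [
        {
            "well": c.well_id,
            "ligand": c.ligand_id,
            "conc_uM": c.concentration_um,
            "tm_C": None if c.adopted_tm_c is None else round(c.adopted_tm_c, 4),
            "biphasic": c.biphasic,
            "delta_tm_K": None
            if c.adopted_tm_c is None
            else round(c.adopted_tm_c + CELSIUS_OFFSET - t0_k, 4),
            "qc_flags": list(c.qc_flags),
        }
        for c in calls
    ]

    summaries = meltcurve.group_and_summarize(calls)
    report["stages"]["replicate_summaries"] = [
        {
            "ligand": s.ligand_id,
            "conc_uM": s.concentration_um,
            "mean_tm_K": round(s.mean_tm_k, 4),
            "sem_tm_K": None if s.sem_tm_k is None else round(s.sem_tm_k, 4),
            "n": s.n,
        }
        for s in summaries
    ]

    # dose-series fits per ligand (>= 4 ligand concentrations)
    by_ligand: dict[str, list[meltcurve.ReplicateSummary]] = defaultdict(list)
    for s in summaries:
        if s.concentration_um > 0:
            by_ligand[s.ligand_id].append(s)
    fits = {}
    errors: dict[str, str] = {}
    for ligand, group in sorted(by_ligand.items()):
        if len(group) < 4:
            continue
        series = binding.DoseSeries(
            ligand_id=ligand,
            concentrations_um=np.array([s.concentration_um for s in group]),
            mean_tm_k=np.array([s.mean_tm_k for s in group]),
        )
        try:
            fit = binding.fit_dose_series(series, t0_k=t0_k)
            fits[ligand] = {
                "kd_app_uM": fit.kd_app_um,
                "dh0_kcal": fit.dh0_kcal,
                "se_kd_uM": fit.se_kd_um,
                "se_dh0_kcal": fit.se_dh0_kcal,
                "converged": fit.converged,
                "residual_rms_K": fit.residual_rms_k,
                "n_points": fit.n_points,
            }
        except ValueError as exc:
            errors[ligand] = str(exc)
            logger.warning("dose-series fit failed for %s: %s", ligand, exc)
    report["stages"]["schellman_fits"] = fits

    # single-point estimates + adoption rule
    estimates_by_ligand: dict[str, list[binding.SinglePointEstimate]] = defaultdict(list)
    for s in by_ligand:
        for summ in by_ligand[s]:
            est = binding.estimate_kd_single_point(
                delta_tm_k=summ.mean_tm_k - t0_k,
                concentration_um=summ.concentration_um,
                t0_k=config.t0_fixed_k if config.t0_source == "fixed" else t0_k,
                dh0_kcal=config.dh0_kcal,
                ligand_id=s,
            )
            estimates_by_ligand[s].append(est)
    selected = {}
    selected_objs: list[binding.SinglePointEstimate] = []
    all_estimates: list[binding.SinglePointEstimate] = []
    for ligand, ests in sorted(estimates_by_ligand.items()):
        all_estimates.extend(ests)
        chosen = binding.select_reporting_estimate(ests)
        selected_objs.append(chosen)
        selected[ligand] = {
            "conc_uM": chosen.concentration_um,
            "delta_tm_K": round(chosen.delta_tm_k, 4),
            "kd_app_uM": chosen.kd_app_um,
            "pKd": chosen.pkd,
            "window": chosen.window,
            "usable": chosen.usable,
            "reason": chosen.selection_reason,
        }
        logger.info("ligand %s: %s", ligand, chosen.selection_reason)
    report["stages"]["single_point"] = selected
    report["stages"]["errors"] = errors

    if response_points:
        ec50s = [response_mod.estimate_ec50(p, drfu_max=config.drfu_max) for p in response_points]
        report["stages"]["ec50"] = {
            e.ligand_id: {"ec50_mM": e.ec50_est_mm, "status": e.status, "pEC50": e.pec50}
            for e in ec50s
        }
        correlations = {}
        try:
            raw = correlate_binding_response(
                all_estimates, response_points, mode=MODE_RAW,
                concentration_mm=response_concentration_mm,
            )
            correlations[MODE_RAW] = {"n": raw.n, "r": round(raw.r, 4)}
        except (ValueError, TypeError) as exc:
            correlations[MODE_RAW] = {"error": str(exc)}
        try:
            pmode = correlate_binding_response(selected_objs, ec50s, mode=MODE_P)
            correlations[MODE_P] = {"n": pmode.n, "r": round(pmode.r, 4)}
        except (ValueError, TypeError) as exc:
            correlations[MODE_P] = {"error": str(exc)}
        report["stages"]["correlations"] = correlations
    else:
        report["stages"]["ec50"] = None
        report["stages"]["correlations"] = None

    if descriptor_table is not None:
        pkd = {e.ligand_id: e.pkd for e in selected_objs if e.usable and e.pkd is not None}
        try:
            search = qsar_search(pkd, descriptor_table)
            report["stages"]["qsar"] = {
                "n_models_tried": search.n_models_tried,
                "any_significant": search.any_significant,
                "top": [
                    {
                        "terms": list(f.terms),
                        "r": round(f.r, 4),
                        "s": round(f.s, 4),
                        "F": round(f.f_statistic, 4),
                        "p": round(f.p_value, 6),
                        "significant": f.significant,
                    }
                    for f in search.fits[:5]
                ],
            }
        except ValueError as exc:
            report["stages"]["qsar"] = {"error": str(exc)}
    else:
        report["stages"]["qsar"] = None

    return report


def write_report(report: Mapping, path: str | Path) -> None:
    """Deterministic JSON serialization (sorted keys, fixed float handling)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
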