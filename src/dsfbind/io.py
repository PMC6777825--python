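"""Plain-text I/O: long-format melt-curve CSV, plate maps, response panels.

File conventions (column units are explicit in the names):

* melt curves — CSV ``well,temperature_C,fluorescence``, long format;
* plate map — CSV ``well,ligand,conc_uM`` (buffer wells: conc 0);
* response panel — CSV ``ligand,conc_mM,dRFU``;
* descriptor table — CSV with ``ligand_id`` index column.

Temperatures are °C in files and kelvin inside the analysis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .meltcurve import BUFFER_LIGAND, MeltCurve, TmCall
from .response import ResponsePoint

__all__ = [
    "read_melt_table",
    "write_melt_table",
    "read_response_table",
    "write_response_table",
    "read_descriptor_table",
    "write_tm_calls",
]

logger = logging.getLogger(__name__)

MELT_COLUMNS = ["well", "temperature_C", "fluorescence"]
MAP_COLUMNS = ["well", "ligand", "conc_uM"]
RESPONSE_COLUMNS = ["ligand", "conc_mM", "dRFU"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_melt_table(path: str | Path, plate_map_path: str | Path) -> list[MeltCurve]:
    """Read long-format melt curves joined to their plate-map annotations.

    Out-of-order temperatures are sorted with a warning; duplicate
    (well, temperature) rows and wells absent from the map are errors.
    """
    df = pd.read_csv(path)
    _require_columns(df, MELT_COLUMNS, path)
    pmap = pd.read_csv(plate_map_path)
    _require_columns(pmap, MAP_COLUMNS, plate_map_path)
    for col in ("temperature_C", "fluorescence"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric values in column {col!r}")
    if df.duplicated(subset=["well", "temperature_C"]).any():
        dupes = df[df.duplicated(subset=["well", "temperature_C"])]["well"].unique()
        raise ValueError(f"{path}: duplicate (well, temperature) rows in well(s) {list(dupes)}")
    annot = pmap.set_index("well")
    if annot.index.duplicated().any():
        raise ValueError(f"{plate_map_path}: duplicate wells in plate map")

    curves = []
    for well, grp in df.groupby("well", sort=True):
        if well not in annot.index:
            raise KeyError(f"well {well!r} present in melt table but missing from plate map")
        temps = grp["temperature_C"].to_numpy()
        if np.any(np.diff(temps) <= 0):
            logger.warning("well %s: temperatures out of order; sorting", well)
            grp = grp.sort_values("temperature_C")
        conc = float(annot.loc[well, "conc_uM"])
        ligand = str(annot.loc[well, "ligand"]) if conc > 0 else BUFFER_LIGAND
        curves.append(
            MeltCurve(
                well_id=str(well),
                ligand_id=ligand,
                concentration_um=conc,
                temperature_c=grp["temperature_C"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return curves


def write_melt_table(
    curves: Iterable[MeltCurve], path: str | Path, plate_map_path: str | Path
) -> None:
    """Write curves as long-format CSV plus the matching plate-map CSV."""
    curves = list(curves)
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "well": c.well_id,
                    "temperature_C": c.temperature_c,
                    "fluorescence": c.fluorescence,
                }
            )
            for c in curves
        ],
        ignore_index=True,
    )
    long.to_csv(path, index=False, float_format="%.6g")
    pmap = pd.DataFrame(
        {
            "well": [c.well_id for c in curves],
            "ligand": [c.ligand_id for c in curves],
            "conc_uM": [c.concentration_um for c in curves],
        }
    )
    pmap.to_csv(plate_map_path, index=False, float_format="%.6g")


def read_response_table(path: str | Path) -> list[ResponsePoint]:
    df = pd.read_csv(path)
    _require_columns(df, RESPONSE_COLUMNS, path)
    return [
        ResponsePoint(ligand_id=str(r.ligand), concentration_mm=float(r.conc_mM), drfu=float(r.dRFU))
        for r in df.itertuples()
    ]


def write_response_table(points: Iterable[ResponsePoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "ligand": [p.ligand_id for p in points],
            "conc_mM": [p.concentration_mm for p in points],
            "dRFU": [p.drfu for p in points],
        }
    ).to_csv(path, index=False, float_format="%.6g")


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="ligand_id")
    return df.astype(float)


def write_tm_calls(calls: Iterable[TmCall], path: str | Path) -> None:
    """TSV of per-well Tm calls for audit: one row per well."""
    rows = [
        {
            "well": c.well_id,
            "ligand": c.ligand_id,
            "conc_uM": c.concentration_um,
            "tm_C": c.adopted_tm_c,
            "biphasic": c.biphasic,
            "delta_tm_K": c.delta_tm_k,
            "qc_flags": ";".join(c.qc_flags),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
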