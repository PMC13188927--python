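"""CSV/TSV/JSON file formats and deterministic result serialization.

All tables are plain CSV with unit-suffixed headers (``e0_nM``,
``s0_mg_per_mL``, ``v0_nM_per_s`` ...); recognized unit suffixes are
converted to the package's canonical units on read.  Floats are written
with 17 significant digits so write→read round-trips are lossless, and
outputs contain no timestamps, making reruns byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import BindingDataset, RateDataset
from .groupstats import GroupData

__all__ = [
    "read_rate_table",
    "read_rate_tables",
    "read_binding_table",
    "read_groups_table",
    "write_rate_table",
    "write_binding_table",
    "write_results",
]

# unit suffix -> factor into canonical units (nM, mg/mL, nM/s, µM)
_E0_UNITS = {"nm": 1.0, "um": 1000.0, "pm": 1e-3}
_S0_UNITS = {"mg_per_ml": 1.0, "g_per_l": 1.0}
_V0_UNITS = {"nm_per_s": 1.0, "um_per_s": 1000.0, "nm_per_min": 1.0 / 60.0}
_EUM_UNITS = {"um": 1.0, "nm": 1e-3}

_FLOAT_FMT = "%.17g"


def _find_unit_column(frame: pd.DataFrame, stem: str, units: dict, path) -> tuple[str, float]:
    for col in frame.columns:
        low = col.strip().lower()
        if low.startswith(stem + "_"):
            suffix = low[len(stem) + 1:]
            if suffix in units:
                return col, units[suffix]
            raise ValueError(
                f"{path}: unrecognized unit suffix {suffix!r} on column {col!r}")
    raise ValueError(f"{path}: missing required column {stem}_<unit>")


def _numeric(frame: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(frame[col], errors="coerce")
    if vals.isna().any():
        # +2: header line plus 1-based row numbering
        row = int(vals.index[vals.isna()][0]) + 2
        raise ValueError(
            f"{path}: non-numeric or missing value in column {col!r}, row {row}")
    return vals.to_numpy(dtype=float)


def read_rate_tables(path) -> list[RateDataset]:
    """Read a rates CSV, one dataset per enzyme×substrate×mode group.

    Required columns: enzyme, substrate, mode, replicate, and unit-suffixed
    e0, s0, v0.  Mode invariants (constant e0 under CMM, constant load
    under IMM) are enforced with row-level error messages.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("enzyme", "substrate", "mode", "replicate"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    e0_col, e0_f = _find_unit_column(frame, "e0", _E0_UNITS, path)
    s0_col, s0_f = _find_unit_column(frame, "s0", _S0_UNITS, path)
    v0_col, v0_f = _find_unit_column(frame, "v0", _V0_UNITS, path)
    e0 = _numeric(frame, e0_col, path) * e0_f
    s0 = _numeric(frame, s0_col, path) * s0_f
    v0 = _numeric(frame, v0_col, path) * v0_f

    datasets = []
    for (enz, sub, mode), grp in frame.groupby(["enzyme", "substrate", "mode"],
                                               sort=True):
        idx = grp.index.to_numpy()
        try:
            ds = RateDataset(mode=str(mode), enzyme=str(enz),
                             substrate=str(sub), e0=e0[idx], mass_s0=s0[idx],
                             v0=v0[idx],
                             replicate=grp["replicate"].to_numpy())
        except ValueError as exc:
            raise ValueError(
                f"{path}: invalid dataset {enz}×{sub} [{mode}] "
                f"(rows {idx[0] + 2}–{idx[-1] + 2}): {exc}") from exc
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"{path}: no data rows")
    return datasets


def read_rate_table(path) -> RateDataset:
    """Read a rates CSV that must contain exactly one dataset."""
    datasets = read_rate_tables(path)
    if len(datasets) != 1:
        raise ValueError(
            f"{path}: expected a single enzyme×substrate×mode group, "
            f"found {len(datasets)}")
    return datasets[0]


def read_binding_table(path) -> list[BindingDataset]:
    """Read an adsorption CSV: enzyme, substrate, replicate, e0, efree, s0."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("enzyme", "substrate", "replicate"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    e0_col, e0_f = _find_unit_column(frame, "e0", _EUM_UNITS, path)
    ef_col, ef_f = _find_unit_column(frame, "efree", _EUM_UNITS, path)
    s0_col, s0_f = _find_unit_column(frame, "s0", _S0_UNITS, path)
    e0 = _numeric(frame, e0_col, path) * e0_f
    ef = _numeric(frame, ef_col, path) * ef_f
    s0 = _numeric(frame, s0_col, path) * s0_f
    out = []
    for (enz, sub), grp in frame.groupby(["enzyme", "substrate"], sort=True):
        idx = grp.index.to_numpy()
        try:
            out.append(BindingDataset(e0=e0[idx], e_free=ef[idx],
                                      mass_s0=s0[idx],
                                      replicate=grp["replicate"].to_numpy(),
                                      enzyme=str(enz), substrate=str(sub)))
        except ValueError as exc:
            raise ValueError(
                f"{path}: invalid binding data {enz}×{sub} "
                f"(rows {idx[0] + 2}–{idx[-1] + 2}): {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no data rows")
    return out


def read_groups_table(path, alpha: float = 0.05) -> GroupData:
    """Read a groups CSV (columns: group, value) for the post-hoc tests."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("group", "value"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    _numeric(frame, "value", path)
    return GroupData.from_frame(frame, alpha=alpha)


def write_rate_table(ds: RateDataset, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame({
        "enzyme": ds.enzyme_name, "substrate": ds.substrate_name,
        "mode": ds.mode, "e0_nM": ds.e0, "s0_mg_per_mL": ds.mass_s0,
        "v0_nM_per_s": ds.v0, "replicate": ds.replicate,
    })
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_binding_table(ds: BindingDataset, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame({
        "enzyme": str(ds.enzyme) or "enzyme",
        "substrate": str(ds.substrate) or "substrate",
        "e0_uM": ds.e0, "efree_uM": ds.e_free, "s0_mg_per_mL": ds.mass_s0,
        "replicate": ds.replicate,
    })
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results, outdir, *, config: dict | None = None,
                  seed: int | None = None) -> dict:
    """Write the pipeline report: parameters.tsv, panel.json, run.log.

    ``results`` is a list of EnzymeSubstrateResult.  The JSON panel carries
    the machine-readable parameter set per enzyme×substrate plus the run
    configuration and seed; all three files are byte-stable across reruns
    of identical input.
    """
    from .pipeline import report as build_report

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep = build_report(results)

    params_path = outdir / "parameters.tsv"
    rep["parameters"].to_csv(params_path, sep="\t", index=False,
                             float_format=_FLOAT_FMT)

    panel = {
        "seed": seed,
        "config": _jsonable(config) if config else None,
        "results": rep["parameters"].to_dict(orient="records"),
        "folds": (rep["folds"].to_dict(orient="records")
                  if rep["folds"] is not None else None),
    }
    panel_path = outdir / "panel.json"
    panel_path.write_text(json.dumps(_jsonable(panel), indent=2,
                                     sort_keys=True) + "\n")

    log_path = outdir / "run.log"
    lines = [f"starchkin pipeline run", f"seed: {seed}",
             f"n_results: {len(results)}"]
    if config:
        lines.append("config: " + json.dumps(_jsonable(config), sort_keys=True))
    for r in sorted(results, key=lambda r: (r.enzyme, r.substrate)):
        lines.append(f"{r.enzyme}×{r.substrate}: flags={list(r.flags)}")
    log_path.write_text("\n".join(lines) + "\n")
    return {"parameters": params_path, "panel": panel_path, "log": log_path}
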