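"""Delimited-text interchange for spectra, grid results and configs.

Spectra travel as CSV: one row per spectrum; first column ``label``,
optional second column ``batch``, remaining p columns the intensities.
The header row carries the grid values as the intensity column names; a
header-less read generates an equally spaced [0, 1] grid instead.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import SimulationConfig, SpectraMatrix
from .evaluation import ComparisonGrid

__all__ = [
    "read_spectra",
    "write_spectra",
    "write_grid_results",
    "read_grid_results",
    "write_config_sidecar",
    "read_config_sidecar",
]

GRID_RESULT_COLUMNS = [
    "shift", "snr", "sens_pca", "sd_pca", "sens_fpca", "sd_fpca", "diff", "kw_p",
]


def write_spectra(spectra: SpectraMatrix, path) -> None:
    cols = {"label": spectra.labels}
    if spectra.batches is not None:
        cols["batch"] = spectra.batches
    df = pd.DataFrame(cols)
    grid_cols = [repr(float(g)) for g in spectra.grid]
    df = pd.concat(
        [df, pd.DataFrame(spectra.intensities, columns=grid_cols)], axis=1
    )
    # 17 significant digits round-trip IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra(path, has_batches: bool = False, grid_header: bool = True) -> SpectraMatrix:
    """Parse a spectra CSV; raises with row numbers on malformed input."""
    path = Path(path)
    df = pd.read_csv(
        path, header=0 if grid_header else None, float_precision="round_trip"
    )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected a label column plus >= 2 intensity columns")
    first_data = 2 if has_batches else 1
    labels = df.iloc[:, 0].to_numpy()
    batches = df.iloc[:, 1].to_numpy() if has_batches else None
    values = df.iloc[:, first_data:]
    bad = values.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna().any(axis=1)
    if bad.any():
        rows = ", ".join(str(i) for i in np.flatnonzero(bad.to_numpy())[:10])
        raise ValueError(f"{path}: non-numeric or missing intensities in row(s) {rows}")
    intensities = values.to_numpy(dtype=float)
    p = intensities.shape[1]
    if grid_header:
        try:
            grid = np.array([float(c) for c in values.columns])
        except ValueError as exc:
            raise ValueError(
                f"{path}: intensity column headers must be numeric grid values "
                "(pass grid_header=False for header-less files)"
            ) from exc
    else:
        grid = np.linspace(0.0, 1.0, p)
    return SpectraMatrix(
        intensities=intensities, grid=grid, labels=labels, batches=batches
    )


def write_grid_results(grid: ComparisonGrid, path) -> None:
    """One CSV row per (shift, snr); missing cells become empty fields."""
    df = grid.table.reindex(columns=GRID_RESULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_grid_results(path) -> ComparisonGrid:
    return ComparisonGrid(table=pd.read_csv(path, float_precision="round_trip"))


def write_config_sidecar(config: SimulationConfig, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2) + "\n")


def read_config_sidecar(path) -> SimulationConfig:
    d = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    d["domain"] = tuple(d["domain"])
    d["peaks"] = tuple(tuple(pk) for pk in d["peaks"])
    d["background_scale"] = tuple(d["background_scale"])
    return SimulationConfig(**d)
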