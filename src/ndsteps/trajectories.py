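"""Harmonizing heterogeneous studies onto a common age grid.

Studies report incidence on different age-bin schemes.  Each study's
trajectory (bin-midpoint age, incidence) is modelled with a natural
cubic spline and evaluated at shared grid ages; trajectories are never
extrapolated outside a study's observed midpoint range (cells are marked
missing instead).  Per stratum, the study trajectories are averaged at
each covered grid age, yielding the d x a incidence matrix I whose
element I(i, j) is the incidence of stratum i at grid age j.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import IncidenceDataset, group_by_stratum

#: Default common age grid: integer ages 30..79 inclusive.
DEFAULT_AGE_GRID = tuple(float(a) for a in range(30, 80))


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """One dataset's incidence evaluated on a common age grid.

    ``values`` are NaN outside the dataset's observed midpoint range (no
    extrapolation); negative spline excursions are clipped to 0.
    """

    label: str
    study_id: str
    age_grid: tuple[float, ...]
    values: tuple[float, ...]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.age_grid), name=self.study_id)


def spline_interpolate(
    dataset: IncidenceDataset, age_grid: Sequence[float] = DEFAULT_AGE_GRID
) -> Trajectory:
    """Interpolate one dataset onto ``age_grid`` with a natural cubic spline.

    The spline passes through (bin midpoint, incidence) knots with
    second-derivative-zero boundary conditions.  Datasets with only 2
    bins fall back to linear interpolation.  Grid ages outside the
    midpoint range are NaN; negative excursions are clipped to 0.
    """
    grid = np.asarray(list(age_grid), dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("age_grid must be non-empty and strictly increasing")
    mids = np.asarray(dataset.midpoints())
    vals = np.asarray(dataset.incidences())
    inside = (grid >= mids[0]) & (grid <= mids[-1])
    out = np.full(grid.shape, np.nan)
    if not inside.any():
        import warnings

        warnings.warn(
            f"dataset {dataset.study_id}: no overlap between age grid "
            f"[{grid[0]}, {grid[-1]}] and midpoint range [{mids[0]}, {mids[-1]}]",
            stacklevel=2,
        )
    elif len(mids) >= 3:
        spline = CubicSpline(mids, vals, bc_type="natural")
        out[inside] = np.clip(spline(grid[inside]), 0.0, None)
    else:
        out[inside] = np.interp(grid[inside], mids, vals)
    return Trajectory(
        label=dataset.label,
        study_id=dataset.study_id,
        age_grid=tuple(grid),
        values=tuple(out),
    )


@dataclasses.dataclass(frozen=True)
class IncidenceMatrix:
    """The d x a harmonized incidence matrix.

    ``values``: DataFrame, rows = stratum labels (sorted), columns = grid
    ages; cell (i, j) is the mean over studies of stratum i covering age
    j, NaN where no study covers it.  ``coverage`` counts contributing
    studies per cell.
    """

    values: pd.DataFrame
    coverage: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def age_grid(self) -> list[float]:
        return list(self.values.columns)

    def complete_case(self) -> pd.DataFrame:
        """Columns (ages) covered by every stratum, with all values > 0."""
        ok = self.values.notna().all(axis=0) & (self.values > 0).all(axis=0)
        return self.values.loc[:, ok]

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.values.rename_axis("stratum").to_csv(fh)
        return path

    def coverage_to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            label: {str(age): int(c) for age, c in row.items()}
            for label, row in self.coverage.iterrows()
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def build_incidence_matrix(
    panel: Iterable[IncidenceDataset], age_grid: Sequence[float] = DEFAULT_AGE_GRID
) -> IncidenceMatrix:
    """Average per-study spline trajectories into the d x a matrix.

    Rows are stratum labels in sorted order; averaging is a plain mean
    over the studies covering each grid age, so it is invariant to study
    order.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty panel")
    grid = [float(a) for a in age_grid]
    by_stratum = group_by_stratum(panel)
    rows, cov_rows = {}, {}
    for label, dsets in by_stratum.items():
        stack = np.vstack(
            [spline_interpolate(ds, grid).values for ds in dsets]
        )
        covered = ~np.isnan(stack)
        counts = covered.sum(axis=0)
        sums = np.where(covered, stack, 0.0).sum(axis=0)
        rows[label] = np.divide(
            sums, counts, out=np.full(counts.shape, np.nan), where=counts > 0
        )
        cov_rows[label] = covered.sum(axis=0)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=grid)
    coverage = pd.DataFrame.from_dict(cov_rows, orient="index", columns=grid)
    return IncidenceMatrix(values=values.sort_index(), coverage=coverage.sort_index())


def dataset_profile_table(
    panel: Iterable[IncidenceDataset], age_grid: Sequence[float] = DEFAULT_AGE_GRID
) -> pd.DataFrame:
    """Per-dataset profile table: rows = study IDs, columns = grid ages.

    Only complete-case columns (covered by every dataset, all values
    positive) are retained — the input expected by the embedding stage.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty panel")
    grid = [float(a) for a in age_grid]
    rows = {
        ds.study_id: spline_interpolate(ds, grid).values for ds in sorted(
            panel, key=lambda d: d.study_id
        )
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=grid)
    ok = table.notna().all(axis=0) & (table > 0).all(axis=0)
    return table.loc[:, ok]
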