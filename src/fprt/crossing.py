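"""Density-difference curves and per-subject crossing points.

Under the binary-mixture hypothesis every pair of condition densities
crosses at the same RT (the fixed point t0), so the zero crossings of all
pairwise density-difference curves should coincide.  This module estimates
those crossings per subject: a shared KDE grid over the subject's pooled
RTs, one density per condition, pointwise differences per condition pair,
and a zero crossing per difference curve.

Noisy KDE tails can produce spurious sign changes far from the modes.  The
crossing search is therefore restricted to a window spanning the union of
the two conditions' interquartile ranges, widened by one bandwidth on each
side, and among the candidate crossings the one with the steepest slope of
the difference curve is returned: the theoretically meaningful crossing
separates the two modes, where the difference curve changes fastest.  (A
narrower inter-median window is not safe: for strongly skewed mixtures the
common crossing can lie below both condition medians.)
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .density import DEFAULT_GRID_SIZE, DensityEstimate, kde, select_bandwidth, shared_grid
from .io import RTDataset

__all__ = [
    "DesignError",
    "DifferenceCurve",
    "Crossing",
    "difference_curve",
    "find_crossing",
    "crossing_points",
    "complete_cases",
]

log = logging.getLogger("fprt")


class DesignError(ValueError):
    """Raised when the experimental design cannot support the analysis."""


class Crossing(NamedTuple):
    location: float
    slope: float


@dataclass(frozen=True)
class DifferenceCurve:
    """Pointwise difference of two density estimates on a shared grid."""

    grid: np.ndarray
    diff: np.ndarray
    pair: tuple

    def __post_init__(self) -> None:
        if self.grid.shape != self.diff.shape:
            raise ValueError("grid and diff must have equal length")


def difference_curve(da: DensityEstimate, db: DensityEstimate) -> DifferenceCurve:
    """``da - db`` pointwise; both estimates must share the identical grid."""
    if da.grid.shape != db.grid.shape or not np.array_equal(da.grid, db.grid):
        raise ValueError("density estimates are on different grids")
    return DifferenceCurve(grid=da.grid, diff=da.density - db.density,
                           pair=(da.condition, db.condition))


def find_crossing(curve: DifferenceCurve, window: tuple | None = None) -> Crossing | None:
    """Locate the zero crossing of a difference curve.

    Sign changes between adjacent grid points are resolved by linear
    interpolation.  Candidates outside ``window`` (an (lo, hi) RT interval)
    are discarded; among the rest the crossing with maximum ``|slope|`` is
    returned, ties broken toward the smaller RT.  Returns ``None`` when no
    crossing falls in the window (the "missing" outcome — e.g. two
    non-overlapping densities).

    Raises ``ValueError`` on an all-zero (degenerate) curve.
    """
    d = np.asarray(curve.diff, dtype=float)
    x = np.asarray(curve.grid, dtype=float)
    if np.all(d == 0.0):
        raise ValueError("degenerate all-zero difference curve")

    locations: list[float] = []
    slopes: list[float] = []

    prod = d[:-1] * d[1:]
    step = np.diff(x)
    for i in np.flatnonzero(prod < 0):
        slope = (d[i + 1] - d[i]) / step[i]
        loc = x[i] - d[i] / slope
        locations.append(float(loc))
        slopes.append(float(slope))
    # exact zeros at interior grid points with a true sign change around them
    for i in np.flatnonzero(d == 0.0):
        if 0 < i < d.size - 1 and d[i - 1] * d[i + 1] < 0:
            locations.append(float(x[i]))
            slopes.append(float((d[i + 1] - d[i - 1]) / (x[i + 1] - x[i - 1])))

    if window is not None:
        lo, hi = window
        keep = [(l, s) for l, s in zip(locations, slopes) if lo <= l <= hi]
    else:
        keep = list(zip(locations, slopes))
    if not keep:
        return None
    # steepest crossing; ties toward the smaller RT
    keep.sort(key=lambda ls: (-abs(ls[1]), ls[0]))
    loc, slope = keep[0]
    return Crossing(location=loc, slope=slope)


def crossing_points(
    data: RTDataset,
    bandwidth: str = "silverman",
    h: float | None = None,
    n_grid: int = DEFAULT_GRID_SIZE,
    min_trials: int = 10,
    condition_order: list | None = None,
) -> pd.DataFrame:
    """Per-subject, per-pair crossing-point table.

    For each subject: one shared grid over that subject's pooled RTs, one
    KDE per condition, all pairwise difference curves, and one crossing per
    pair.  Subjects with any condition cell below ``min_trials`` are
    excluded (logged).  Requires at least three conditions — with fewer
    there is only one crossing and coincidence cannot be assessed.

    Returns a DataFrame with columns ``subject, pair, cond_a, cond_b,
    crossing, slope, status``; the attrs carry the global condition order,
    per-subject bandwidths and the exclusion list.  Condition order (and
    hence pair naming) is fixed globally by ascending grand-mean RT so that
    a given pair label means the same contrast for every subject.
    """
    frame = data.frame
    if condition_order is None:
        means = frame.groupby("condition")["rt"].mean().sort_values(kind="stable")
        condition_order = [c for c, _ in sorted(means.items(), key=lambda kv: (kv[1], str(kv[0])))]
    conditions = list(condition_order)
    if len(conditions) < 3:
        raise DesignError(
            f"at least 3 conditions are required to test crossing-point coincidence; got {len(conditions)}"
        )

    pairs = list(itertools.combinations(range(len(conditions)), 2))
    rows = []
    excluded: list = []
    bandwidths: dict = {}

    for subject, sub in frame.groupby("subject", sort=True):
        counts = sub.groupby("condition").size()
        if any(counts.get(c, 0) < min_trials for c in conditions):
            excluded.append(subject)
            log.warning("subject %r excluded: fewer than %d trials in some condition",
                        subject, min_trials)
            continue
        pooled = sub["rt"].to_numpy(dtype=float)
        h_s = h if (bandwidth == "fixed" or h is not None) else None
        h_s = select_bandwidth(pooled, "fixed" if h_s is not None else bandwidth, h=h_s)
        bandwidths[subject] = h_s
        grid = shared_grid(pooled, h_s, n_grid)
        dens = {}
        quart = {}
        for cond in conditions:
            x = sub.loc[sub["condition"] == cond, "rt"].to_numpy(dtype=float)
            dens[cond] = kde(x, h_s, grid, condition=str(cond))
            quart[cond] = np.percentile(x, [25, 75])
        for i, j in pairs:
            a, b = conditions[i], conditions[j]
            curve = difference_curve(dens[a], dens[b])
            window = (min(quart[a][0], quart[b][0]) - h_s,
                      max(quart[a][1], quart[b][1]) + h_s)
            hit = find_crossing(curve, window=window)
            rows.append({
                "subject": subject,
                "pair": f"{a} vs {b}",
                "cond_a": a,
                "cond_b": b,
                "crossing": hit.location if hit else np.nan,
                "slope": hit.slope if hit else np.nan,
                "status": "ok" if hit else "missing",
            })

    table = pd.DataFrame(rows, columns=["subject", "pair", "cond_a", "cond_b",
                                        "crossing", "slope", "status"])
    table.attrs["condition_order"] = conditions
    table.attrs["excluded"] = excluded
    table.attrs["bandwidths"] = bandwidths
    return table


def complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    """Subjects with an ok crossing for every pair (balanced subset).

    The repeated-measures inference requires a full pair set per subject;
    subjects with any missing crossing are dropped (logged), keeping the
    design balanced without imputation.
    """
    n_pairs = table["pair"].nunique()
    ok = table[table["status"] == "ok"]
    counts = ok.groupby("subject").size()
    keep = counts[counts == n_pairs].index
    dropped = sorted(set(table["subject"]) - set(keep))
    if dropped:
        log.warning("dropped %d subject(s) with missing crossings: %s", len(dropped), dropped)
    out = ok[ok["subject"].isin(keep)].reset_index(drop=True)
    out.attrs.update(table.attrs)
    out.attrs["incomplete_subjects"] = dropped
    return out
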