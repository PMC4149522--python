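"""Trial-level RT data ingestion, result serialization, and diagnostic plots."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DEFAULT_GRID_SIZE, kde, select_bandwidth, shared_grid

__all__ = ["RTDataset", "read_rt_table", "write_result", "plot_diagnostics"]

log = logging.getLogger("fprt")

_UNITS = ("s", "ms", "arbitrary")


@dataclass(frozen=True)
class RTDataset:
    """Long-format trial table: one row per trial (subject, condition, rt).

    ``unit`` tags the RT scale.  For "s" or "ms" data all RTs must be
    strictly positive; "arbitrary" admits any finite real (simulation
    studies may use, e.g., standard-normal base distributions).
    """

    frame: pd.DataFrame
    unit: str = "s"
    extra_columns: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}")
        required = {"subject", "condition", "rt"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        rt = self.frame["rt"].to_numpy(dtype=float)
        if not np.all(np.isfinite(rt)):
            raise ValueError("all rt values must be finite")
        if self.unit != "arbitrary" and np.any(rt <= 0):
            raise ValueError("rt values must be positive for time-tagged data")

    @property
    def conditions(self) -> list:
        return sorted(self.frame["condition"].unique())

    @property
    def subjects(self) -> list:
        return sorted(self.frame["subject"].unique())

    def cell_counts(self) -> pd.DataFrame:
        """Trial count per (subject, condition) cell."""
        return self.frame.groupby(["subject", "condition"], sort=True).size().unstack(fill_value=0)


def read_rt_table(
    path,
    subject: str = "subject",
    condition: str = "condition",
    rt: str = "rt",
    delimiter: str = ",",
    unit: str = "s",
    between: str | None = None,
    max_bad_fraction: float = 0.5,
) -> RTDataset:
    """Read a delimited trial-level table into an :class:`RTDataset`.

    Rows whose RT is missing, non-numeric, non-finite, or (for time-tagged
    units) non-positive are dropped with a logged count; if more than
    ``max_bad_fraction`` of rows are dropped, an error is raised instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter)
    for col in (subject, condition, rt):
        if col not in raw.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    if between is not None and between not in raw.columns:
        raise ValueError(f"between column {between!r} not found in {path.name}")
    if len(raw) == 0:
        raise ValueError(f"{path.name} contains no data rows")

    cols = {subject: "subject", condition: "condition", rt: "rt"}
    frame = raw.rename(columns=cols)
    keep = ["subject", "condition", "rt"] + ([between] if between else [])
    frame = frame[keep]
    rt_num = pd.to_numeric(frame["rt"], errors="coerce")
    bad = ~np.isfinite(rt_num.to_numpy(dtype=float))
    if unit != "arbitrary":
        bad |= rt_num.to_numpy(dtype=float) <= 0
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("dropped %d of %d rows with invalid rt values", n_bad, len(frame))
    if n_bad > max_bad_fraction * len(frame):
        raise ValueError(f"{n_bad} of {len(frame)} rows unparseable; refusing to continue")
    frame = frame.loc[~bad].copy()
    frame["rt"] = rt_num[~bad].astype(float)
    if len(frame) == 0:
        raise ValueError("no valid rows after filtering")
    extra = (between,) if between else ()
    return RTDataset(frame=frame.reset_index(drop=True), unit=unit, extra_columns=extra)


def write_result(result, outdir) -> dict:
    """Serialize a FixedPointResult: crossing table as CSV, stats as JSON.

    The JSON settings block records bandwidth, grid size, seed and
    exclusions — enough to re-run the analysis bit-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / "crossing_table.csv"
    result.crossing_table.to_csv(table_path, index=False)

    payload = {
        "bf01": {k: float(v) for k, v in result.bf01.items()},
        "bf10": {k: float(v) for k, v in result.bf10.items()},
        "anova": {
            k: {"F": float(a.F), "df1": float(a.df1), "df2": float(a.df2), "p": float(a.p)}
            for k, a in result.anova.items()
        },
        "settings": _jsonable(result.settings),
    }
    json_path = outdir / "result.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"crossing_table": table_path, "result": json_path}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def plot_diagnostics(result, data: RTDataset, outdir) -> list:
    """Three-panel diagnostics: densities, difference curves, crossing boxplots.

    One panel row per between-group level when the analysis had a
    between-subject factor, otherwise a single row.  Densities and
    differences are computed across all pooled observations (ignoring the
    subject structure), which is how the group-level pattern is usually
    displayed; the boxplots show the per-subject crossing points that the
    inference actually used.  Plotting is best-effort: a missing panel is
    logged, never fatal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    settings = result.settings
    conditions = settings.get("condition_order") or data.conditions
    between_col = settings.get("between")
    if between_col:
        groups = sorted(data.frame[between_col].unique())
    else:
        groups = [None]

    h = settings.get("h")
    rule = settings.get("bandwidth_rule", "silverman")
    n_grid = settings.get("grid_size", DEFAULT_GRID_SIZE)

    fig, axes = plt.subplots(len(groups), 3, figsize=(13, 3.6 * len(groups)), squeeze=False)
    table = result.crossing_table

    for row, group in enumerate(groups):
        if group is None:
            sub = data.frame
            subjects = set(sub["subject"])
            title = ""
        else:
            sub = data.frame[data.frame[between_col] == group]
            subjects = set(sub["subject"])
            title = f"{between_col} = {group}"

        pooled = sub["rt"].to_numpy(dtype=float)
        h_row = h if h is not None else select_bandwidth(pooled, rule)
        grid = shared_grid(pooled, h_row, n_grid)
        dens = {}
        for cond in conditions:
            x = sub.loc[sub["condition"] == cond, "rt"].to_numpy(dtype=float)
            if x.size == 0:
                log.warning("no data for condition %r in group %r; panel trace skipped", cond, group)
                continue
            dens[cond] = kde(x, h_row, grid, condition=str(cond))

        ax = axes[row][0]
        for cond, d in dens.items():
            ax.plot(d.grid, d.density, label=str(cond))
        ax.set_xlabel(f"RT ({data.unit})")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        ax.set_title(f"densities {title}".strip())

        ax = axes[row][1]
        names = list(dens)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ax.plot(grid, dens[names[i]].density - dens[names[j]].density,
                        label=f"{names[i]} vs {names[j]}")
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel(f"RT ({data.unit})")
        ax.set_ylabel("density difference")
        ax.legend(fontsize=8)
        ax.set_title(f"differences {title}".strip())

        ax = axes[row][2]
        ok = table[(table["status"] == "ok") & table["subject"].isin(subjects)]
        if len(ok) == 0:
            log.warning("no crossing points for group %r; boxplot panel omitted", group)
            ax.set_visible(False)
        else:
            pairs = sorted(ok["pair"].unique())
            ax.boxplot([ok.loc[ok["pair"] == p, "crossing"] for p in pairs],
                       tick_labels=pairs)
            ax.set_ylabel(f"crossing point ({data.unit})")
            ax.tick_params(axis="x", labelsize=7)
            ax.set_title(f"crossing points {title}".strip())

    fig.tight_layout()
    path = outdir / "diagnostics.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return [path]
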