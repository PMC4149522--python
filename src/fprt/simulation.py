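"""Synthetic fixed-point experiments and the validation harness.

Two generators emulate the standard study conditions:

* ``mixture`` — every condition draws from the *same* two base
  distributions, only the mixture proportion differs across conditions.
  The fixed-point property holds by construction.
* ``shift`` — three distributions whose means (and, for inverse-Gaussian
  bases, shapes) are linearly interpolated between the two bases.  Their
  condition means match the matched mixture design with proportions
  (1, .5, 0), but the densities are shifted copies rather than mixtures, so
  the crossing points do *not* coincide.

Both add an optional per-subject additive random effect (one normal shift
applied to all of a subject's trials).  ``run_study`` replicates
generate -> fixed_point_test over a list of configurations and aggregates
Bayes factors, F statistics, and crossing-point precision (RMSD against the
analytic fixed point).  Presets ``sim1`` .. ``sim4`` reproduce the
canonical validation sweeps at desk scale (default 100 replicates per cell
instead of the original thousands; pass ``replications`` to change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .crossing import complete_cases
from .density import kde, select_bandwidth, shared_grid
from .inference import fixed_point_test
from .io import RTDataset
from .mixtures import (
    BaseDistribution,
    MixtureSpec,
    analytic_fixed_point,
    inverse_gaussian,
    normal,
    sample_mixture,
)

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "gen_mixture_experiment",
    "gen_shift_experiment",
    "rmsd_crossings",
    "run_study",
    "preset",
    "PRESETS",
]

log = logging.getLogger("fprt")


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of a simulation study.

    ``proportions`` are the per-condition mixture weights on ``first``
    (mixture scenario); the shift scenario ignores them and builds three
    interpolated distributions from ``first`` and ``second``.
    """

    scenario: str  # "mixture" | "shift"
    first: BaseDistribution
    second: BaseDistribution
    proportions: tuple = (0.1, 0.4, 0.8)
    subjects: int = 50
    trials: int = 200
    random_effect_sd: float = 0.0
    bandwidth: float = 0.1  # kernel SD, RT units
    min_trials: int = 10
    n_grid: int = 512
    label: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in ("mixture", "shift"):
            raise ValueError("scenario must be 'mixture' or 'shift'")
        if self.scenario == "mixture":
            if len(self.proportions) < 3:
                raise ValueError("at least 3 mixture conditions are required")
            if any(not (0.0 <= p <= 1.0) for p in self.proportions):
                raise ValueError("proportions must lie in [0, 1]")
        if self.subjects < 2:
            raise ValueError("at least 2 subjects are required")
        if self.trials < 10:
            raise ValueError("at least 10 trials per condition are required")
        if self.random_effect_sd < 0:
            raise ValueError("random_effect_sd must be non-negative")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def _subject_ids(n: int) -> list:
    width = len(str(n))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def gen_mixture_experiment(config: SimulationConfig, rng: np.random.Generator) -> RTDataset:
    """Simulate a mixture experiment: same bases, condition-specific proportions.

    Each subject receives one additive shift ~ N(0, random_effect_sd)
    applied to all their RTs; the mixture proportions themselves are
    identical across subjects, but the realized number of draws from each
    base is binomially random per cell.
    """
    if config.scenario != "mixture":
        raise ValueError("config.scenario must be 'mixture'")
    rows = []
    conditions = [f"p={p:g}" for p in config.proportions]
    for subject in _subject_ids(config.subjects):
        shift = rng.normal(0.0, config.random_effect_sd) if config.random_effect_sd > 0 else 0.0
        for cond, p in zip(conditions, config.proportions):
            spec = MixtureSpec(config.first, config.second, p)
            rts = sample_mixture(spec, config.trials, rng) + shift
            rows.append(pd.DataFrame({"subject": subject, "condition": cond, "rt": rts}))
    frame = pd.concat(rows, ignore_index=True)
    return RTDataset(frame=frame, unit="arbitrary")


def _shift_conditions(first: BaseDistribution, second: BaseDistribution):
    mus = (first.mean, (first.mean + second.mean) / 2.0, second.mean)
    if first.family != second.family:
        raise ValueError("shift scenario requires both bases from the same family")
    disps = (first.dispersion,
             (first.dispersion + second.dispersion) / 2.0,
             second.dispersion)
    return [BaseDistribution(first.family, m, d) for m, d in zip(mus, disps)]


def gen_shift_experiment(config: SimulationConfig, rng: np.random.Generator) -> RTDataset:
    """Simulate shifted (non-mixture) data matched in condition means.

    The three condition distributions have means mu1, (mu1+mu2)/2, mu2 and
    dispersions interpolated the same way, so a mean-based analysis cannot
    tell them from the matched mixture design — only the distribution shape
    (and hence the crossing points) differs.
    """
    if config.scenario != "shift":
        raise ValueError("config.scenario must be 'shift'")
    dists = _shift_conditions(config.first, config.second)
    conditions = [f"shift{i + 1}" for i in range(len(dists))]
    rows = []
    for subject in _subject_ids(config.subjects):
        shift = rng.normal(0.0, config.random_effect_sd) if config.random_effect_sd > 0 else 0.0
        for cond, dist in zip(conditions, dists):
            rts = dist.rvs(config.trials, rng) + shift
            rows.append(pd.DataFrame({"subject": subject, "condition": cond, "rt": rts}))
    frame = pd.concat(rows, ignore_index=True)
    return RTDataset(frame=frame, unit="arbitrary")


def generate(config: SimulationConfig, rng: np.random.Generator) -> RTDataset:
    if config.scenario == "mixture":
        return gen_mixture_experiment(config, rng)
    return gen_shift_experiment(config, rng)


def rmsd_crossings(table: pd.DataFrame, reference: float) -> float:
    """Root-mean-squared deviation of all ok crossings from ``reference``."""
    ok = table.loc[table["status"] == "ok", "crossing"].to_numpy(dtype=float)
    if ok.size == 0:
        raise ValueError("no ok-status crossings to evaluate")
    return float(np.sqrt(np.mean((ok - reference) ** 2)))


@dataclass
class SimulationSummary:
    """Aggregated results of a sweep, one row per configuration cell."""

    frame: pd.DataFrame
    replications: int
    seed: int | None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _log_mode(values: np.ndarray) -> float:
    """Mode of a Bayes-factor distribution, on the log scale.

    BF distributions are heavily right-skewed; the mode is located as the
    peak of a KDE-smoothed histogram of log(BF), then mapped back.
    """
    lv = np.log(values)
    if lv.size < 3 or np.ptp(lv) == 0:
        return float(np.exp(np.median(lv)))
    h = select_bandwidth(lv, "silverman")
    grid = shared_grid(lv, h, 256)
    dens = kde(lv, h, grid)
    return float(np.exp(grid[np.argmax(dens.density)]))


def run_study(
    configs: Sequence[SimulationConfig],
    replications: int = 100,
    seed: int | None = None,
) -> SimulationSummary:
    """Replicate generate -> fixed_point_test per configuration cell.

    Per replicate the pair-effect BF01, the F statistic, and (for mixture
    cells) the RMSD of the crossing points around the analytic fixed point
    are recorded; per cell the mean and log-scale mode of BF01, the mean F,
    and the mean RMSD are reported.  Replicate failures are counted and
    logged, never fatal to the sweep.  Deterministic given ``seed``.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(len(configs))
    records = []
    for config, cell_ss in zip(configs, cell_seeds):
        bfs, fs, rmsds, spreads = [], [], [], []
        failures = 0
        ref = None
        if config.scenario == "mixture":
            try:
                ref = analytic_fixed_point(config.first, config.second)
            except ValueError:
                ref = None
        for rep_ss in cell_ss.spawn(replications):
            rng = np.random.default_rng(rep_ss)
            try:
                data = generate(config, rng)
                res = fixed_point_test(data, h=config.bandwidth,
                                       n_grid=config.n_grid,
                                       min_trials=config.min_trials)
                cc = complete_cases(res.crossing_table)
                bfs.append(res.bf01["pair"])
                fs.append(res.anova["pair"].F)
                per_subj = cc.groupby("subject")["crossing"]
                spreads.append(float((per_subj.max() - per_subj.min()).mean()))
                if ref is not None:
                    rmsds.append(rmsd_crossings(cc, ref))
            except Exception as exc:  # noqa: BLE001 - per-replicate isolation
                failures += 1
                log.warning("replicate failed for cell %r: %s", config.label, exc)
        bf_arr = np.asarray(bfs)
        records.append({
            "label": config.label,
            "scenario": config.scenario,
            "subjects": config.subjects,
            "trials": config.trials,
            "bandwidth": config.bandwidth,
            **config.params,
            "bf01_mean": float(bf_arr.mean()) if bf_arr.size else np.nan,
            "bf01_median": float(np.median(bf_arr)) if bf_arr.size else np.nan,
            "bf01_mode": _log_mode(bf_arr) if bf_arr.size else np.nan,
            "f_mean": float(np.mean(fs)) if fs else np.nan,
            "rmsd_mean": float(np.mean(rmsds)) if rmsds else np.nan,
            "crossing_spread_mean": float(np.mean(spreads)) if spreads else np.nan,
            "fixed_point": ref,
            "n_reps": len(bfs),
            "n_failed": failures,
        })
    return SimulationSummary(frame=pd.DataFrame(records), replications=replications, seed=seed)


# ---------------------------------------------------------------------------
# presets: the four canonical validation studies
# ---------------------------------------------------------------------------

def _sim1() -> list[SimulationConfig]:
    # inverse-Gaussian bases in seconds; mild additive subject random effect
    return [SimulationConfig(
        scenario="mixture",
        first=inverse_gaussian(0.8, 5.0),
        second=inverse_gaussian(1.0, 5.0),
        proportions=(0.1, 0.4, 0.8),
        subjects=50,
        trials=200,
        random_effect_sd=0.1,
        bandwidth=0.1,
        label="sim1",
    )]


def sim2_second_base(mu2: float, mu1: float = 200.0, lam1: float = 100.0) -> BaseDistribution:
    """Second inverse-Gaussian base of the effect-size sweep.

    The shape grows with the mean, ``lam2 = lam1 + mu2 - mu1``, so the SD
    of the second base increases roughly linearly with its mean, as
    commonly observed in RT data.
    """
    return inverse_gaussian(mu2, lam1 + mu2 - mu1)


def _sim2(mu2_values: Sequence[float] | None = None) -> list[SimulationConfig]:
    # effect-size sweep in ms: mixture vs shifted data at matched means
    if mu2_values is None:
        mu2_values = np.linspace(225.0, 1175.0, 11)
    first = inverse_gaussian(200.0, 100.0)
    cells = []
    for mu2 in mu2_values:
        second = sim2_second_base(float(mu2))
        for scenario in ("mixture", "shift"):
            cells.append(SimulationConfig(
                scenario=scenario,
                first=first,
                second=second,
                proportions=(1.0, 0.5, 0.0),
                subjects=50,
                trials=200,
                bandwidth=100.0,
                label=f"sim2-{scenario}-mu2={mu2:g}",
                params={"mu2": float(mu2)},
            ))
    return cells


_SIM34_H = (1.0, 1.5, 2.0)


def _sim3() -> list[SimulationConfig]:
    # sample-size sweep: normal bases, unit SD; h in units of the base SD
    cells = []
    for subjects in (10, 50, 100):
        for h in _SIM34_H:
            cells.append(SimulationConfig(
                scenario="mixture",
                first=normal(0.0, 1.0),
                second=normal(1.5, 1.0),
                proportions=(0.1, 0.5, 0.9),
                subjects=subjects,
                trials=200,
                bandwidth=h,
                label=f"sim3-s={subjects}-h={h:g}",
            ))
    return cells


def _sim4() -> list[SimulationConfig]:
    cells = []
    for trials in (100, 200, 500):
        for h in _SIM34_H:
            cells.append(SimulationConfig(
                scenario="mixture",
                first=normal(0.0, 1.0),
                second=normal(1.5, 1.0),
                proportions=(0.1, 0.5, 0.9),
                subjects=50,
                trials=trials,
                bandwidth=h,
                label=f"sim4-n={trials}-h={h:g}",
            ))
    return cells


PRESETS = {"sim1": _sim1, "sim2": _sim2, "sim3": _sim3, "sim4": _sim4}


def preset(name: str, **overrides) -> list[SimulationConfig]:
    """Configuration cells for a named preset, with optional field overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cells = PRESETS[name]()
    if overrides:
        cells = [replace(c, **overrides) for c in cells]
    return cells
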