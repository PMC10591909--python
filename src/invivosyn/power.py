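"""Empirical power and type-I-error estimation over design grids.

Power is strictly empirical: simulate ``n_sim`` independent studies at a
grid point, analyze each with the stratified-bootstrap synergy test, and
report the fraction in which synergy is detected — P < alpha with the
observed effect on the synergy side (SS > 0, equivalently CI < 1).  A
significant result in the antagonism direction is not a synergy detection;
counting it as one would, for example, make the transient antagonism-signed
Bliss contrast of a delayed-kick-in study look like "power".  For a
scenario whose combination arm is exactly additive under the Bliss null,
the same number is the empirical rate of false synergy claims (the FDR of
declaring synergy).  Set ``direction="two_sided"`` to count any rejection.

Seeds form a hierarchy (master -> grid point -> replicate -> simulation /
bootstrap streams) so grid points are independent and individually
reproducible.  The default test statistic is the Bliss synergy score (SS);
the CI statistic is available via ``statistic="ci"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .bootstrap import BootstrapConfig, bootstrap_synergy
from .errors import ConfigError, InvivoSynError
from .simulate import SimulationScenario, apply_grid_point, simulate_study


@dataclass
class PowerConfig:
    """Grid-power configuration.

    ``grid`` maps parameter names (see
    :func:`invivosyn.simulate.apply_grid_point`) to value sequences; the
    grid is their cartesian product.  ``n_boot`` defaults to 1000 to match
    the headline analysis; 200 is a reasonable scaled-down fast mode.
    """

    scenario: SimulationScenario
    grid: dict[str, Sequence[float]] = field(default_factory=dict)
    n_sim: int = 100
    alpha: float = 0.05
    model: str = "bliss"
    statistic: str = "ss"
    n_boot: int = 1000
    t_eval: float = 21.0
    seed: int = 0
    direction: str = "synergy"
    max_regenerate: int = 100

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ConfigError("n_sim must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.statistic not in ("ci", "ss"):
            raise ConfigError("statistic must be 'ci' or 'ss'")
        if self.direction not in ("synergy", "two_sided"):
            raise ConfigError("direction must be 'synergy' or 'two_sided'")

    def grid_points(self) -> list[dict[str, float]]:
        if not self.grid:
            return [{}]
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


@dataclass
class PowerRow:
    """Empirical power at one grid point with binomial (Wilson) uncertainty."""

    point: dict[str, float]
    power: float
    successes: int
    n_valid: int
    n_sim: int
    ci_low: float
    ci_high: float
    n_degenerate: int = 0
    n_regenerated: int = 0


@dataclass
class PowerResult:
    rows: list[PowerRow]
    n_sim: int
    alpha: float
    model: str
    statistic: str
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = dict(r.point)
            rec.update(
                power=r.power, successes=r.successes, n_valid=r.n_valid,
                n_sim=r.n_sim, ci_low=r.ci_low, ci_high=r.ci_high,
                n_degenerate=r.n_degenerate, n_regenerated=r.n_regenerated,
            )
            recs.append(rec)
        return pd.DataFrame(recs)


def _analyze_once(
    scenario: SimulationScenario, cfg: PowerConfig, rep_seq: np.random.SeedSequence
) -> tuple[float, bool]:
    """(P value, synergy-direction flag) of one simulated study.

    P is NaN if the inference is degenerate.
    """
    sim_seq, boot_seq = rep_seq.spawn(2)
    ds = simulate_study(scenario, seed=sim_seq)
    inference = bootstrap_synergy(
        ds,
        BootstrapConfig(
            n_boot=cfg.n_boot, seed=boot_seq, model=cfg.model, t_eval=cfg.t_eval
        ),
    )
    stat = inference.ci if cfg.statistic == "ci" else inference.ss
    synergistic = inference.estimate.ss > 0  # equivalently ci < 1
    return stat.p_value, synergistic


def estimate_power(
    cfg: PowerConfig,
    grid_point: Mapping[str, float] | None = None,
    seed_seq: np.random.SeedSequence | None = None,
) -> PowerRow:
    """Empirical power at one grid point.

    A replicate whose simulated study cannot be analyzed at all (e.g. a
    group left with no analyzable curve by extreme truncation) is
    regenerated from the next seed substream and counted; a replicate whose
    bootstrap distribution is degenerate is counted and excluded from the
    denominator.
    """
    point = dict(grid_point or {})
    scenario = apply_grid_point(cfg.scenario, point)
    seq = seed_seq if seed_seq is not None else np.random.SeedSequence(cfg.seed)

    successes = 0
    n_valid = 0
    n_degenerate = 0
    n_regenerated = 0
    for _ in range(cfg.n_sim):
        attempts = 0
        while True:
            rep_seq = seq.spawn(1)[0]
            try:
                p, synergistic = _analyze_once(scenario, cfg, rep_seq)
                break
            except InvivoSynError:
                attempts += 1
                n_regenerated += 1
                if attempts > cfg.max_regenerate:
                    raise
        if np.isnan(p):
            n_degenerate += 1
            continue
        n_valid += 1
        if p < cfg.alpha and (cfg.direction == "two_sided" or synergistic):
            successes += 1
    power = successes / n_valid if n_valid else float("nan")
    if n_valid:
        lo, hi = proportion_confint(successes, n_valid, alpha=0.05, method="wilson")
    else:
        lo = hi = float("nan")
    return PowerRow(
        point=point, power=power, successes=successes, n_valid=n_valid,
        n_sim=cfg.n_sim, ci_low=float(lo), ci_high=float(hi),
        n_degenerate=n_degenerate, n_regenerated=n_regenerated,
    )


def power_grid(cfg: PowerConfig) -> PowerResult:
    """Empirical power at every grid point, deterministic given the master
    seed (each point gets its own independent seed substream)."""
    points = cfg.grid_points()
    if not points:
        raise ConfigError("empty grid")
    master = np.random.SeedSequence(cfg.seed)
    child_seqs = master.spawn(len(points))
    rows = [
        estimate_power(cfg, point, seed_seq=child)
        for point, child in zip(points, child_seqs)
    ]
    return PowerResult(
        rows=rows, n_sim=cfg.n_sim, alpha=cfg.alpha, model=cfg.model,
        statistic=cfg.statistic, n_boot=cfg.n_boot, seed=cfg.seed,
    )
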