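"""Stratified BCa bootstrap inference for CI and SS.

Mice are resampled with replacement within their treatment group (the
strata), each group to its own original size, so every bootstrap dataset is
a valid 4-group study of the same design.  Each replicate re-runs the
eGR -> relative survival -> CI/SS pipeline; because the per-mouse eGR is a
deterministic function of its curve, this reduces to resampling the
per-mouse eGR values and re-averaging, which is what the implementation
does (the equivalence is asserted by the test suite).

Intervals are bias-corrected and accelerated (BCa): the bias term z0 comes
from the fraction of bootstrap values below the observed estimate (ties
counted half) and the acceleration a from the skewness of leave-one-mouse-
out jackknife values.  The combination index is processed on the log scale
(its sampling distribution is approximately log-normal; the additivity null
log CI = 0), the synergy score on its natural scale (null 0).

The two-sided P value is the smallest alpha for which the null value falls
outside the (1 - alpha) BCa interval, found by bisection, so the reported P
and interval are consistent by construction (null inside the 95% interval
iff P > 0.05).  P is floored at 1/n_boot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .egr import GroupEgrTable, group_egr
from .errors import ConfigError, StudyStructureError
from .study_data import GROUPS, GrowthCurve, StudyDataset
from .synergy import DEFAULT_T_EVAL, MODELS, SynergyEstimate, estimate_synergy

#: Deterministic group order in which resample indices are drawn.
RESAMPLE_ORDER = GROUPS


@dataclass
class BootstrapConfig:
    """Configuration of the stratified bootstrap.

    ``n_boot`` defaults to 1000 resamples; ``level`` is the confidence level
    of the BCa intervals; ``max_day`` optionally truncates curves before the
    growth-rate step (e.g. 21 to restrict all analyses to three weeks).
    """

    n_boot: int = 1000
    level: float = 0.95
    seed: int | np.random.SeedSequence | None = None
    model: str = "bliss"
    t_eval: float = DEFAULT_T_EVAL
    max_day: float | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ConfigError(f"n_boot must be >= 2, got {self.n_boot}")
        if not 0 < self.level < 1:
            raise ConfigError(f"level must be in (0, 1), got {self.level}")
        if self.model not in MODELS:
            raise ConfigError(f"model must be one of {MODELS}, got {self.model!r}")


@dataclass(frozen=True)
class BcaInterval:
    """BCa interval endpoints plus diagnostics.

    ``degenerate`` flags an all-identical bootstrap distribution; ``clamped``
    flags an adjusted quantile that fell outside (0, 1) and was clamped to
    an extreme order statistic.
    """

    lower: float
    upper: float
    z0: float
    accel: float
    degenerate: bool = False
    clamped: bool = False

    def __iter__(self):
        return iter((self.lower, self.upper))


@dataclass
class StatisticInference:
    """Bootstrap inference for one statistic (ci or ss)."""

    statistic: str
    observed: float
    lower: float
    upper: float
    level: float
    p_value: float
    null_value: float
    z0: float
    accel: float
    boot: np.ndarray
    degenerate: bool = False
    clamped: bool = False

    def to_dict(self, include_boot: bool = False) -> dict:
        out = {
            "statistic": self.statistic,
            "observed": self.observed,
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "p_value": None if np.isnan(self.p_value) else self.p_value,
            "null_value": self.null_value,
            "z0": None if not np.isfinite(self.z0) else self.z0,
            "accel": None if not np.isfinite(self.accel) else self.accel,
            "degenerate": self.degenerate,
            "clamped": self.clamped,
        }
        if include_boot:
            out["boot"] = self.boot.tolist()
        return out


@dataclass
class SynergyInference:
    """Observed CI/SS with BCa intervals and P values for one model."""

    estimate: SynergyEstimate
    ci: StatisticInference
    ss: StatisticInference
    n_boot: int
    seed: object
    egrs: GroupEgrTable
    group_sizes: dict[str, int] = field(default_factory=dict)

    def to_dict(self, include_boot: bool = False) -> dict:
        return {
            "model": self.estimate.model,
            "t_eval": self.estimate.t_eval,
            "verdict": self.estimate.verdict,
            "egr": dict(self.egrs.means),
            "ci": self.ci.to_dict(include_boot),
            "ss": self.ss.to_dict(include_boot),
            "n_boot": self.n_boot,
            "group_sizes": dict(self.group_sizes),
            "p_value_construction": "BCa interval inversion (bisection over alpha)",
        }


def stratified_resample(ds: StudyDataset, rng: np.random.Generator) -> StudyDataset:
    """One stratified resample of the study: mice drawn with replacement
    within each group, each group to its own original size.

    Resampled mice get unique synthetic ids (a mouse drawn twice is two
    curves).  Groups are drawn in the fixed order C, A, B, AB.
    """
    curves: list[GrowthCurve] = []
    for g in RESAMPLE_ORDER:
        pool = ds.curves_by_group(g)
        if not pool:
            raise StudyStructureError(f"group {g} is empty; cannot resample")
        idx = rng.integers(0, len(pool), size=len(pool))
        for j, i in enumerate(idx):
            src = pool[i]
            curves.append(
                GrowthCurve(f"{g}*{j + 1}<-{src.mouse_id}", g,
                            src.days.copy(), src.volumes.copy())
            )
    return StudyDataset(curves=curves)


# ---------------------------------------------------------------------------
# BCa machinery
# ---------------------------------------------------------------------------


def _bias_term(boot: np.ndarray, observed: float) -> float:
    """z0 from the fraction of bootstrap values below the observed estimate,
    ties counted half.  +-inf on complete separation."""
    prop = (np.sum(boot < observed) + 0.5 * np.sum(boot == observed)) / boot.size
    if prop <= 0.0:
        return -np.inf
    if prop >= 1.0:
        return np.inf
    return float(norm.ppf(prop))


def _acceleration(jackknife_values: Sequence[float]) -> float:
    """Acceleration a from jackknife skewness:
    a = sum((theta_bar - theta_i)^3) / (6 * (sum((theta_bar - theta_i)^2))^1.5)."""
    jack = np.asarray(jackknife_values, dtype=float)
    d = jack.mean() - jack
    denom = 6.0 * np.sum(d**2) ** 1.5
    if denom == 0.0:
        return 0.0
    return float(np.sum(d**3) / denom)


def _adjusted_level(z0: float, a: float, z: float) -> float:
    """BCa-adjusted quantile level Phi(z0 + (z0 + z)/(1 - a (z0 + z)))."""
    if not np.isfinite(z0):
        return 0.0 if z0 < 0 else 1.0
    y = z0 + z
    den = 1.0 - a * y
    if den <= 0.0:
        return 1.0 if y > 0 else 0.0
    return float(norm.cdf(z0 + y / den))


def _interval_from_terms(
    boot: np.ndarray, z0: float, a: float, level: float
) -> tuple[float, float, bool]:
    alpha = 1.0 - level
    z_lo = float(norm.ppf(alpha / 2.0))
    a1 = _adjusted_level(z0, a, z_lo)
    a2 = _adjusted_level(z0, a, -z_lo)
    clamped = a1 <= 0.0 or a1 >= 1.0 or a2 <= 0.0 or a2 >= 1.0
    lower = float(np.quantile(boot, min(max(a1, 0.0), 1.0)))
    upper = float(np.quantile(boot, min(max(a2, 0.0), 1.0)))
    return lower, upper, clamped


def bca_interval(
    boot_values: Sequence[float],
    observed: float,
    jackknife_values: Sequence[float],
    level: float = 0.95,
) -> BcaInterval:
    """Efron's BCa interval from bootstrap and jackknife values.

    With z0 = 0 and a = 0 this reduces to the percentile interval.  An
    all-identical bootstrap distribution yields the degenerate interval
    (v, v) with ``degenerate=True``; adjusted quantile levels outside (0, 1)
    are clamped to the extreme order statistics with ``clamped=True``.
    """
    boot = np.asarray(boot_values, dtype=float)
    if np.ptp(boot) == 0.0:
        v = float(boot[0])
        return BcaInterval(v, v, np.nan, np.nan, degenerate=True)
    z0 = _bias_term(boot, observed)
    a = _acceleration(jackknife_values)
    lower, upper, clamped = _interval_from_terms(boot, z0, a, level)
    return BcaInterval(lower, upper, z0, a, degenerate=False, clamped=clamped)


def bootstrap_pvalue(
    boot_values: Sequence[float],
    null_value: float,
    bca_terms: tuple[float, float],
    tol: float = 1e-7,
) -> float:
    """Two-sided P value by BCa interval inversion.

    Smallest alpha for which ``null_value`` falls outside the (1 - alpha)
    BCa interval, located by bisection; consistent with :func:`bca_interval`
    at any level by construction.  Floored at 1/n_boot; NaN for a degenerate
    (zero-spread) bootstrap distribution.
    """
    boot = np.asarray(boot_values, dtype=float)
    if np.ptp(boot) == 0.0:
        return np.nan
    z0, a = bca_terms
    floor = 1.0 / boot.size

    def outside(alpha: float) -> bool:
        lower, upper, _ = _interval_from_terms(boot, z0, a, 1.0 - alpha)
        return null_value < lower or null_value > upper

    hi = 1.0 - 1e-9
    if not outside(hi):
        return 1.0
    if outside(floor):
        return floor
    lo = floor
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if outside(mid):
            hi = mid
        else:
            lo = mid
    return float(max(hi, floor))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _boot_group_means(
    values: Mapping[str, np.ndarray], n_boot: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Bootstrap means of per-mouse eGRs, drawn group-major in the fixed
    order C, A, B, AB (single seeded generator, reproducible)."""
    means: dict[str, np.ndarray] = {}
    for g in RESAMPLE_ORDER:
        v = np.asarray(values[g], dtype=float)
        idx = rng.integers(0, v.size, size=(n_boot, v.size))
        means[g] = v[idx].mean(axis=1)
    return means


def _jackknife_group_means(values: Mapping[str, np.ndarray]) -> list[dict[str, float]]:
    """Leave-one-mouse-out group means: for each mouse, its own group's mean
    is recomputed without it, the other groups keep their full means.
    Strata of size 1 contribute no jackknife point (nothing to leave out)."""
    base = {g: float(np.mean(values[g])) for g in GROUPS}
    out: list[dict[str, float]] = []
    for g in RESAMPLE_ORDER:
        v = np.asarray(values[g], dtype=float)
        if v.size < 2:
            continue
        s = v.sum()
        for x in v:
            m = dict(base)
            m[g] = (s - x) / (v.size - 1)
            out.append(m)
    return out


def _work_statistic(
    means: Mapping[str, float | np.ndarray], model: str, t_eval: float, statistic: str
):
    """CI on the log scale, SS on its natural (percentage-point) scale."""
    mC, mA, mB, mAB = (means[g] for g in GROUPS)
    if statistic == "ci":
        if model == "bliss":
            return t_eval * (mC + mAB - mA - mB)
        return t_eval * (mAB - np.minimum(mA, mB))
    s_a = np.exp(-t_eval * (mC - mA))
    s_b = np.exp(-t_eval * (mC - mB))
    s_ab = np.exp(-t_eval * (mC - mAB))
    expected = s_a * s_b if model == "bliss" else np.minimum(s_a, s_b)
    return 100.0 * (expected - s_ab)


def bootstrap_synergy(
    ds: StudyDataset,
    cfg: BootstrapConfig | None = None,
    egrs: GroupEgrTable | None = None,
) -> SynergyInference:
    """Stratified bootstrap inference for CI and SS of one synergy model.

    Returns the observed estimates, the bootstrap distributions (CI reported
    on its natural ratio scale), BCa intervals at ``cfg.level`` and two-sided
    P values for the additivity nulls CI = 1 and SS = 0.
    """
    cfg = cfg or BootstrapConfig()
    if egrs is None:
        egrs = group_egr(ds, max_day=cfg.max_day)
    values = egrs.values_by_group()
    estimate = estimate_synergy(egrs, cfg.model, cfg.t_eval)

    rng = np.random.default_rng(cfg.seed)
    boot_means = _boot_group_means(values, cfg.n_boot, rng)
    jack_means = _jackknife_group_means(values)

    results: dict[str, StatisticInference] = {}
    for stat, null in (("ci", 0.0), ("ss", 0.0)):
        obs = _work_statistic(egrs.means, cfg.model, cfg.t_eval, stat)
        boot = np.asarray(_work_statistic(boot_means, cfg.model, cfg.t_eval, stat))
        jack = np.array(
            [_work_statistic(m, cfg.model, cfg.t_eval, stat) for m in jack_means]
        )
        interval = bca_interval(boot, obs, jack, cfg.level)
        if interval.degenerate:
            p = np.nan
        else:
            p = bootstrap_pvalue(boot, null, (interval.z0, interval.accel))
        if stat == "ci":  # back to ratio scale for reporting
            results[stat] = StatisticInference(
                "ci", float(np.exp(obs)), float(np.exp(interval.lower)),
                float(np.exp(interval.upper)), cfg.level, p, 1.0,
                interval.z0, interval.accel, np.exp(boot),
                interval.degenerate, interval.clamped,
            )
        else:
            results[stat] = StatisticInference(
                "ss", float(obs), interval.lower, interval.upper, cfg.level,
                p, 0.0, interval.z0, interval.accel, boot,
                interval.degenerate, interval.clamped,
            )

    return SynergyInference(
        estimate=estimate,
        ci=results["ci"],
        ss=results["ss"],
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        egrs=egrs,
        group_sizes={g: int(values[g].size) for g in GROUPS},
    )
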