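"""Combination index (CI) and synergy score (SS) under Bliss and HSA models.

Treating tumor volume as a cell-count proxy and the group eGRs as rate
constants of equivalent exponential kinetics, the relative survival of arm g
with respect to vehicle control at evaluation time t is

    S_g = exp(-(eGR_C - eGR_g) * t),        g in {A, B, AB}.

The Bliss independence null expects the combination survival to equal the
product S_A * S_B; the highest-single-agent (HSA) null expects min(S_A, S_B).
The combination index is observed over expected survival,

    CI_bliss = S_AB / (S_A * S_B),     CI_hsa = S_AB / min(S_A, S_B),

with CI < 1 synergy, CI = 1 additivity, CI > 1 antagonism.  The synergy
score is the survival difference in percentage points,

    SS = 100 * (S_expected - S_AB),

with SS > 0 synergy.  By convention t = 21 days (three weeks of treatment)
so that CI is on the familiar scale of cell-line studies; CI and SS vary
with t but their verdict (and the bootstrap P value for CI) does not.

The module also provides the single-day local Bliss CI and its average, the
global CI (gCI), as a comparison baseline.  Note the baseline's orientation
is opposite: local CI > 0 indicates synergy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .egr import GroupEgrTable
from .errors import DomainError, NotComputableError, StudyStructureError
from .study_data import GROUPS, StudyDataset

DEFAULT_T_EVAL = 21.0
MODELS = ("bliss", "hsa")


@dataclass(frozen=True)
class SurvivalProfile:
    """Relative survivals of the three drug arms at time ``t_eval``.

    Values are dimensionless fractions; a value above 1 means the treatment
    accelerated growth relative to control.
    """

    t_eval: float
    s_a: float
    s_b: float
    s_ab: float


@dataclass(frozen=True)
class SynergyEstimate:
    """Point estimates of CI and SS for one model at one evaluation time."""

    model: str
    t_eval: float
    ci: float
    ss: float
    verdict: str


def _means(egrs: GroupEgrTable | Mapping[str, float]) -> dict[str, float]:
    means = egrs.means if isinstance(egrs, GroupEgrTable) else dict(egrs)
    missing = [g for g in GROUPS if g not in means]
    if missing:
        raise StudyStructureError(f"missing group eGR(s): {missing}")
    return {g: float(means[g]) for g in GROUPS}


def relative_survival(
    egrs: GroupEgrTable | Mapping[str, float], t_eval: float = DEFAULT_T_EVAL
) -> SurvivalProfile:
    """Relative survival S_g = exp(-(eGR_C - eGR_g) t) for g in {A, B, AB}."""
    if not t_eval > 0:
        raise DomainError(f"t_eval must be positive, got {t_eval}")
    m = _means(egrs)
    s = {g: float(np.exp(-(m["C"] - m[g]) * t_eval)) for g in ("A", "B", "AB")}
    return SurvivalProfile(t_eval=t_eval, s_a=s["A"], s_b=s["B"], s_ab=s["AB"])


def _verdict(ci: float) -> str:
    if ci < 1.0:
        return "synergy"
    if ci > 1.0:
        return "antagonism"
    return "additivity"


def estimate_synergy(
    egrs: GroupEgrTable | Mapping[str, float],
    model: str = "bliss",
    t_eval: float = DEFAULT_T_EVAL,
) -> SynergyEstimate:
    """CI and SS for one synergy model at evaluation time ``t_eval``."""
    if model not in MODELS:
        raise DomainError(f"model must be one of {MODELS}, got {model!r}")
    s = relative_survival(egrs, t_eval)
    expected = s.s_a * s.s_b if model == "bliss" else min(s.s_a, s.s_b)
    ci = s.s_ab / expected
    ss = 100.0 * (expected - s.s_ab)
    return SynergyEstimate(model=model, t_eval=t_eval, ci=ci, ss=ss, verdict=_verdict(ci))


def combination_index(
    egrs: GroupEgrTable | Mapping[str, float],
    model: str = "bliss",
    t_eval: float = DEFAULT_T_EVAL,
) -> SynergyEstimate:
    """Combination index (returned inside a full :class:`SynergyEstimate`)."""
    return estimate_synergy(egrs, model, t_eval)


def synergy_score(
    egrs: GroupEgrTable | Mapping[str, float],
    model: str = "bliss",
    t_eval: float = DEFAULT_T_EVAL,
) -> SynergyEstimate:
    """Synergy score (returned inside a full :class:`SynergyEstimate`)."""
    return estimate_synergy(egrs, model, t_eval)


# ---------------------------------------------------------------------------
# Single-day Bliss CI baseline (gCI)
# ---------------------------------------------------------------------------


@dataclass
class LocalCIBaseline:
    """Per-day local Bliss CI values and their mean (gCI).

    ``table`` holds, per computable day, the group mean relative TVs mu_g,
    the treatment effects delta_g = (mu_C - mu_g)/mu_C, and the local CI
    log(mu_A) + log(mu_B) - log(mu_C) - log(mu_AB) (natural log; > 0 means
    synergy in this baseline's orientation).
    """

    days: np.ndarray
    local_ci: np.ndarray
    gci: float
    table: pd.DataFrame
    skipped_days: list[float]


def _mean_relative_tv(ds: StudyDataset, group: str, day: float) -> float:
    rels = []
    for c in ds.curves_by_group(group):
        if c.n_points == 0:
            continue
        hit = np.nonzero(c.days == day)[0]
        if hit.size:
            rels.append(c.volumes[hit[0]] / c.volumes[0])
    if not rels:
        raise NotComputableError(f"group {group} has no measurement at day {day:g}")
    return float(np.mean(rels))


def local_bliss_ci(ds: StudyDataset, day: float) -> float:
    """Single-day log-scale Bliss CI (baseline orientation: > 0 synergy).

    A mouse contributes to day x only if it was measured exactly at x; no
    interpolation.  Raises :class:`NotComputableError` when any group lacks
    data at the day — the baseline's documented weakness for uneven designs.
    """
    mu = {g: _mean_relative_tv(ds, g, day) for g in GROUPS}
    return float(np.log(mu["A"]) + np.log(mu["B"]) - np.log(mu["C"]) - np.log(mu["AB"]))


def global_ci(ds: StudyDataset) -> LocalCIBaseline:
    """gCI: mean of local Bliss CI values over all computable days > 0.

    Day 0 is excluded (all relative TVs equal 1 there, the local CI is
    identically 0).  Days where any group has no measurement are skipped and
    recorded.
    """
    rows = []
    skipped: list[float] = []
    for day in ds.measurement_days():
        if day <= 0:
            continue
        try:
            mu = {g: _mean_relative_tv(ds, g, day) for g in GROUPS}
        except NotComputableError:
            skipped.append(float(day))
            continue
        local = float(
            np.log(mu["A"]) + np.log(mu["B"]) - np.log(mu["C"]) - np.log(mu["AB"])
        )
        row = {"day": float(day)}
        row.update({f"mu_{g}": mu[g] for g in GROUPS})
        row.update(
            {f"delta_{g}": (mu["C"] - mu[g]) / mu["C"] for g in ("A", "B", "AB")}
        )
        row["local_ci"] = local
        rows.append(row)
    if not rows:
        raise StudyStructureError(
            "no day (> 0) has measurements in all four groups; gCI not computable"
        )
    table = pd.DataFrame(rows)
    local = table["local_ci"].to_numpy()
    return LocalCIBaseline(
        days=table["day"].to_numpy(),
        local_ci=local,
        gci=float(local.mean()),
        table=table,
        skipped_days=skipped,
    )
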