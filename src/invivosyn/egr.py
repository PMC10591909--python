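"""The eGR (exponential growth rate) efficacy metric.

eGR summarizes a whole tumor growth curve by the rate constant of the
*equivalent* exponential curve: the exponential TV(t) = TV0 * exp(k t) whose
net log-scale area matches the observed curve's.  Concretely, the curve is
plotted in natural-log TV; the trapezoidal rule gives the total area under
the log-curve over the study duration d, from which the rectangle d*ln(TV0)
is subtracted to obtain the net-gain area (positive for net growth, zero for
stasis, negative for net shrinkage).  Since an exact exponential has net
area k d^2 / 2,

    eGR = 2 * AUC_net / d^2

recovers k exactly for exponential growth and requires no curve fitting or
growth-model assumption otherwise.  eGR is invariant to the starting TV and
to the sampling density of a log-linear curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, NotAnalyzableError, StudyStructureError
from .study_data import GROUPS, GrowthCurve, StudyDataset


@dataclass(frozen=True)
class MouseEgr:
    """Per-mouse growth-rate summary.

    ``net_auc`` is in day * ln(mm^3) units, ``egr`` in 1/day.
    """

    mouse_id: str
    group: str
    net_auc: float
    duration: float
    egr: float


@dataclass
class GroupEgrTable:
    """Per-group mean eGR plus the per-mouse values behind it.

    The group eGR is the arithmetic mean of its mice's eGRs; per-mouse values
    are retained for bootstrap and jackknife resampling.
    """

    mice: list[MouseEgr]
    means: dict[str, float]
    counts: dict[str, int]

    def values(self, group: str) -> np.ndarray:
        return np.array([m.egr for m in self.mice if m.group == group])

    def values_by_group(self) -> dict[str, np.ndarray]:
        return {g: self.values(g) for g in GROUPS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.mouse_id, m.group, m.net_auc, m.duration, m.egr) for m in self.mice],
            columns=["mouse", "group", "net_auc", "duration", "egr"],
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(GROUPS),
                "n": [self.counts[g] for g in GROUPS],
                "egr": [self.means[g] for g in GROUPS],
            }
        )


def _prepare(curve: GrowthCurve, max_day: float | None) -> GrowthCurve:
    if max_day is not None:
        curve = curve.truncated(max_day)
    if curve.n_points < 2:
        raise NotAnalyzableError(
            f"mouse {curve.mouse_id}: fewer than 2 measurements"
            + (f" at day <= {max_day:g}" if max_day is not None else "")
        )
    return curve


def log_auc_net(curve: GrowthCurve, max_day: float | None = None) -> tuple[float, float]:
    """Net log-scale AUC and duration d of one curve.

    Trapezoidal area under ln(TV) over the observed days, minus the rectangle
    d * ln(TV0) where TV0 is the first measurement.  Returns ``(auc_net, d)``.
    """
    curve = _prepare(curve, max_day)
    logv = np.log(curve.volumes)
    total = float(np.trapezoid(logv, curve.days))
    d = curve.duration
    return total - d * logv[0], d


def mouse_egr(curve: GrowthCurve, max_day: float | None = None) -> MouseEgr:
    """eGR of one mouse: 2 * AUC_net / d^2 (units 1/day)."""
    auc, d = log_auc_net(curve, max_day)
    if d == 0:
        raise DomainError(f"mouse {curve.mouse_id}: zero study duration")
    return MouseEgr(curve.mouse_id, curve.group, auc, d, 2.0 * auc / d**2)


def group_egr(ds: StudyDataset, max_day: float | None = None) -> GroupEgrTable:
    """Per-group mean eGR over all analyzable mice.

    Each mouse's eGR uses its own study duration (its last observed day), so
    uneven designs — early euthanasia in fast-growing arms, extended dosing
    in responsive arms — contribute all of their data.  ``max_day`` optionally
    truncates every curve first (e.g. restrict all analyses to day 21).
    """
    mice: list[MouseEgr] = []
    for c in ds.curves:
        candidate = c if max_day is None else c.truncated(max_day)
        if candidate.n_points >= 2:
            mice.append(mouse_egr(c, max_day))
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for g in GROUPS:
        vals = [m.egr for m in mice if m.group == g]
        if not vals:
            raise StudyStructureError(f"group {g} has no analyzable curve")
        means[g] = float(np.mean(vals))
        counts[g] = len(vals)
    return GroupEgrTable(mice=mice, means=means, counts=counts)
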