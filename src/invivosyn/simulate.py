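"""Exponential tumor-growth simulator for 4-group combination studies.

The generative model is exponential growth TV(t) = TV0 * exp(k t) with
treatment acting as a rate offset.  A treatment arm is parameterized by its
day-21 tumor growth inhibition TGI21 = 1 - RTV_treated(21)/RTV_control(21),
which maps to a treated rate

    k_tr = k + ln(1 - TGI21) / 21,

so that under pure exponentials the day-21 relative-TV ratio is exactly
1 - TGI21.  Three departures from the pure two-rate model are supported:

* delayed kick-in (t_ki): the arm grows at the control rate until day t_ki,
  at the treated rate thereafter;
* intrinsic resistance (p_rt with t_ir = 0): a fraction p_rt of cells grows
  at the control rate throughout, the rest follows the treated curve;
* induced resistance (p_rt with t_ir > 0): at day t_ir a fraction p_rt of
  the current population reverts to the control rate thereafter.

Between-animal variation: TV0 is log-normal with mean tv0_mean and
coefficient of variation cv0; the per-mouse base rate is normal with mean
k_mean and SD cvk * k_mean, truncated positive.  Measurement error is
multiplicative log-normal with log-scale SD sigma.  A mouse is euthanized at
the first measurement reaching tv_max (that measurement is kept by default;
later days are dropped).

Defaults emulate a typical subcutaneous xenograft study: treatment starts at
~200 mm^3 with 20% between-animal spread, tumors double weekly, TV is
measured twice weekly (days 0, 4, 7, 10, 14, 18, 21, extended in the
alternating +4/+3-day pattern), euthanasia at 3000 mm^3.  The rate and
measurement noise defaults (cvk = 0.03, sigma = 0.03) are calibrated so
that the simulated design-guidance properties reproduce the published
behavior of this class of study (strong Bliss synergy detectable with very
few mice, steady power gain with sample size under weak synergy, low false
synergy rate under additivity); they are optimistic relative to noisy
caliper data, so power estimates are best-case — see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import ConfigError, DomainError
from .study_data import GROUPS, GrowthCurve, StudyDataset

LN2 = math.log(2.0)
TREATED_ARMS = ("A", "B", "AB")


@dataclass(frozen=True)
class ArmSpec:
    """Treatment-effect parameters of one arm.

    tgi21: day-21 tumor growth inhibition in [0, 1); 0 for control.
    t_ki:  kick-in delay in days (0 = immediate effect).
    p_rt:  resistant cell fraction in [0, 1).
    t_ir:  day induced resistance emerges (0 = intrinsic, i.e. from day 0).
    """

    arm: str
    tgi21: float = 0.0
    t_ki: float = 0.0
    p_rt: float = 0.0
    t_ir: float = 0.0

    def __post_init__(self) -> None:
        if self.arm not in GROUPS:
            raise ConfigError(f"arm must be one of {GROUPS}, got {self.arm!r}")
        if not 0.0 <= self.tgi21 < 1.0:
            raise DomainError(
                f"tgi21 must be in [0, 1), got {self.tgi21} (complete kill is "
                f"not representable by a finite rate)"
            )
        if not 0.0 <= self.p_rt < 1.0:
            raise DomainError(f"p_rt must be in [0, 1), got {self.p_rt}")
        if self.t_ki < 0 or self.t_ir < 0:
            raise DomainError("t_ki and t_ir must be >= 0")
        if self.arm == "C" and (self.tgi21 or self.t_ki or self.p_rt or self.t_ir):
            raise ConfigError("control arm must have tgi21 = t_ki = p_rt = t_ir = 0")


def default_schedule(t_obs: float) -> np.ndarray:
    """Twice-weekly measurement days 0, 4, 7, 10, 14, 18, 21, continued past
    day 21 in the alternating +4/+3-day pattern up to ``t_obs``."""
    days = [0.0, 4.0, 7.0, 10.0, 14.0, 18.0, 21.0]
    days = [d for d in days if d <= t_obs]
    if days and days[-1] == 21.0:
        step = 4.0
        while days[-1] + step <= t_obs:
            days.append(days[-1] + step)
            step = 7.0 - step  # alternate 4, 3
    return np.array(days)


@dataclass
class SimulationScenario:
    """Full parameter set of one simulated 4-group study.

    ``k_mean`` is the control growth rate (1/day); use ``ln2/DT`` for a
    doubling time DT.  ``schedule=None`` means the default twice-weekly
    schedule extended to ``t_obs``.
    """

    arms: dict[str, ArmSpec]
    tv0_mean: float = 200.0
    cv0: float = 0.2
    k_mean: float = LN2 / 7.0
    cvk: float = 0.03
    sigma: float = 0.03
    tv_max: float = 3000.0
    t_obs: float = 21.0
    schedule: np.ndarray | None = None
    n_per_group: int = 6
    seed: int | np.random.SeedSequence | None = None
    keep_sacrifice_measurement: bool = True

    def __post_init__(self) -> None:
        arms = dict(self.arms)
        arms.setdefault("C", ArmSpec("C"))
        missing = [g for g in GROUPS if g not in arms]
        if missing:
            raise ConfigError(f"scenario missing arm spec(s): {missing}")
        for g, spec in arms.items():
            if spec.arm != g:
                raise ConfigError(f"arm spec under key {g!r} is labelled {spec.arm!r}")
        self.arms = arms
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if not self.tv_max > self.tv0_mean:
            raise ConfigError(
                f"tv_max ({self.tv_max}) must exceed tv0_mean ({self.tv0_mean})"
            )
        if self.k_mean <= 0:
            raise ConfigError("k_mean must be positive")
        for name in ("cv0", "cvk", "sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        sched = self.measurement_days
        if sched.size < 2:
            raise ConfigError("schedule must contain at least 2 days")
        if sched[0] != 0 or np.any(np.diff(sched) <= 0) or sched[-1] > self.t_obs:
            raise ConfigError(
                "schedule must start at day 0, be strictly increasing, and "
                "not extend past t_obs"
            )

    @property
    def measurement_days(self) -> np.ndarray:
        if self.schedule is not None:
            return np.asarray(self.schedule, dtype=float)
        return default_schedule(self.t_obs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationScenario":
        d = dict(d)
        arms_in = d.pop("arms", {})
        arms = {}
        for g, spec in arms_in.items():
            g2 = str(g).upper()
            arms[g2] = ArmSpec(arm=g2, **spec) if isinstance(spec, Mapping) else spec
        dt = d.pop("doubling_time", None)
        if dt is not None:
            if "k_mean" in d:
                raise ConfigError("give doubling_time or k_mean, not both")
            d["k_mean"] = LN2 / float(dt)
        if "schedule" in d and d["schedule"] is not None:
            d["schedule"] = np.asarray(d["schedule"], dtype=float)
        try:
            return cls(arms=arms, **d)
        except TypeError as exc:
            raise ConfigError(f"invalid scenario field: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "arms": {
                g: {"tgi21": a.tgi21, "t_ki": a.t_ki, "p_rt": a.p_rt, "t_ir": a.t_ir}
                for g, a in self.arms.items()
            },
            "tv0_mean": self.tv0_mean,
            "cv0": self.cv0,
            "k_mean": self.k_mean,
            "cvk": self.cvk,
            "sigma": self.sigma,
            "tv_max": self.tv_max,
            "t_obs": self.t_obs,
            "schedule": self.measurement_days.tolist(),
            "n_per_group": self.n_per_group,
            "seed": self.seed if isinstance(self.seed, (int, type(None))) else None,
            "keep_sacrifice_measurement": self.keep_sacrifice_measurement,
        }


def make_scenario(
    tgi: tuple[float, float, float] = (0.5, 0.4, 0.7),
    dt: float = 7.0,
    *,
    t_ki: tuple[float, float, float] = (0.0, 0.0, 0.0),
    p_rt: tuple[float, float, float] = (0.0, 0.0, 0.0),
    t_ir: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_per_group: int = 6,
    t_obs: float = 21.0,
    tv_max: float = 3000.0,
    tv0_mean: float = 200.0,
    cv0: float = 0.2,
    cvk: float = 0.03,
    sigma: float = 0.03,
    seed=None,
    schedule=None,
) -> SimulationScenario:
    """Convenience constructor; treated-arm tuples are ordered (A, B, AB)."""
    arms = {"C": ArmSpec("C")}
    for i, g in enumerate(TREATED_ARMS):
        arms[g] = ArmSpec(g, tgi21=tgi[i], t_ki=t_ki[i], p_rt=p_rt[i], t_ir=t_ir[i])
    return SimulationScenario(
        arms=arms, tv0_mean=tv0_mean, cv0=cv0, k_mean=LN2 / dt, cvk=cvk,
        sigma=sigma, tv_max=tv_max, t_obs=t_obs, schedule=schedule,
        n_per_group=n_per_group, seed=seed,
    )


def tgi_to_rate(k_control: float, tgi21: float) -> float:
    """Treated growth rate achieving the given day-21 TGI under exponentials:
    k_tr = k_control + ln(1 - tgi21)/21."""
    if not 0.0 <= tgi21 < 1.0:
        raise DomainError(f"tgi21 must be in [0, 1), got {tgi21}")
    return k_control + math.log(1.0 - tgi21) / 21.0


def expected_tv(arm: ArmSpec, k_c: float, tv0: float, t) -> np.ndarray | float:
    """Noise-free tumor volume of ``arm`` at time(s) ``t``.

    ``k_c`` is the (per-mouse) control growth rate; the treated rate is the
    TGI21-calibrated offset.  Kick-in delay and the resistant-fraction
    mixture are applied as in the module docstring.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    k_tr = tgi_to_rate(k_c, arm.tgi21)
    t_ki = arm.t_ki

    def g(tt):
        # treated relative curve with kick-in delay (tv0 = 1)
        return np.where(
            tt <= t_ki,
            np.exp(k_c * tt),
            np.exp(k_c * t_ki + k_tr * (tt - t_ki)),
        )

    if arm.p_rt == 0.0:
        rel = g(t)
    else:
        t_ir = arm.t_ir
        g_ir = float(g(np.asarray(t_ir)))
        rel = np.where(
            t <= t_ir,
            g(t),
            arm.p_rt * g_ir * np.exp(k_c * (t - t_ir)) + (1.0 - arm.p_rt) * g(t),
        )
    out = tv0 * rel
    return float(out) if out.ndim == 0 else out


def simulate_mouse(
    scenario: SimulationScenario, arm: str, rng: np.random.Generator,
    mouse_id: str | None = None,
) -> GrowthCurve:
    """One simulated growth curve: draw TV0 and the base rate, evaluate the
    arm's expected trajectory on the schedule, apply multiplicative
    log-normal measurement error, truncate at the euthanasia threshold."""
    spec = scenario.arms[arm]
    if scenario.cv0 > 0:
        s2 = math.log(1.0 + scenario.cv0**2)
        tv0 = float(
            rng.lognormal(math.log(scenario.tv0_mean) - 0.5 * s2, math.sqrt(s2))
        )
    else:
        tv0 = scenario.tv0_mean
    if scenario.cvk > 0:
        k = float(rng.normal(scenario.k_mean, scenario.cvk * scenario.k_mean))
        while k <= 0:
            k = float(rng.normal(scenario.k_mean, scenario.cvk * scenario.k_mean))
    else:
        k = scenario.k_mean

    days = scenario.measurement_days
    tv = np.asarray(expected_tv(spec, k, tv0, days), dtype=float)
    if scenario.sigma > 0:
        tv = tv * np.exp(rng.normal(0.0, scenario.sigma, size=tv.size))

    over = np.nonzero(tv >= scenario.tv_max)[0]
    if over.size:
        cut = over[0] + (1 if scenario.keep_sacrifice_measurement else 0)
        cut = max(cut, 1)  # always keep the first measurement
        days, tv = days[:cut], tv[:cut]
    return GrowthCurve(mouse_id or f"{arm}1", arm, days, tv)


def simulate_study(
    scenario: SimulationScenario,
    seed: int | np.random.SeedSequence | None = None,
) -> StudyDataset:
    """Simulate a full 4-group study (``n_per_group`` mice per arm, arms in
    the order C, A, B, AB; mouse ids like C1..Cn, A1..An)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    curves: list[GrowthCurve] = []
    for g in GROUPS:
        for i in range(scenario.n_per_group):
            curves.append(simulate_mouse(scenario, g, rng, mouse_id=f"{g}{i + 1}"))
    return StudyDataset(curves=curves)


def apply_grid_point(
    scenario: SimulationScenario, point: Mapping[str, float]
) -> SimulationScenario:
    """Scenario with grid-point overrides applied.

    Recognized keys: ``n`` / ``n_per_group``, ``dt`` (doubling time, sets
    ``k_mean``), ``t_obs``, ``tv_max``, ``tv0_mean``, ``cv0``, ``cvk``,
    ``sigma``, ``k_mean``, and ``tgi_a`` / ``tgi_b`` / ``tgi_ab``.
    """
    kw: dict = {}
    arms = dict(scenario.arms)
    for key, val in point.items():
        if key in ("n", "n_per_group"):
            kw["n_per_group"] = int(val)
        elif key == "dt":
            kw["k_mean"] = LN2 / float(val)
        elif key in ("t_obs", "tv_max", "tv0_mean", "cv0", "cvk", "sigma", "k_mean"):
            kw[key] = float(val)
        elif key in ("tgi_a", "tgi_b", "tgi_ab"):
            g = key.split("_", 1)[1].upper()
            arms[g] = replace(arms[g], tgi21=float(val))
        else:
            raise ConfigError(f"unknown grid parameter {key!r}")
    if scenario.schedule is None:
        kw.setdefault("schedule", None)  # regenerate for a new t_obs
    return replace(scenario, arms=arms, **kw)
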