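"""Protocol-faithful synthetic trial and cohort generation.

Generates core-temperature traces with known ground truth following the
progressive heat-stress protocol: 30-min equilibration (saturating
exponential T_gi rise to a plateau), a slow below-limit drift, then a
sustained linear rise starting when the ramped environmental variable
first exceeds the trial's true critical value.  AR(1) noise models the
autocorrelated drift of telemetry capsules.  Every output is fully
determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import psychro, reference
from .calorimetry import MassBalance, MetabolicSample, Subject
from .inflection import Trace
from .trials import RampSchedule, TrialRecord

__all__ = [
    "TraceSpec",
    "CohortCell",
    "CensorRule",
    "CohortSpec",
    "generate_trace",
    "generate_cohort",
    "default_cohort_spec",
]

#: Hard cap on trial length, min.
MAX_TRIAL_MINUTES = 150.0


class SpecError(ValueError):
    """Synthetic-data specification cannot produce a valid trial."""


@dataclass(frozen=True)
class TraceSpec:
    """Ground-truth specification of one synthetic trial trace.

    ``true_critical`` is the env value above which T_gi starts its
    sustained rise; ``None`` produces a never-inflecting (censored)
    trial.  Slopes are °C·h⁻¹.  The transition at the critical point is
    a continuous slope change by default; ``smooth_transition`` blends
    the slopes logistically over ~5 min to stress model mismatch.
    """

    schedule: RampSchedule
    true_critical: Optional[float]
    t_gi_baseline: float = 37.0
    equil_rise: float = 0.3
    equil_tau: float = 10.0  # min
    slope_below: float = reference.SLOPE_BELOW_MEAN
    slope_above: float = reference.SLOPE_ABOVE_MEAN
    noise_sd: float = 0.0
    ar1: float = 0.8
    sample_interval: float = 1.0  # min
    post_critical: float = 45.0  # min of trace after the inflection
    censored_duration: float = 125.0  # trial length when never inflecting
    smooth_transition: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.true_critical is not None:
            if self.slope_above <= self.slope_below:
                raise SpecError("slope_above must exceed slope_below")
            t_crit = self.schedule.time_env_exceeds(self.true_critical)
            if t_crit > MAX_TRIAL_MINUTES:
                raise SpecError(
                    f"true critical {self.true_critical} not reachable within "
                    f"{MAX_TRIAL_MINUTES:g} min of the schedule")
            if self.true_critical < self.schedule.start_value:
                raise SpecError("true critical lies below the schedule start value")
        if not 0 <= self.ar1 <= 0.95:
            raise SpecError("ar1 must lie in [0, 0.95]")
        if self.noise_sd < 0 or self.sample_interval <= 0:
            raise SpecError("noise_sd must be ≥ 0 and sample_interval > 0")

    @property
    def inflection_time(self) -> Optional[float]:
        if self.true_critical is None:
            return None
        return self.schedule.time_env_exceeds(self.true_critical)


def _ar1_noise(rng: np.ndarray, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


def generate_trace(
    spec: TraceSpec,
    *,
    trial_id: str = "synthetic",
    subject_id: str = "S0",
    activity: str = "Rest",
) -> TrialRecord:
    """Render a :class:`TraceSpec` into a concrete trial record.

    Deterministic given ``spec.seed``: two calls with the same spec
    produce identical arrays.
    """
    sched = spec.schedule
    t_c = spec.inflection_time
    if t_c is None:
        t_end = spec.censored_duration
        if sched.mode == "P_crit":
            # a humid-limb ramp cannot climb past saturation at the fixed T_db
            psat = psychro.saturation_vapor_pressure(sched.fixed_value)
            t_end = min(t_end, sched.time_env_exceeds(psat - 1.0))
    else:
        t_end = min(t_c + spec.post_critical, MAX_TRIAL_MINUTES)
    t = np.arange(0.0, t_end + 1e-9, spec.sample_interval)
    env = np.asarray(sched.env_at(t))

    # deterministic T_gi mean: saturating equilibration rise + hinge drift
    sb = spec.slope_below / 60.0  # °C·min⁻¹
    sa = spec.slope_above / 60.0
    mean = spec.t_gi_baseline + spec.equil_rise * (1.0 - np.exp(-t / spec.equil_tau))
    eq = sched.equilibration
    if t_c is None:
        mean = mean + sb * np.maximum(t - eq, 0.0)
    elif spec.smooth_transition:
        blend = 1.0 / (1.0 + np.exp(-(t - t_c) / 1.25))  # ~5-min logistic blend
        # integrate the blended slope on the sampling grid
        slope = np.where(t < eq, 0.0, sb + (sa - sb) * blend)
        mean = mean + np.concatenate([[0.0], np.cumsum(
            0.5 * (slope[1:] + slope[:-1]) * np.diff(t))])
    else:
        mean = (mean + sb * (np.clip(t, eq, t_c) - eq)
                + sa * np.maximum(t - t_c, 0.0))

    rng = np.random.default_rng(spec.seed)
    t_gi = mean + _ar1_noise(rng, len(t), spec.noise_sd, spec.ar1)

    trace = Trace(t=t, t_gi=t_gi, env=env, fixed=sched.fixed_value, mode=sched.mode)
    return TrialRecord(trial_id=trial_id, subject_id=subject_id,
                       activity=activity, schedule=sched, trace=trace)


@dataclass(frozen=True)
class CohortCell:
    """One condition-group cell of a synthetic cohort."""

    condition: str
    mode: str
    fixed_value: float
    n: int
    critical_mean: float
    critical_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SpecError("cell n must be non-negative")
        if self.n and self.critical_sd <= 0:
            raise SpecError("cell SD must be positive")


@dataclass(frozen=True)
class CensorRule:
    """Force ``count`` trials in matching cells to never inflect."""

    condition: str
    count: int


@dataclass
class CohortSpec:
    """Specification of a full synthetic study arm."""

    group: str  # e.g. "older-MinAct"
    age_group: str
    activity: str
    cells: Sequence[CohortCell]
    height_mean: float
    height_sd: float
    mass_mean: float
    mass_sd: float
    age_mean: float = 70.0
    age_sd: float = 5.0
    vo2_mean: float = 0.45
    vo2_sd: float = 0.10
    bml_mean: float = 0.38
    bml_sd: float = 0.20
    slope_below: float = reference.SLOPE_BELOW_MEAN
    slope_above: float = reference.SLOPE_ABOVE_MEAN
    noise_sd: float = 0.05
    ar1: float = 0.8
    censor_rules: Sequence[CensorRule] = field(default_factory=tuple)
    start_offset: float = 8.0  # ramp starts this many units below the drawn critical
    seed: Optional[int] = None


def _draw_subject(rng, spec: CohortSpec, idx: int) -> Subject:
    height = float(np.clip(rng.normal(spec.height_mean, spec.height_sd), 1.45, 2.05))
    mass = float(np.clip(rng.normal(spec.mass_mean, spec.mass_sd), 45.0, 150.0))
    age = float(rng.normal(spec.age_mean, spec.age_sd))
    return Subject(id=f"{spec.group}-S{idx:03d}", age_group=spec.age_group,
                   height=height, mass=mass, age=age)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[TrialRecord], dict[str, Subject], pd.DataFrame]:
    """Generate all trials of one study arm plus the ground-truth table.

    Per-trial critical values are drawn from each cell's normal truth;
    anthropometrics per subject from the group distributions.  Censor
    rules turn the stated number of trials in matching cells into
    never-inflecting traces.  Returns ``(records, subjects, truth)``
    where ``truth`` has one row per trial with the generating values.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[TrialRecord] = []
    subjects: dict[str, Subject] = {}
    truth_rows = []
    sidx = 0
    for cell in spec.cells:
        if cell.n == 0:
            continue
        n_censor = sum(r.count for r in spec.censor_rules
                       if r.condition == cell.condition)
        if n_censor > cell.n:
            raise SpecError(f"censor rule exceeds cell size for {cell.condition}")
        for j in range(cell.n):
            subject = _draw_subject(rng, spec, sidx)
            subjects[subject.id] = subject
            censored = j < n_censor
            crit = float(rng.normal(cell.critical_mean, cell.critical_sd))
            # keep the drawn critical on the reachable side of the ramp
            crit = max(crit, cell.critical_mean - 3 * cell.critical_sd)
            start = float(np.floor(crit)) - spec.start_offset
            sched = RampSchedule(mode=cell.mode, fixed_value=cell.fixed_value,
                                 start_value=start)
            sb = float(max(rng.normal(spec.slope_below, reference.SLOPE_BELOW_SD / 2), 0.0))
            sa = float(max(rng.normal(spec.slope_above, reference.SLOPE_ABOVE_SD / 2),
                           sb + 0.25))
            tspec = TraceSpec(
                schedule=sched,
                true_critical=None if censored else crit,
                slope_below=sb,
                slope_above=sa,
                noise_sd=spec.noise_sd,
                ar1=spec.ar1,
                seed=int(rng.integers(2**31)),
            )
            trial_id = f"{spec.group}-{cell.condition}-{j:02d}"
            rec = generate_trace(tspec, trial_id=trial_id,
                                 subject_id=subject.id, activity=spec.activity)
            vo2 = float(np.clip(rng.normal(spec.vo2_mean, spec.vo2_sd), 0.15, 1.2))
            rer = float(np.clip(rng.normal(0.85, 0.05), 0.7, 1.0))
            rec.metabolic = (
                MetabolicSample(vo2=vo2, rer=rer, minute_mark=5.0),
                MetabolicSample(
                    vo2=float(np.clip(vo2 + rng.normal(0, 0.02), 0.15, 1.2)),
                    rer=rer, minute_mark=60.0),
            )
            bml = float(np.clip(rng.normal(spec.bml_mean, spec.bml_sd), 0.0, 2.0))
            duration = rec.trace.duration / 60.0
            mass_post = subject.mass * (1.0 - bml / 100.0)
            rec.mass_balance = MassBalance(
                mass_pre=subject.mass, mass_post=mass_post,
                duration=float(np.clip(duration, 0.75, 4.0)))
            records.append(rec)
            truth_rows.append({
                "trial_id": trial_id,
                "subject_id": subject.id,
                "group": spec.group,
                "activity": spec.activity,
                "condition": cell.condition,
                "mode": cell.mode,
                "fixed_value": cell.fixed_value,
                "true_critical": float("nan") if censored else crit,
                "censored_truth": censored,
                "slope_below_truth": tspec.slope_below,
                "slope_above_truth": tspec.slope_above,
            })
            sidx += 1
    return records, subjects, pd.DataFrame(truth_rows)


def default_cohort_spec(
    group: str,
    n_per_cell: int = reference.ASSUMED_N_PER_CELL,
    *,
    seed: Optional[int] = None,
    noise_sd: float = 0.05,
    censor_34C: Optional[int] = None,
) -> CohortSpec:
    """Study-replication cohort spec for one of the three default groups.

    Cell truths come from the published condition summaries; by default
    the 34 °C P_crit cell of the Rest arm censors 3 trials and the MinAct
    arms censor 2 (matching the study's structure).  ``n_per_cell``
    scales the arm.
    """
    g = reference.STUDY_GROUPS[group]
    cells = tuple(
        CohortCell(condition=c.condition, mode=c.mode, fixed_value=c.fixed_value,
                   n=n_per_cell, critical_mean=c.critical_mean,
                   critical_sd=c.critical_sd)
        for c in g.conditions
    )
    if censor_34C is None:
        censor_34C = 3 if g.activity == "Rest" else 2
    censor_34C = min(censor_34C, n_per_cell)
    rules = (CensorRule("34C", censor_34C),) if censor_34C else ()
    return CohortSpec(
        group=g.name, age_group=g.age_group, activity=g.activity,
        cells=cells,
        height_mean=g.height_mean, height_sd=g.height_sd,
        mass_mean=g.mass_mean, mass_sd=g.mass_sd,
        age_mean=g.age_mean, age_sd=g.age_sd,
        vo2_mean=g.vo2_mean, vo2_sd=g.vo2_sd,
        bml_mean=g.bml_mean, bml_sd=g.bml_sd,
        censor_rules=rules,
        seed=seed,
    )
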