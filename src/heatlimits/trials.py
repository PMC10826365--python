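"""Trial-level orchestration.

Models the ramp schedule (30-min equilibration, then +1 unit every
5 min), runs the inflection detector and calorimetry on one trial, and
estimates a heat-balance-based critical vapor pressure for censored
34 °C P_crit trials that never inflected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calorimetry, inflection, psychro
from .calorimetry import MassBalance, MetabolicSample, Subject
from .inflection import InflectionFit, Trace

log = logging.getLogger(__name__)

__all__ = [
    "RampSchedule",
    "TrialRecord",
    "TrialResult",
    "HeatBalanceParams",
    "build_schedule",
    "analyze_trial",
    "analyze_trials",
    "estimate_censored_limit",
    "last_completed_stage",
    "results_to_frame",
    "default_heat_balance_params",
]

#: Fixed values used in the study-replication configurations.
P_CRIT_FIXED_TDB = (34.0, 36.0, 38.0, 40.0)  # °C
T_CRIT_FIXED_PA = (12.0, 16.0)  # mmHg

#: A censored heat-balance estimate may not exceed the last completed
#: stage by more than this many mmHg.
CENSORED_CLAMP_MMHG = 5.0

MIN_TRACE_MINUTES = 45.0
MAX_MISSING_FRACTION = 0.10


class ConfigError(ValueError):
    """Invalid trial/schedule configuration."""


@dataclass(frozen=True)
class RampSchedule:
    """Commanded chamber schedule for one progressive heat-stress trial.

    The ramped variable starts at ``start_value`` and increments by
    ``step`` at the start of each ``step_interval`` beginning when the
    equilibration period ends.
    """

    mode: str  # "P_crit" (ramp P_a) | "T_crit" (ramp T_db)
    fixed_value: float
    start_value: float
    step: float = 1.0
    step_interval: float = 5.0
    equilibration: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("P_crit", "T_crit"):
            raise ConfigError(f"unknown trial mode {self.mode!r}")
        if self.step <= 0:
            raise ConfigError("step must be positive")
        if self.step_interval <= 0 or self.equilibration < 0:
            raise ConfigError("step_interval must be positive and equilibration non-negative")

    def env_at(self, t):
        """Commanded ramped-variable value at time ``t`` (min), vectorized.

        The setpoint changes at the start of each interval: during
        ``[equilibration + k·interval, equilibration + (k+1)·interval)``
        the value is ``start + (k+1)·step``.
        """
        t = np.asarray(t, dtype=float)
        k = np.floor((t - self.equilibration) / self.step_interval)
        val = np.where(t < self.equilibration, self.start_value,
                       self.start_value + (k + 1) * self.step)
        return float(val) if val.ndim == 0 else val

    def time_env_exceeds(self, value: float) -> float:
        """First time (min) at which the commanded env is strictly above ``value``."""
        if value < self.start_value:
            return 0.0
        # smallest k ≥ 0 with start + (k+1)·step > value
        k = int(np.floor((value - self.start_value) / self.step))
        return self.equilibration + k * self.step_interval

    def is_study_replication(self) -> bool:
        fixed = P_CRIT_FIXED_TDB if self.mode == "P_crit" else T_CRIT_FIXED_PA
        return any(abs(self.fixed_value - f) < 1e-9 for f in fixed)


def build_schedule(config: dict) -> RampSchedule:
    """Build a :class:`RampSchedule` from a plain config mapping.

    Requires ``mode``, ``fixed_value`` and ``start_value``; ``step``,
    ``step_interval`` and ``equilibration`` default to the study protocol
    (+1 unit / 5 min after 30 min).
    """
    try:
        sched = RampSchedule(
            mode=config["mode"],
            fixed_value=float(config["fixed_value"]),
            start_value=float(config["start_value"]),
            step=float(config.get("step", 1.0)),
            step_interval=float(config.get("step_interval", 5.0)),
            equilibration=float(config.get("equilibration", 30.0)),
        )
    except KeyError as e:
        raise ConfigError(f"schedule config missing required key {e.args[0]!r}") from None
    if not sched.is_study_replication():
        log.info("schedule fixed_value %g is outside the study-replication set",
                 sched.fixed_value)
    return sched


@dataclass(frozen=True)
class HeatBalanceParams:
    """Biophysical coefficients for the censored-trial isothermal estimate.

    Conventional still-air values; their influence on the estimate is
    bounded by the 5-mmHg clamp above the last completed stage.
    """

    t_sk: float = 36.0  # assumed mean skin temperature, °C
    h_c: float = 4.3  # convective coefficient, W·m⁻²·K⁻¹
    h_r: float = 4.7  # radiative coefficient, W·m⁻²·K⁻¹
    h_e: Optional[float] = None  # evaporative, W·m⁻²·mmHg⁻¹; default Lewis 2.2·h_c
    w_max: float = 0.65  # maximal skin wettedness

    def __post_init__(self) -> None:
        if self.h_e is None:
            object.__setattr__(self, "h_e", 2.2 * self.h_c)
        if min(self.t_sk, self.h_c, self.h_r, self.h_e, self.w_max) <= 0:
            raise ValueError("all heat-balance parameters must be positive")
        if self.w_max > 1:
            raise ValueError("w_max cannot exceed 1")


def default_heat_balance_params(age_group: str) -> HeatBalanceParams:
    """Age-group defaults differing only in maximal skin wettedness."""
    return HeatBalanceParams(w_max=0.85 if age_group == "young" else 0.65)


@dataclass
class TrialRecord:
    """One experimental trial: identity, schedule, trace and side measurements."""

    trial_id: str
    subject_id: str
    activity: str  # "MinAct" | "Rest"
    schedule: RampSchedule
    trace: Trace
    metabolic: Sequence[MetabolicSample] = field(default_factory=tuple)
    mass_balance: Optional[MassBalance] = None

    def __post_init__(self) -> None:
        if self.activity not in ("MinAct", "Rest"):
            raise ValueError(f"activity must be 'MinAct' or 'Rest', got {self.activity!r}")

    @property
    def condition(self) -> str:
        """Condition label, e.g. ``'36C'`` or ``'16mmHg'``."""
        if self.schedule.mode == "P_crit":
            return f"{self.schedule.fixed_value:g}C"
        return f"{self.schedule.fixed_value:g}mmHg"


@dataclass
class TrialResult:
    """Per-trial outcome of the full analysis."""

    trial_id: str
    subject_id: str
    activity: str
    mode: str
    condition: str
    critical_value: float  # °C (T_crit) or mmHg (P_crit); lower bound if censored
    t_db: float  # locus dry-bulb, °C
    p_a: float  # locus vapor pressure, mmHg
    censored: bool
    estimation: str  # "observed" | "censored" | "heat_balance_estimated"
    breakpoint_time: float = float("nan")
    slope_below: float = float("nan")  # °C·h⁻¹
    slope_above: float = float("nan")  # °C·h⁻¹
    m_net: float = float("nan")  # W·m⁻²
    mets: float = float("nan")
    sweat_rate: float = float("nan")  # g·m⁻²·h⁻¹
    body_mass_loss: float = float("nan")  # %

    @property
    def rh(self) -> float:
        """Relative humidity at the locus, %."""
        return float(psychro.relative_humidity(self.t_db, self.p_a,
                                               allow_supersaturation=True))


def last_completed_stage(trace: Trace, schedule: RampSchedule) -> float:
    """Env value of the last ramp stage completed in full before trace end.

    The recorded env series is authoritative over the commanded schedule.
    """
    t_end = float(trace.t[-1])
    values = np.unique(trace.env)
    tol = 1e-6
    for v in values[::-1]:
        times = trace.t[np.abs(trace.env - v) < tol]
        if times.size and times[-1] - times[0] >= schedule.step_interval - 1.0 - tol:
            return float(v)
    return float(values[0])


def estimate_censored_limit(
    m_net: float,
    t_db: float,
    last_stage: float,
    hb: HeatBalanceParams,
    *,
    correlation: str = "antoine",
) -> float:
    """Heat-balance estimate of P_crit for a trial with no observed inflection.

    Solves the compensability boundary (required evaporation equal to the
    maximum achievable) for ambient vapor pressure::

        P_est = P_sat(T_sk) − [M_net − (h_c + h_r)(T_sk − T_db)] / (w_max · h_e)

    The estimate is clamped to ``[last_stage, last_stage + 5]`` mmHg —
    censored estimates never exceed the final completed stage by more
    than 5 mmHg — so the conventional coefficient choices have bounded
    influence.
    """
    psat_sk = psychro.saturation_vapor_pressure(hb.t_sk, correlation)
    e_req = m_net - (hb.h_c + hb.h_r) * (hb.t_sk - t_db)
    # physical cap: ambient vapor pressure cannot exceed saturation at T_db
    hi = min(last_stage + CENSORED_CLAMP_MMHG,
             psychro.saturation_vapor_pressure(t_db, correlation))
    if e_req <= 0:
        log.warning("required evaporation non-positive (heat balance trivially "
                    "maintained); returning clamp upper bound %g mmHg", hi)
        return hi
    p_est = psat_sk - e_req / (hb.w_max * hb.h_e)
    return float(min(max(p_est, last_stage), hi))


def analyze_trial(
    record: TrialRecord,
    subject: Optional[Subject] = None,
    *,
    hb: Optional[HeatBalanceParams] = None,
    search_start: Optional[float] = None,
    min_slope_gap: float = inflection.DEFAULT_MIN_SLOPE_GAP,
    estimate_censored: bool = True,
    rate_window: float = 10.0,
) -> TrialResult:
    """Run the full per-trial pipeline and return a :class:`TrialResult`.

    Detection → critical env value → below/above rates → calorimetry.
    Censored P_crit trials at fixed T_db = 34 °C are routed to the
    heat-balance estimator (when a subject with metabolic data is
    available); all other censored trials stay left-censored at the last
    completed stage.
    """
    trace, sched = record.trace, record.schedule
    if trace.duration < MIN_TRACE_MINUTES:
        raise inflection.ProtocolError(
            f"trial {record.trial_id}: trace of {trace.duration:g} min is shorter "
            f"than the {MIN_TRACE_MINUTES:g}-min minimum")

    fit = inflection.detect_inflection(trace, search_start, min_slope_gap=min_slope_gap)

    a_d = subject.a_d if subject is not None else float("nan")
    m_net = mets = float("nan")
    if record.metabolic and subject is not None:
        m_net = calorimetry.trial_m_net(record.metabolic, a_d)
        mean_vo2 = float(np.mean([s.vo2 for s in record.metabolic]))
        mets = calorimetry.mets_from_vo2(mean_vo2, subject.mass)
    sr = bml = float("nan")
    if record.mass_balance is not None and subject is not None:
        sr, bml = calorimetry.sweat_rate(record.mass_balance, a_d)

    if fit.detected:
        crit = inflection.critical_env_value(trace, fit)
        slope_b, slope_a = inflection.tgi_rate_of_change(trace, fit, rate_window)
        censored, estimation = False, "observed"
        log.info("trial %s: inflection at %.1f min, critical %s = %.2f",
                 record.trial_id, fit.breakpoint_time, sched.mode, crit)
    else:
        slope_b, slope_a = float("nan"), float("nan")
        crit = last_completed_stage(trace, sched)
        censored, estimation = True, "censored"
        eligible = sched.mode == "P_crit" and abs(sched.fixed_value - 34.0) < 1e-9
        if eligible and estimate_censored and np.isfinite(m_net):
            hb_use = hb or default_heat_balance_params(
                subject.age_group if subject else "older")
            crit = estimate_censored_limit(m_net, sched.fixed_value, crit, hb_use)
            estimation = "heat_balance_estimated"
            log.info("trial %s: censored; heat-balance estimate %.2f mmHg",
                     record.trial_id, crit)
        else:
            log.info("trial %s: censored at last completed stage %.2f",
                     record.trial_id, crit)

    if sched.mode == "P_crit":
        t_db, p_a = sched.fixed_value, crit
    else:
        t_db, p_a = crit, sched.fixed_value

    return TrialResult(
        trial_id=record.trial_id,
        subject_id=record.subject_id,
        activity=record.activity,
        mode=sched.mode,
        condition=record.condition,
        critical_value=float(crit),
        t_db=float(t_db),
        p_a=float(p_a),
        censored=censored,
        estimation=estimation,
        breakpoint_time=fit.breakpoint_time if fit.detected else float("nan"),
        slope_below=slope_b,
        slope_above=slope_a,
        m_net=m_net,
        mets=mets,
        sweat_rate=sr,
        body_mass_loss=bml,
    )


def analyze_trials(
    records: Sequence[TrialRecord],
    subjects: Optional[dict[str, Subject]] = None,
    **kwargs,
) -> list[TrialResult]:
    """Analyze a batch of trials, order-preserving; errors carry the trial id."""
    subjects = subjects or {}
    out = []
    for rec in records:
        try:
            out.append(analyze_trial(rec, subjects.get(rec.subject_id), **kwargs))
        except Exception as e:
            log.error("trial %s failed: %s", rec.trial_id, e)
            raise
    return out


def results_to_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    """Tabulate trial results, one row per trial, rh derived per locus."""
    rows = []
    for r in results:
        d = {k: getattr(r, k) for k in (
            "trial_id", "subject_id", "activity", "mode", "condition",
            "critical_value", "t_db", "p_a", "censored", "estimation",
            "breakpoint_time", "slope_below", "slope_above",
            "m_net", "mets", "sweat_rate", "body_mass_loss")}
        d["rh"] = r.rh
        rows.append(d)
    return pd.DataFrame(rows)
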