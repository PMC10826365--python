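"""Default study-replication configuration.

Published condition-level critical-limit summaries and cohort
anthropometrics used as ground-truth defaults by the synthetic-data
generator, so the whole pipeline can be exercised without the original
deposited dataset.  Values are means with 95% CI bounds; per-cell SDs
are back-derived from the CIs assuming t-intervals at n = 8 trials per
cell (~49 subjects spread over 6 conditions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConditionSummary",
    "GroupDefaults",
    "STUDY_GROUPS",
    "ASSUMED_N_PER_CELL",
    "sd_from_ci",
    "SLOPE_BELOW_MEAN",
    "SLOPE_ABOVE_MEAN",
]

#: Assumed trials per condition-group cell when converting CI → SD.
ASSUMED_N_PER_CELL = 8

#: Cohort mean T_gi drift below / rise above the critical limit, °C·h⁻¹
#: (older MinAct values; used as generator defaults).
SLOPE_BELOW_MEAN = 0.10
SLOPE_BELOW_SD = 0.12
SLOPE_ABOVE_MEAN = 0.62
SLOPE_ABOVE_SD = 0.48


def sd_from_ci(lo: float, hi: float, n: int = ASSUMED_N_PER_CELL) -> float:
    """Back out a sample SD from a t-based 95% CI of the mean."""
    half = (hi - lo) / 2.0
    return half * np.sqrt(n) / stats.t.ppf(0.975, n - 1)


@dataclass(frozen=True)
class ConditionSummary:
    """One condition-group cell: mean critical point with 95% CIs.

    The ramped variable (P_a in P_crit mode, T_db in T_crit mode) is the
    one whose distribution defines the cell's critical value.
    """

    condition: str  # "34C" ... "40C", "12mmHg", "16mmHg"
    mode: str  # "P_crit" | "T_crit"
    fixed_value: float  # held-constant T_db (°C) or P_a (mmHg)
    t_db: float
    t_db_ci: tuple[float, float]
    p_a: float
    p_a_ci: tuple[float, float]
    rh: float
    rh_ci: tuple[float, float]

    @property
    def critical_mean(self) -> float:
        return self.p_a if self.mode == "P_crit" else self.t_db

    @property
    def critical_ci(self) -> tuple[float, float]:
        return self.p_a_ci if self.mode == "P_crit" else self.t_db_ci

    @property
    def critical_sd(self) -> float:
        return float(sd_from_ci(*self.critical_ci))


@dataclass(frozen=True)
class GroupDefaults:
    """Anthropometric and metabolic defaults for one study group."""

    name: str  # "older-MinAct" | "young-MinAct" | "older-Rest"
    age_group: str  # "older" | "young"
    activity: str  # "MinAct" | "Rest"
    height_mean: float  # m
    height_sd: float
    mass_mean: float  # kg
    mass_sd: float
    age_mean: float  # years
    age_sd: float
    vo2_mean: float  # L·min⁻¹, trial-level
    vo2_sd: float
    bml_mean: float  # % body-mass loss per trial
    bml_sd: float
    conditions: tuple[ConditionSummary, ...]

    def condition(self, label: str) -> ConditionSummary:
        for c in self.conditions:
            if c.condition == label:
                return c
        raise KeyError(f"no condition {label!r} in group {self.name}")


def _pcell(cond, fixed, t_db, t_ci, p_a, p_ci, rh, rh_ci):
    return ConditionSummary(cond, "P_crit", fixed, t_db, t_ci, p_a, p_ci, rh, rh_ci)


def _tcell(cond, fixed, t_db, t_ci, p_a, p_ci, rh, rh_ci):
    return ConditionSummary(cond, "T_crit", fixed, t_db, t_ci, p_a, p_ci, rh, rh_ci)


_OLDER_MINACT = (
    _pcell("34C", 34.0, 33.9, (33.7, 34.0), 25.6, (22.6, 28.6), 62.1, (52.8, 71.4)),
    _pcell("36C", 36.0, 36.2, (36.0, 36.4), 24.1, (21.7, 26.5), 53.5, (48.2, 58.8)),
    _pcell("38C", 38.0, 38.0, (37.8, 38.3), 23.0, (20.6, 25.5), 46.1, (41.7, 50.6)),
    _pcell("40C", 40.0, 40.2, (40.0, 40.3), 19.0, (16.3, 21.7), 34.0, (29.2, 38.8)),
    _tcell("16mmHg", 16.0, 40.3, (38.4, 42.2), 15.9, (15.6, 16.2), 28.6, (25.8, 31.5)),
    _tcell("12mmHg", 12.0, 42.9, (40.9, 44.8), 11.9, (11.6, 12.2), 18.8, (17.0, 20.5)),
)

_YOUNG_MINACT = (
    _pcell("34C", 34.0, 33.9, (33.7, 34.2), 31.7, (30.9, 32.5), 79.7, (77.6, 81.7)),
    _pcell("36C", 36.0, 36.0, (35.9, 36.1), 29.6, (28.6, 30.7), 66.5, (64.1, 69.0)),
    _pcell("38C", 38.0, 38.1, (37.8, 38.4), 29.7, (27.8, 31.6), 59.5, (55.5, 63.6)),
    _pcell("40C", 40.0, 40.0, (39.9, 40.1), 28.2, (26.6, 29.7), 51.0, (48.2, 53.8)),
    _tcell("16mmHg", 16.0, 46.4, (45.5, 47.3), 16.3, (16.0, 16.5), 20.7, (19.9, 21.5)),
    _tcell("12mmHg", 12.0, 49.3, (48.2, 50.4), 12.2, (12.0, 12.4), 13.8, (12.9, 14.7)),
)

_OLDER_REST = (
    _pcell("34C", 34.0, 33.9, (33.7, 34.1), 26.4, (22.7, 30.2), 66.5, (55.9, 77.1)),
    _pcell("36C", 36.0, 36.2, (35.9, 36.4), 26.4, (24.4, 28.4), 59.1, (54.6, 63.5)),
    _pcell("38C", 38.0, 38.1, (37.9, 38.3), 26.7, (24.2, 29.3), 53.4, (48.4, 58.5)),
    _pcell("40C", 40.0, 40.1, (40.0, 40.1), 21.6, (19.3, 24.0), 38.8, (34.5, 43.1)),
    _tcell("16mmHg", 16.0, 44.1, (41.8, 46.4), 16.1, (15.6, 16.5), 24.0, (21.2, 26.8)),
    _tcell("12mmHg", 12.0, 46.1, (44.1, 48.1), 11.5, (11.2, 11.9), 15.6, (13.7, 17.5)),
)

#: The three study groups with their condition-cell truths.
#: Masses are derived from BMI (mean, SD) × height² at the group mean height.
STUDY_GROUPS: dict[str, GroupDefaults] = {
    "older-MinAct": GroupDefaults(
        name="older-MinAct", age_group="older", activity="MinAct",
        height_mean=1.68, height_sd=0.1, mass_mean=73.4, mass_sd=14.1,
        age_mean=71, age_sd=6,
        vo2_mean=0.45, vo2_sd=0.10, bml_mean=0.38, bml_sd=0.20,
        conditions=_OLDER_MINACT,
    ),
    "young-MinAct": GroupDefaults(
        name="young-MinAct", age_group="young", activity="MinAct",
        height_mean=1.72, height_sd=0.1, mass_mean=74.0, mass_sd=11.8,
        age_mean=23, age_sd=4,
        vo2_mean=0.47, vo2_sd=0.09, bml_mean=0.72, bml_sd=0.35,
        conditions=_YOUNG_MINACT,
    ),
    "older-Rest": GroupDefaults(
        name="older-Rest", age_group="older", activity="Rest",
        height_mean=1.68, height_sd=0.1, mass_mean=73.4, mass_sd=14.1,
        age_mean=71, age_sd=6,
        vo2_mean=0.28, vo2_sd=0.07, bml_mean=0.27, bml_sd=0.15,
        conditions=_OLDER_REST,
    ),
}
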