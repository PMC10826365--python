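"""Condition-level critical environmental limits and psychrometric curves.

Aggregates per-trial critical loci into per-condition means with t-based
95% CIs, fits the second-order (quadratic) psychrometric limit curve
through the mean or lower-CI loci, and compares two groups' limits via a
within-condition label-permutation test (a deliberate, documented
substitute for mixed-effects modeling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import psychro

__all__ = [
    "CriticalLocus",
    "LimitCurve",
    "aggregate_loci",
    "loci_to_frame",
    "fit_psychrometric_curve",
    "compare_limit_sets",
]


def _t_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-interval bounds; (mean, nan, nan) for singletons."""
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    n = len(x)
    if n < 2:
        return m, float("nan"), float("nan")
    se = float(np.std(x, ddof=1)) / np.sqrt(n)
    h = stats.t.ppf(0.5 + level / 2, n - 1) * se
    return m, m - h, m + h


@dataclass(frozen=True)
class CriticalLocus:
    """Per condition-group mean critical point with 95% CIs.

    ``mean_rh`` is the mean of per-trial rh ratios (not the rh of the
    mean point — the two differ because rh is nonlinear in T_db).
    """

    condition: str
    group: str
    n: int
    mean_t_db: float
    ci_t_db: tuple[float, float]
    mean_p_a: float
    ci_p_a: tuple[float, float]
    mean_rh: float
    ci_rh: tuple[float, float]

    @property
    def has_ci(self) -> bool:
        return np.isfinite(self.ci_t_db[0])


def aggregate_loci(
    results: pd.DataFrame,
    *,
    group_col: str = "group",
    condition_col: str = "condition",
    level: float = 0.95,
) -> list[CriticalLocus]:
    """Aggregate per-trial loci into per condition-group critical loci.

    ``results`` needs columns ``t_db``, ``p_a`` plus the grouping
    columns; per-trial rh is derived before averaging so the rh column is
    a mean of ratios.  Singleton cells get a mean with CI flagged
    unavailable (NaN bounds).
    """
    for col in ("t_db", "p_a", condition_col, group_col):
        if col not in results.columns:
            raise ValueError(f"results frame lacks required column {col!r}")
    out = []
    for (grp, cond), cell in results.groupby([group_col, condition_col], sort=False):
        rh = psychro.relative_humidity(
            cell["t_db"].to_numpy(), cell["p_a"].to_numpy(),
            allow_supersaturation=True)
        mt, lt, ht = _t_ci(cell["t_db"].to_numpy(), level)
        mp, lp, hp = _t_ci(cell["p_a"].to_numpy(), level)
        mr, lr, hr = _t_ci(np.asarray(rh), level)
        out.append(CriticalLocus(
            condition=str(cond), group=str(grp), n=len(cell),
            mean_t_db=mt, ci_t_db=(lt, ht),
            mean_p_a=mp, ci_p_a=(lp, hp),
            mean_rh=mr, ci_rh=(lr, hr),
        ))
    return out


def loci_to_frame(loci: Sequence[CriticalLocus]) -> pd.DataFrame:
    """Summary-table layout: condition × group × {T_db, P_a, rh} with CI bounds."""
    return pd.DataFrame([{
        "group": l.group, "condition": l.condition, "n": l.n,
        "t_db_mean": l.mean_t_db, "t_db_lo": l.ci_t_db[0], "t_db_hi": l.ci_t_db[1],
        "p_a_mean": l.mean_p_a, "p_a_lo": l.ci_p_a[0], "p_a_hi": l.ci_p_a[1],
        "rh_mean": l.mean_rh, "rh_lo": l.ci_rh[0], "rh_hi": l.ci_rh[1],
    } for l in loci])


@dataclass(frozen=True)
class LimitCurve:
    """Quadratic psychrometric limit ``P_a = a·T_db² + b·T_db + c``.

    Valid only on the fitted T_db span; evaluation beyond ±1 °C of the
    span raises (the quadratic has no physical meaning out there).
    """

    a: float
    b: float
    c: float
    t_span: tuple[float, float]
    variant: str  # "mean" | "lower95"
    residuals: tuple[float, ...] = ()

    #: permitted extrapolation beyond the fitted span, °C
    EXTRAPOLATION_SLACK = 1.0

    def __call__(self, t_db) -> np.ndarray:
        t = np.asarray(t_db, dtype=float)
        lo = self.t_span[0] - self.EXTRAPOLATION_SLACK
        hi = self.t_span[1] + self.EXTRAPOLATION_SLACK
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(
                f"T_db outside fitted span [{lo:g}, {hi:g}] °C; refusing to extrapolate")
        out = self.a * t * t + self.b * t + self.c
        return float(out) if out.ndim == 0 else out

    def is_compensable(self, t_db: float, p_a: float) -> bool:
        """A point strictly below the curve is compensable."""
        return bool(p_a < self(t_db))


def fit_psychrometric_curve(
    loci: Sequence[CriticalLocus],
    variant: Literal["mean", "lower95"] = "mean",
    *,
    weight_by_n: bool = False,
) -> LimitCurve:
    """Second-order least-squares fit of P_a on T_db through the loci.

    ``variant='mean'`` fits the mean points, ``'lower95'`` the lower 95%
    CI bounds of both coordinates (the conservative limit curve drawn on
    charts).  Requires ≥3 distinct T_db values.
    """
    if variant == "mean":
        t = np.array([l.mean_t_db for l in loci])
        p = np.array([l.mean_p_a for l in loci])
    elif variant == "lower95":
        for l in loci:
            if not l.has_ci:
                raise ValueError(f"locus {l.condition}/{l.group} has no CI; "
                                 "cannot fit the lower95 variant")
        t = np.array([l.ci_t_db[0] for l in loci])
        p = np.array([l.ci_p_a[0] for l in loci])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if len(np.unique(t)) < 3:
        raise ValueError("need ≥3 distinct T_db values to fit a quadratic")
    w = np.array([l.n for l in loci], dtype=float) if weight_by_n else None
    coeffs = np.polyfit(t, p, 2, w=None if w is None else np.sqrt(w))
    resid = p - np.polyval(coeffs, t)
    return LimitCurve(
        a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]),
        t_span=(float(t.min()), float(t.max())),
        variant=variant,
        residuals=tuple(float(r) for r in resid),
    )


def compare_limit_sets(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    *,
    n_perm: int = 9999,
    seed: Optional[int] = None,
    condition_col: str = "condition",
    value_col: str = "critical_value",
) -> tuple[float, float]:
    """Within-condition permutation test of group critical-limit offset.

    The statistic is the mean over shared conditions of the difference in
    cell means (A − B).  Group labels are permuted within each condition;
    the two-sided Monte-Carlo p uses the add-one estimator.  Returns
    ``(observed_statistic, p)``.  This deliberately replaces a
    mixed-effects model with an exchangeability-based test.
    """
    conds = sorted(set(group_a[condition_col]) & set(group_b[condition_col]))
    if len(conds) < 2:
        raise ValueError("need ≥2 shared conditions between the groups")
    cells = []
    for cond in conds:
        a = group_a.loc[group_a[condition_col] == cond, value_col].to_numpy(dtype=float)
        b = group_b.loc[group_b[condition_col] == cond, value_col].to_numpy(dtype=float)
        cells.append((a, b))

    def statistic(cell_pairs) -> float:
        return float(np.mean([a.mean() - b.mean() for a, b in cell_pairs]))

    obs = statistic(cells)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = []
        for a, b in cells:
            pooled = np.concatenate([a, b])
            rng.shuffle(pooled)
            perm.append((pooled[: len(a)], pooled[len(a):]))
        if abs(statistic(perm)) >= abs(obs) - 1e-12:
            hits += 1
    return obs, (1 + hits) / (1 + n_perm)


def plot_limit_curves(
    curve_sets: dict[str, tuple[LimitCurve, Optional[LimitCurve]]],
    loci: Optional[Iterable[CriticalLocus]] = None,
    ax=None,
):
    """Chart-style plot: mean curves solid, lower95 dashed, loci as points."""
    import matplotlib.pyplot as plt

    if ax is None:
        ax = psychro.plot_psychrometric_chart()
    for label, (mean_curve, lo_curve) in curve_sets.items():
        t = np.linspace(*mean_curve.t_span, 100)
        line, = ax.plot(t, mean_curve(t), label=label)
        if lo_curve is not None:
            tl = np.linspace(*lo_curve.t_span, 100)
            ax.plot(tl, lo_curve(tl), linestyle="--", color=line.get_color(), lw=0.9)
    if loci is not None:
        for l in loci:
            ax.plot(l.mean_t_db, l.mean_p_a, "o", ms=3, color="k")
    ax.legend(fontsize=8)
    return ax
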