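"""Core-temperature inflection detection on progressive ramp trials.

A ramp trial holds one environmental variable fixed and steps the other
(+1 unit every 5 min) until core temperature departs from its plateau.
The detector fits a continuous two-segment ("hinge") linear model of
T_gi against time at every candidate breakpoint on the sampling grid and
keeps the breakpoint with the smallest total squared error.  A trial
with no convincing slope change (segmented model not better than a
single line, or slopes not separated) is reported undetected, i.e. the
trial is censored at its last completed stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "InflectionFit",
    "detect_inflection",
    "critical_env_value",
    "tgi_rate_of_change",
    "DEFAULT_MIN_SLOPE_GAP",
    "DEFAULT_SEARCH_START",
]

#: Minimum separation between above- and below-breakpoint slopes (°C·h⁻¹)
#: for a detection: below-limit drift sits near 0.07–0.10 °C·h⁻¹ and the
#: post-inflection rise near 0.6–0.7, so 0.1 separates the regimes.
DEFAULT_MIN_SLOPE_GAP = 0.1

#: Default start of the breakpoint search: end of the 30-min
#: equilibration plus 15 min for the plateau to establish.
DEFAULT_SEARCH_START = 45.0

#: Breakpoint candidates must leave at least this much trace after them (min).
MIN_TAIL = 10.0

TGI_LO, TGI_HI = 35.0, 41.0


class ProtocolError(ValueError):
    """Trace does not satisfy the ramp-protocol requirements."""


@dataclass
class Trace:
    """Synchronized per-trial time series.

    ``t`` is minutes since trial start (strictly increasing, ≤1-min
    spacing); ``env`` is the ramped variable (T_db °C or P_a mmHg) and
    ``fixed`` the held-constant variable's value.
    """

    t: np.ndarray
    t_gi: np.ndarray
    env: np.ndarray
    fixed: float
    mode: str = "P_crit"  # "P_crit" | "T_crit"
    flags: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.t_gi = np.asarray(self.t_gi, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        if not (len(self.t) == len(self.t_gi) == len(self.env)):
            raise ValueError("t, t_gi and env must have equal length")
        if len(self.t) < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(dt > 1.0 + 1e-6):
            raise ValueError("sampling interval must be ≤ 1 min")
        if np.any(~np.isfinite(self.t_gi)) or np.any(~np.isfinite(self.env)):
            raise ValueError("missing values must be cleaned before analysis")
        if self.mode not in ("P_crit", "T_crit"):
            raise ValueError(f"mode must be 'P_crit' or 'T_crit', got {self.mode!r}")
        # Physiological screen: out-of-band samples are flagged, not fatal.
        screen = (self.t_gi < TGI_LO) | (self.t_gi > TGI_HI)
        if self.flags is None:
            self.flags = screen
        if np.any(screen):
            log.warning("%d T_gi samples outside [%g, %g] °C flagged",
                        int(screen.sum()), TGI_LO, TGI_HI)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class InflectionFit:
    """Result of the segmented fit on one trace."""

    detected: bool
    breakpoint_time: float  # min
    slope_below: float  # °C·h⁻¹
    slope_above: float  # °C·h⁻¹
    sse: float
    plateau_onset: float  # min (= search start used)
    f_pvalue: float = float("nan")


def _hinge_fit(tt: np.ndarray, yy: np.ndarray, c: float) -> tuple[np.ndarray, float]:
    """OLS fit of y = a + b·(t−c) + d·max(t−c, 0); returns (beta, sse)."""
    x = tt - c
    design = np.column_stack([np.ones_like(x), x, np.maximum(x, 0.0)])
    beta, *_ = np.linalg.lstsq(design, yy, rcond=None)
    resid = yy - design @ beta
    return beta, float(resid @ resid)


def detect_inflection(
    trace: Trace,
    search_start: Optional[float] = None,
    *,
    min_slope_gap: float = DEFAULT_MIN_SLOPE_GAP,
    alpha: float = 0.05,
    free_intercept: bool = False,
) -> InflectionFit:
    """Locate the T_gi inflection by exhaustive breakpoint search.

    Candidate breakpoints are the sampling instants in
    ``[search_start, t_end − 10 min]``.  At each candidate a two-segment
    least-squares line, continuous at the breakpoint, is fit to the
    post-plateau samples; the candidate minimizing total SSE wins (ties
    broken toward the earliest breakpoint).  The fit is reported
    undetected when the above-slope does not exceed the below-slope by
    ``min_slope_gap`` (°C·h⁻¹) or when an F-test cannot reject a single
    straight line at level ``alpha``.

    ``free_intercept=True`` drops the continuity constraint (two fully
    free lines) for sensitivity analysis.
    """
    if search_start is None:
        search_start = DEFAULT_SEARCH_START
    t_end = float(trace.t[-1])
    if t_end < search_start + 20.0:
        raise ProtocolError(
            f"trace ends at {t_end:g} min; need ≥ {search_start + 20:g} min "
            f"(search start {search_start:g} + 20)"
        )

    mask = trace.t >= search_start
    tt = trace.t[mask]
    yy = trace.t_gi[mask]
    cand_mask = tt <= t_end - MIN_TAIL
    candidates = tt[cand_mask]
    # interior candidates only: need ≥2 points on each side for a free fit
    candidates = candidates[(candidates > tt[0]) & (candidates < tt[-1])]
    if candidates.size == 0:
        raise ProtocolError("no candidate breakpoints in search window")

    n = len(tt)
    best_c, best_beta, best_sse = None, None, np.inf
    for c in candidates:
        if free_intercept:
            lo, hi = tt < c, tt >= c
            if lo.sum() < 2 or hi.sum() < 2:
                continue
            b_lo = np.polyfit(tt[lo], yy[lo], 1)
            b_hi = np.polyfit(tt[hi], yy[hi], 1)
            sse = float(np.sum((yy[lo] - np.polyval(b_lo, tt[lo])) ** 2)
                        + np.sum((yy[hi] - np.polyval(b_hi, tt[hi])) ** 2))
            beta = np.array([np.polyval(b_lo, c), b_lo[0], b_hi[0] - b_lo[0]])
        else:
            beta, sse = _hinge_fit(tt, yy, c)
        if sse < best_sse - 1e-12:  # strict improvement → earliest kept on ties
            best_c, best_beta, best_sse = float(c), beta, sse

    slope_below = float(best_beta[1]) * 60.0
    slope_above = float(best_beta[1] + best_beta[2]) * 60.0

    # F-test of the segmented model against a single straight line.
    line = np.polyfit(tt, yy, 1)
    sse0 = float(np.sum((yy - np.polyval(line, tt)) ** 2))
    k_extra = 2  # breakpoint + slope change
    df_den = n - 4
    if best_sse <= 1e-12 * max(sse0, 1.0):
        # perfect segmented fit: detected iff the single line is not also perfect
        f_p = 0.0 if sse0 > 1e-10 else 1.0
    elif df_den <= 0:
        f_p = 1.0
    else:
        fstat = ((sse0 - best_sse) / k_extra) / (best_sse / df_den)
        f_p = float(stats.f.sf(max(fstat, 0.0), k_extra, df_den))

    detected = (slope_above >= slope_below + min_slope_gap) and (f_p < alpha)
    return InflectionFit(
        detected=detected,
        breakpoint_time=best_c,
        slope_below=slope_below,
        slope_above=slope_above,
        sse=best_sse,
        plateau_onset=float(search_start),
        f_pvalue=f_p,
    )


def critical_env_value(trace: Trace, fit: InflectionFit, *, window: float = 2.0) -> float:
    """Critical environmental value: mean env over the 2 min before the breakpoint.

    Averages env samples with ``breakpoint − window ≤ t < breakpoint``.
    If fewer than 2 samples fall in that window it widens to the nearest
    2 samples preceding the breakpoint, with a logged warning.
    """
    if not fit.detected:
        raise ValueError("critical value undefined for an undetected (censored) fit")
    bp = fit.breakpoint_time
    sel = (trace.t >= bp - window) & (trace.t < bp)
    if sel.sum() < 2:
        before = np.flatnonzero(trace.t < bp)
        if before.size < 2:
            raise ValueError("fewer than 2 samples precede the breakpoint")
        log.warning("fewer than 2 env samples in the %g-min pre-breakpoint "
                    "window; widening to the nearest 2 samples", window)
        sel = before[-2:]
    return float(np.mean(trace.env[sel]))


def tgi_rate_of_change(
    trace: Trace, fit: InflectionFit, window: float = 10.0
) -> tuple[float, float]:
    """Least-squares T_gi slopes below and above the breakpoint, °C·h⁻¹.

    Below uses ``[breakpoint − window, breakpoint)``, above uses
    ``(breakpoint, breakpoint + window]``.  If the post-breakpoint trace
    is shorter than ``window`` the available span is used provided it is
    at least 5 min.
    """
    if not fit.detected:
        raise ValueError("rates undefined for an undetected (censored) fit")
    bp = fit.breakpoint_time
    below = (trace.t >= bp - window) & (trace.t < bp)
    if below.sum() < 2:
        raise ValueError("fewer than 2 samples in the below-breakpoint window")
    above = (trace.t > bp) & (trace.t <= bp + window)
    span_above = float(trace.t[-1]) - bp
    if span_above < window:
        if span_above < 5.0:
            raise ValueError(
                f"only {span_above:g} min of trace after the breakpoint; need ≥ 5"
            )
        log.warning("post-breakpoint span %.1f min < window %.1f; using it", span_above, window)
    slope_b = np.polyfit(trace.t[below], trace.t_gi[below], 1)[0] * 60.0
    slope_a = np.polyfit(trace.t[above], trace.t_gi[above], 1)[0] * 60.0
    return float(slope_b), float(slope_a)
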