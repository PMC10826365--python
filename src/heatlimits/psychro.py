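"""Psychrometric primitives.

Links dry-bulb temperature (``T_db``, °C), ambient water vapor pressure
(``P_a``, mmHg) and relative humidity (``rh``, %).  All limit curves in
this package live in (T_db, P_a) coordinates; rh is always *derived*
from the pair, never stored, so inconsistent triplets cannot exist.

The saturation-pressure correlation is a named, swappable strategy
(:data:`CORRELATIONS`).  The default is the Antoine equation for water
with 1–100 °C constants, which is accurate to well under 0.1 % over the
33–50 °C band the heat-stress protocol occupies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

__all__ = [
    "PsychroState",
    "CORRELATIONS",
    "saturation_vapor_pressure",
    "relative_humidity",
    "vapor_pressure_from_rh",
    "mmhg_to_kpa",
    "kpa_to_mmhg",
    "plot_psychrometric_chart",
]

ArrayLike = Union[float, np.ndarray]

#: mmHg per kPa
MMHG_PER_KPA = 760.0 / 101.325

#: Validity range (°C) enforced for every correlation.
T_MIN, T_MAX = -10.0, 100.0


def _antoine(t_db: ArrayLike) -> ArrayLike:
    """Antoine equation for water, mmHg (constants for 1–100 °C)."""
    return 10.0 ** (8.07131 - 1730.63 / (233.426 + np.asarray(t_db, dtype=float)))


def _arden_buck(t_db: ArrayLike) -> ArrayLike:
    """Arden Buck equation (over liquid water), converted kPa → mmHg."""
    t = np.asarray(t_db, dtype=float)
    kpa = 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))
    return kpa * MMHG_PER_KPA


#: Registry of saturation-pressure strategies, each ``f(T_db °C) -> mmHg``.
CORRELATIONS: dict[str, Callable[[ArrayLike], ArrayLike]] = {
    "antoine": _antoine,
    "buck": _arden_buck,
}


def saturation_vapor_pressure(t_db: ArrayLike, correlation: str = "antoine") -> ArrayLike:
    """Saturation water vapor pressure over liquid water, in mmHg.

    Parameters
    ----------
    t_db:
        Dry-bulb temperature in °C, scalar or array.  Must lie in
        [-10, 100] °C, the validity range enforced for the bundled
        correlations.
    correlation:
        Name of the correlation strategy; see :data:`CORRELATIONS`.

    Raises
    ------
    ValueError
        If ``t_db`` falls outside [-10, 100] °C or the correlation name
        is unknown.
    """
    try:
        fn = CORRELATIONS[correlation]
    except KeyError:
        raise ValueError(
            f"unknown saturation-pressure correlation {correlation!r}; "
            f"available: {sorted(CORRELATIONS)}"
        ) from None
    t = np.asarray(t_db, dtype=float)
    if np.any(t < T_MIN) or np.any(t > T_MAX):
        raise ValueError(
            f"dry-bulb temperature outside valid range [{T_MIN}, {T_MAX}] °C"
        )
    out = fn(t)
    if np.isscalar(t_db) or np.ndim(t_db) == 0:
        return float(out)
    return out


def relative_humidity(
    t_db: ArrayLike,
    p_a: ArrayLike,
    *,
    correlation: str = "antoine",
    allow_supersaturation: bool = False,
) -> ArrayLike:
    """Relative humidity ``100 * P_a / P_sat(T_db)`` in percent.

    ``P_a`` must be non-negative.  Values above saturation raise unless
    ``allow_supersaturation`` is set (raw chamber telemetry can briefly
    overshoot the saturation line).
    """
    p = np.asarray(p_a, dtype=float)
    if np.any(p < 0):
        raise ValueError("vapor pressure must be non-negative")
    rh = 100.0 * p / np.asarray(saturation_vapor_pressure(t_db, correlation))
    if not allow_supersaturation and np.any(rh > 100.0 + 1e-9):
        raise ValueError(
            "vapor pressure exceeds saturation; pass allow_supersaturation=True "
            "to permit rh > 100%"
        )
    if np.isscalar(t_db) and np.isscalar(p_a):
        return float(rh)
    return rh


def vapor_pressure_from_rh(
    t_db: ArrayLike, rh: ArrayLike, *, correlation: str = "antoine"
) -> ArrayLike:
    """Invert :func:`relative_humidity`: vapor pressure (mmHg) at given rh (%)."""
    r = np.asarray(rh, dtype=float)
    if np.any(r < 0) or np.any(r > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    p = np.asarray(saturation_vapor_pressure(t_db, correlation)) * r / 100.0
    if np.isscalar(t_db) and np.isscalar(rh):
        return float(p)
    return p


def mmhg_to_kpa(p_mmhg: ArrayLike) -> ArrayLike:
    """Boundary helper: mmHg → kPa (internally everything is mmHg)."""
    return np.asarray(p_mmhg, dtype=float) / MMHG_PER_KPA if np.ndim(p_mmhg) else float(p_mmhg) / MMHG_PER_KPA


def kpa_to_mmhg(p_kpa: ArrayLike) -> ArrayLike:
    """Boundary helper: kPa → mmHg."""
    return np.asarray(p_kpa, dtype=float) * MMHG_PER_KPA if np.ndim(p_kpa) else float(p_kpa) * MMHG_PER_KPA


@dataclass(frozen=True)
class PsychroState:
    """A point on the psychrometric chart.

    ``rh`` is a derived property, guaranteed consistent with
    ``(t_db, p_a)`` by construction.
    """

    t_db: float  # dry-bulb temperature, °C
    p_a: float  # ambient water vapor pressure, mmHg
    correlation: str = "antoine"

    def __post_init__(self) -> None:
        if self.p_a < 0:
            raise ValueError("vapor pressure must be non-negative")
        psat = saturation_vapor_pressure(self.t_db, self.correlation)
        if self.p_a > psat * (1 + 1e-9):
            raise ValueError(
                f"P_a={self.p_a} mmHg exceeds saturation "
                f"({psat:.2f} mmHg at {self.t_db} °C)"
            )

    @property
    def rh(self) -> float:
        """Relative humidity in %, derived."""
        return float(
            relative_humidity(
                self.t_db, self.p_a, correlation=self.correlation,
                allow_supersaturation=True,
            )
        )


def plot_psychrometric_chart(
    ax=None,
    *,
    t_range: tuple[float, float] = (30.0, 52.0),
    rh_lines: tuple[float, ...] = (10, 20, 40, 60, 80, 100),
    correlation: str = "antoine",
):
    """Draw background rh iso-lines for a (T_db, P_a) chart; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    t = np.linspace(*t_range, 200)
    for rh in rh_lines:
        ax.plot(t, vapor_pressure_from_rh(t, rh, correlation=correlation),
                color="0.8", lw=0.8, zorder=0)
        ax.annotate(f"{rh:g}%", (t[-1], float(vapor_pressure_from_rh(t[-1], rh))),
                    fontsize=7, color="0.5")
    ax.set_xlabel("Dry-bulb temperature, °C")
    ax.set_ylabel("Ambient water vapor pressure, mmHg")
    ax.set_xlim(*t_range)
    ax.set_ylim(bottom=0)
    return ax
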