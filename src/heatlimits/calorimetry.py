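"""Partitional-calorimetry-derived per-trial quantities.

Body surface area (DuBois), net metabolic heat production from indirect
calorimetry, metabolic equivalents, and whole-trial sweat rate / percent
body-mass loss from pre/post nude mass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Subject",
    "MetabolicSample",
    "MassBalance",
    "dubois_bsa",
    "energy_equivalent",
    "metabolic_heat_production",
    "trial_m_net",
    "mets_from_vo2",
    "sweat_rate",
]

#: Energy equivalents of O2 (kJ per L O2) for pure-carbohydrate and
#: pure-fat oxidation; the RER interpolates linearly between them.
ENERGY_EQ_CHO = 21.13
ENERGY_EQ_FAT = 19.62

#: Assumed resting oxygen uptake defining 1 MET, mL·kg⁻¹·min⁻¹.
RESTING_VO2_ML_KG_MIN = 3.5

#: Mass-scale resolution, kg (10 g); masses are quantized before differencing.
MASS_RESOLUTION_KG = 0.010

RER_MIN, RER_MAX = 0.67, 1.3


def dubois_bsa(height_m: float, mass_kg: float) -> float:
    """DuBois body surface area (m²) from height (m) and mass (kg).

    ``A_D = 0.007184 · mass^0.425 · (100·height)^0.725``
    """
    if height_m <= 0 or mass_kg <= 0:
        raise ValueError("height and mass must be positive")
    return 0.007184 * mass_kg**0.425 * (height_m * 100.0) ** 0.725


@dataclass
class Subject:
    """One participant; ``a_d`` (DuBois area) is derived, never stored."""

    id: str
    age_group: str  # "young" | "older"
    height: float  # m
    mass: float  # kg
    age: Optional[float] = None  # years
    vo2max: Optional[float] = None  # mL·kg⁻¹·min⁻¹

    def __post_init__(self) -> None:
        if self.age_group not in ("young", "older"):
            raise ValueError(f"age_group must be 'young' or 'older', got {self.age_group!r}")
        if not 1.2 <= self.height <= 2.2:
            raise ValueError(f"height {self.height} m outside plausible range [1.2, 2.2]")
        if not 35 <= self.mass <= 200:
            raise ValueError(f"mass {self.mass} kg outside plausible range [35, 200]")

    @property
    def a_d(self) -> float:
        """DuBois body surface area, m²."""
        return dubois_bsa(self.height, self.mass)

    @property
    def a_d_per_kg(self) -> float:
        """Surface-area-to-mass ratio, m²·kg⁻¹."""
        return self.a_d / self.mass


@dataclass(frozen=True)
class MetabolicSample:
    """One open-circuit spirometry sample taken during a trial."""

    vo2: float  # L·min⁻¹
    rer: float  # dimensionless
    minute_mark: Optional[float] = None  # min into trial

    def __post_init__(self) -> None:
        if self.vo2 <= 0:
            raise ValueError("vo2 must be positive")
        if not RER_MIN <= self.rer <= RER_MAX:
            raise ValueError(f"rer {self.rer} outside physiological range [{RER_MIN}, {RER_MAX}]")


@dataclass(frozen=True)
class MassBalance:
    """Pre/post nude body mass over a trial; fluid intake disallowed."""

    mass_pre: float  # kg
    mass_post: float  # kg
    duration: float  # h

    def __post_init__(self) -> None:
        if not 0.5 < self.duration <= 4:
            raise ValueError(f"duration {self.duration} h outside (0.5, 4]")
        if self.mass_post > self.mass_pre:
            warnings.warn(
                "post-trial mass exceeds pre-trial mass (fluid intake is not "
                "allowed during trials); check the record",
                stacklevel=2,
            )


def energy_equivalent(rer: float, coefficients: tuple[float, float] = (ENERGY_EQ_CHO, ENERGY_EQ_FAT)) -> float:
    """Energy released per litre O2 (kJ·L⁻¹) at the given RER.

    Linear interpolation between the fat (RER 0.7) and carbohydrate
    (RER 1.0) equivalents, clamped outside that band.
    """
    cho, fat = coefficients
    f = min(max((rer - 0.7) / 0.3, 0.0), 1.0)
    return cho * f + fat * (1.0 - f)


def metabolic_heat_production(
    vo2: float,
    rer: float,
    a_d: float,
    external_work: float = 0.0,
    *,
    coefficients: tuple[float, float] = (ENERGY_EQ_CHO, ENERGY_EQ_FAT),
) -> float:
    """Net metabolic heat production M_net in W·m⁻².

    ``M_net = (vo2 · e(rer) · 1000/60 − external_work) / A_D`` where
    ``e(rer)`` is the O2 energy equivalent in kJ·L⁻¹.  External work is 0
    for seated rest and zero-resistance pedaling.
    """
    if a_d <= 0:
        raise ValueError("body surface area must be positive")
    if external_work < 0:
        raise ValueError("external work must be non-negative")
    if not RER_MIN <= rer <= RER_MAX:
        raise ValueError(f"rer {rer} outside physiological range [{RER_MIN}, {RER_MAX}]")
    watts = vo2 * energy_equivalent(rer, coefficients) * 1000.0 / 60.0
    return (watts - external_work) / a_d


def trial_m_net(
    samples: Sequence[MetabolicSample],
    a_d: float,
    external_work: float = 0.0,
    *,
    use: str = "mean",
) -> float:
    """Trial-level M_net from the available spirometry samples.

    With two samples (the 5- and 60-min marks) the default is their mean;
    ``use='last'`` switches to the final sample alone.  A single sample is
    used as-is with a logged warning.
    """
    if not samples:
        raise ValueError("at least one metabolic sample is required")
    if use not in ("mean", "last"):
        raise ValueError("use must be 'mean' or 'last'")
    if len(samples) == 1:
        log.warning("only one metabolic sample available; using it alone")
    picked = list(samples) if use == "mean" else [samples[-1]]
    vals = [metabolic_heat_production(s.vo2, s.rer, a_d, external_work) for s in picked]
    return sum(vals) / len(vals)


def mets_from_vo2(vo2: float, mass: float) -> float:
    """Metabolic equivalents: mass-specific V̇O2 over 3.5 mL·kg⁻¹·min⁻¹."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return (vo2 * 1000.0 / mass) / RESTING_VO2_ML_KG_MIN


def _quantize_mass(mass_kg: float) -> float:
    return round(mass_kg / MASS_RESOLUTION_KG) * MASS_RESOLUTION_KG


def sweat_rate(mb: MassBalance, a_d: float) -> tuple[float, float]:
    """Whole-trial sweat rate and percent body-mass loss.

    Returns ``(SR in g·m⁻²·h⁻¹, BML in %)``.  Both masses are quantized
    to the 10-g scale resolution before differencing, so sub-resolution
    perturbations cannot change the output.
    """
    if a_d <= 0:
        raise ValueError("body surface area must be positive")
    pre = _quantize_mass(mb.mass_pre)
    post = _quantize_mass(mb.mass_post)
    loss_kg = pre - post
    sr = loss_kg * 1000.0 / (a_d * mb.duration)
    bml = 100.0 * loss_kg / pre
    return sr, bml
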