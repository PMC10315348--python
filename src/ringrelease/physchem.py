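"""Weak-base solution physicochemistry.

Ionization, pH-dependent solubility, octanol/water distribution and
co-solvent pKa extrapolation for a monoprotic weak base (the relevant
chemistry for a diaminopyrimidine antiretroviral formulated in a silicone
elastomer ring).  All logarithms are base 10, following pharmacopoeial
convention for pKa / log P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "DrugProperties",
    "TitrationPoint",
    "ionized_fraction",
    "ph_dependent_solubility",
    "distribution_coefficient",
    "yasuda_shedlovsky_extrapolate",
    "EPSILON_WATER",
    "LOG10_WATER_MOLARITY",
]

#: Relative permittivity of pure water used as the extrapolation endpoint.
EPSILON_WATER = 78.3
#: log10 of the molar concentration of pure water (55.5 M).
LOG10_WATER_MOLARITY = math.log10(55.5)


@dataclass(frozen=True)
class DrugProperties:
    """Immutable physicochemical constants of the formulated drug.

    Parameters
    ----------
    molecular_weight : float
        g/mol.
    pKa : float
        Aqueous ionization constant of the (monoprotic, basic) drug.
    logP : float
        Octanol/water partition coefficient of the neutral species.
    intrinsic_solubility : float
        Aqueous solubility of the unionized species, µg/mL.
    medium_solubilities : mapping
        Measured saturation solubility per medium label, µg/mL.
    ring_loading : float
        Drug content per ring, µg.
    """

    molecular_weight: float
    pKa: float
    logP: float
    intrinsic_solubility: float
    ring_loading: float
    medium_solubilities: Mapping[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.pKa < 14.0:
            raise InvalidParameterError(f"pKa must lie in (0, 14), got {self.pKa}")
        if self.intrinsic_solubility <= 0:
            raise InvalidParameterError("intrinsic solubility must be positive")
        if self.ring_loading <= 0:
            raise InvalidParameterError("ring loading must be positive")
        if self.molecular_weight <= 0:
            raise InvalidParameterError("molecular weight must be positive")
        for label, s in self.medium_solubilities.items():
            if s <= 0:
                raise InvalidParameterError(
                    f"solubility in medium {label!r} must be positive, got {s}"
                )

    def solubility_in(self, medium: str) -> float:
        """Measured saturation solubility (µg/mL) in a named medium."""
        try:
            return self.medium_solubilities[medium]
        except KeyError:
            raise KeyError(
                f"no measured solubility for medium {medium!r}; "
                f"known media: {sorted(self.medium_solubilities)}"
            ) from None


@dataclass(frozen=True)
class TitrationPoint:
    """One apparent-pKa determination in a water/co-solvent mixture.

    ``apparent_pKa`` (psKa) is the ionization constant measured in the mixed
    solvent; ``dielectric_constant`` is the relative permittivity of that
    mixture and ``log_water_concentration`` the log10 molar water
    concentration in it.
    """

    cosolvent_fraction: float
    apparent_pKa: float
    dielectric_constant: float
    log_water_concentration: float = LOG10_WATER_MOLARITY

    def __post_init__(self) -> None:
        if not 0.0 <= self.cosolvent_fraction < 100.0:
            raise InvalidParameterError(
                f"co-solvent fraction must be in [0, 100), got {self.cosolvent_fraction}"
            )
        if self.dielectric_constant <= 1.0:
            raise InvalidParameterError("dielectric constant must exceed 1")


def ionized_fraction(pH, pKa):
    """Protonated (ionized) fraction of a monoprotic base.

    f = 1 / (1 + 10**(pH - pKa)).  Equals 0.5 at pH = pKa and decreases
    monotonically with pH (Henderson-Hasselbalch).
    """
    return 1.0 / (1.0 + np.power(10.0, np.asarray(pH, dtype=float) - pKa))


def ph_dependent_solubility(S0, pKa, pH):
    """Total saturation solubility of a weak base at a given pH, µg/mL.

    S(pH) = S0 * (1 + 10**(pKa - pH)): the neutral species saturates at the
    intrinsic solubility S0 while the protonated form adds capacity at low
    pH.  Always >= S0.
    """
    if np.any(np.asarray(S0) <= 0):
        raise InvalidParameterError("intrinsic solubility S0 must be positive")
    return np.asarray(S0, dtype=float) * (
        1.0 + np.power(10.0, pKa - np.asarray(pH, dtype=float))
    )


def distribution_coefficient(logP, pKa, pH):
    """pH-dependent octanol/water distribution coefficient, log D.

    log D = log P - log10(1 + 10**(pKa - pH)), assuming only the neutral
    species partitions into octanol (ion-pair partition neglected).
    Approaches log P at high pH where the base is unionized.
    """
    return logP - np.log10(1.0 + np.power(10.0, pKa - np.asarray(pH, dtype=float)))


def yasuda_shedlovsky_extrapolate(
    points: Sequence[TitrationPoint],
    *,
    epsilon_water: float = EPSILON_WATER,
    log_water_concentration_water: float = LOG10_WATER_MOLARITY,
    mode: str = "dielectric",
) -> tuple[float, float]:
    """Extrapolate apparent pKa values in co-solvent mixtures to pure water.

    The default ``dielectric`` mode regresses (psKa + log[H2O]) against the
    reciprocal dielectric constant 1/eps of each mixture and evaluates the
    line at the pure-water point (1/eps_water, log[H2O]_water):

        psKa + log[H2O] = m / eps + c
        pKa(aq) = m / eps_water + c - log[H2O]_water

    ``mode="cosolvent"`` instead regresses psKa linearly against the
    co-solvent fraction and evaluates at 0% — a cruder variant offered for
    instruments that report that abscissa.

    Returns
    -------
    (aqueous_pKa, r_squared)
    """
    if len(points) < 3:
        raise InsufficientDataError(
            f"co-solvent extrapolation needs >= 3 titration points, got {len(points)}"
        )
    if mode == "dielectric":
        x = np.array([1.0 / p.dielectric_constant for p in points])
        y = np.array([p.apparent_pKa + p.log_water_concentration for p in points])
    elif mode == "cosolvent":
        x = np.array([p.cosolvent_fraction for p in points])
        y = np.array([p.apparent_pKa for p in points])
    else:  # pragma: no cover - guarded API misuse
        raise InvalidParameterError(f"unknown extrapolation mode {mode!r}")
    if np.ptp(x) == 0.0:
        raise InsufficientDataError("titration points have degenerate abscissa")

    fit = stats.linregress(x, y)
    if mode == "dielectric":
        pka = (
            fit.slope / epsilon_water
            + fit.intercept
            - log_water_concentration_water
        )
    else:
        pka = fit.intercept
    return float(pka), float(fit.rvalue**2)
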