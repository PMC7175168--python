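"""Thermodynamics of bond formation: Boltzmann link between the Gibbs free
energy of a single inter-monomer bond and the equilibrium bonding probability.

Because every bond site is an independent two-state system, the equilibrium
occupancy follows Boltzmann statistics,

    Pb = e^(-dG/RT) / (1 + e^(-dG/RT)),

a logistic function of dG/RT. The mass-action equilibrium constant
kappa = k-/k+ carries units of concentration in this model (the common
dimensionless e^(dG/RT) is inconsistent here), so it also depends on the
total monomer-unit concentration [U].

Energies are kcal/mol and temperatures kelvin throughout; the CLI accepts
degrees Celsius and converts by +273.15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy.special import expit, log_expit

from .errors import DomainError

__all__ = [
    "R_KCAL",
    "ThermoParameters",
    "Regime",
    "prob_from_energy",
    "energy_from_prob",
    "kappa_from_energy",
    "decompose_enthalpy_entropy",
    "classify_regime",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.987204e-3


def celsius_to_kelvin(t_c: float) -> float:
    return float(t_c) + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return float(t_k) - 273.15


def _check_T(T: float) -> float:
    T = float(T)
    if not T > 0:
        raise DomainError(f"absolute temperature T={T!r} must be > 0 K")
    return T


@dataclass(frozen=True)
class ThermoParameters:
    """Bond-formation thermodynamics: dG (kcal/mol) at temperature T (K),
    optionally decomposed into enthalpy dH (kcal/mol) and entropy dS
    (kcal mol^-1 K^-1) with dG = dH - T dS."""

    dG: float
    T: float
    dH: float | None = None
    dS: float | None = None

    def __post_init__(self) -> None:
        _check_T(self.T)
        if self.dH is not None and self.dS is not None:
            implied = self.dH - self.T * self.dS
            scale = max(abs(self.dG), abs(implied), 1e-300)
            if abs(implied - self.dG) > 1e-9 * scale:
                raise DomainError(
                    f"dG={self.dG} inconsistent with dH - T*dS = {implied} at T={self.T}"
                )

    @property
    def Pb(self) -> float:
        return prob_from_energy(self.dG, self.T)


def prob_from_energy(dG: float, T: float) -> float:
    """Equilibrium bonding probability Pb = (1 + e^(dG/RT))^-1.

    Evaluated with a numerically stable logistic; strictly decreasing in dG.
    """
    T = _check_T(T)
    return float(expit(-float(dG) / (R_KCAL * T)))


def energy_from_prob(Pb: float, T: float) -> float:
    """Bond free energy dG = -RT ln(Pb/(1-Pb)), the exact inverse of
    :func:`prob_from_energy`. Pb in the open interval (0, 1)."""
    T = _check_T(T)
    Pb = float(Pb)
    if not 0.0 < Pb < 1.0:
        raise DomainError(f"Pb={Pb!r} must lie strictly inside (0, 1)")
    return -R_KCAL * T * (math.log(Pb) - math.log1p(-Pb))


def kappa_from_energy(dG: float, T: float, U: float) -> float:
    """Dimensional equilibrium constant kappa = [U] e^(g) / (1 + e^(-g)),
    g = dG/RT, in mol/L. Identical to (1-Pb)^2 U / Pb with Pb from
    :func:`prob_from_energy`."""
    T = _check_T(T)
    U = float(U)
    if not U > 0:
        raise DomainError(f"U={U!r} must be > 0")
    g = float(dG) / (R_KCAL * T)
    # e^g / (1 + e^-g) = exp(g + log sigma(g)); stable for g of either sign
    return U * math.exp(g + float(log_expit(g)))


def decompose_enthalpy_entropy(
    dG1: float, T1: float, dG2: float, T2: float
) -> tuple[float, float]:
    """Split bond free energies at two temperatures into (dH, dS).

    Assumes dH and dS are temperature-independent, so dG(T) = dH - T dS is
    linear: dS = -(dG2 - dG1)/(T2 - T1) and dH = dG1 + T1 dS. The returned
    pair reproduces both inputs exactly.
    """
    T1, T2 = _check_T(T1), _check_T(T2)
    if T1 == T2:
        raise DomainError("decomposition requires two distinct temperatures")
    dS = -(float(dG2) - float(dG1)) / (T2 - T1)
    dH = float(dG1) + T1 * dS
    return dH, dS


class Regime(str, Enum):
    """Temperature dependence of bond favorability, by the signs of (dH, dS)."""

    FAVORABLE_ABOVE_TC = "favorable above Tc"  # dH > 0, dS > 0
    UNFAVORABLE_ALL_T = "unfavorable at all T"  # dH > 0, dS < 0
    FAVORABLE_ALL_T = "favorable at all T"  # dH < 0, dS > 0
    FAVORABLE_BELOW_TC = "favorable below Tc"  # dH < 0, dS < 0


def classify_regime(dH: float, dS: float) -> tuple[Regime, float | None]:
    """Classify the temperature dependence of bond formation.

    Returns the regime label and, when dH and dS share a sign, the critical
    temperature Tc = dH/dS (K) at which dG = 0 and Pb crosses 1/2. When the
    signs differ there is no sign change and Tc is None. dS = 0 with dH != 0
    is the degenerate temperature-independent case (favorability fixed by
    the sign of dH); both zero is rejected.
    """
    dH, dS = float(dH), float(dS)
    if dH == 0.0 and dS == 0.0:
        raise DomainError("dH and dS cannot both be zero")
    if dS == 0.0:
        regime = Regime.FAVORABLE_ALL_T if dH < 0 else Regime.UNFAVORABLE_ALL_T
        return regime, None
    if dH == 0.0:
        # dG = -T dS never changes sign for T > 0
        regime = Regime.FAVORABLE_ALL_T if dS > 0 else Regime.UNFAVORABLE_ALL_T
        return regime, None
    if dH > 0 and dS > 0:
        return Regime.FAVORABLE_ABOVE_TC, dH / dS
    if dH > 0 and dS < 0:
        return Regime.UNFAVORABLE_ALL_T, None
    if dH < 0 and dS > 0:
        return Regime.FAVORABLE_ALL_T, None
    return Regime.FAVORABLE_BELOW_TC, dH / dS
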