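"""Rate-constant parameterization and the exact dynamics of the bonding
probability p(t).

A well-mixed polyaddition system with association rate constant k+
(L mol^-1 s^-1) and bond dissociation rate k- (s^-1) drives the single
Flory-Schulz parameter p through the Riccati equation

    dp/dt = k+ [U] (1 - p)^2 - k- p,

whose steady state is Pb = 1 + kbar - sqrt(kbar (2 + kbar)) with
kbar = k-/(2 k+ [U]). The equation is separable and solves in closed form
as a shifted/scaled tanh of time; when the initial condition starts below
the steady state the printed inverse-tanh argument exceeds 1 and the
solution continues analytically on the coth branch. The irreversible case
k- = 0 degenerates to a rational solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .thermodynamics import kappa_from_energy, prob_from_energy

__all__ = [
    "RateConstants",
    "ClosedFormSolution",
    "steady_state_probability",
    "dp_dt",
    "solve_p",
    "p_closed_form",
    "critical_concentration",
    "dXn_dt",
    "rate_from_thermo",
]

#: hyperbolic arguments beyond this are clamped; tanh/coth are 1 to machine
#: precision long before, so the asymptote Pb is returned exactly.
HYP_ARG_MAX = 350.0

#: |p0 - Pb| below this selects the constant branch
BRANCH_TOL = 1e-12


@dataclass(frozen=True)
class RateConstants:
    """Bonding rate constant k+ (L mol^-1 s^-1) and unbonding rate k- (s^-1)."""

    kplus: float
    kminus: float

    def __post_init__(self) -> None:
        if not self.kplus > 0:
            raise DomainError(f"kplus={self.kplus!r} must be > 0")
        if not self.kminus >= 0:
            raise DomainError(f"kminus={self.kminus!r} must be >= 0")

    @property
    def kappa(self) -> float:
        """Equilibrium constant kappa = k-/k+, mol/L; equals the critical
        concentration."""
        return self.kminus / self.kplus

    def kappa_bar(self, U: float) -> float:
        """Reduced (dimensionless) equilibrium constant kappa/(2 U)."""
        _check_U(U)
        return self.kappa / (2.0 * U)

    def delta(self, U: float) -> float:
        """Delta = sqrt(kbar (2 + kbar)), the dimensionless rate scale."""
        kb = self.kappa_bar(U)
        return math.sqrt(kb * (2.0 + kb))


def _check_U(U: float) -> float:
    U = float(U)
    if not U > 0:
        raise DomainError(f"U={U!r} must be > 0")
    return U


def steady_state_probability(rates: RateConstants, U: float) -> float:
    """Steady-state bonding probability Pb = 1 + kbar - sqrt(kbar (2 + kbar)).

    This is the unique root in [0, 1] of the Hill-Langmuir fixed point
    Pb = (1-Pb) U / ((1-Pb) U + kappa); the other quadratic root 1+kbar+Delta
    exceeds 1 for all kbar > 0.
    """
    _check_U(U)
    kb = rates.kappa_bar(U)
    # rationalized form of 1 + kb - sqrt(kb (2 + kb)): avoids catastrophic
    # cancellation when kb is large (Pb near 0)
    return 1.0 / (1.0 + kb + math.sqrt(kb * (2.0 + kb)))


def dp_dt(p: float, rates: RateConstants, U: float) -> float:
    """Time derivative of the bonding probability, 1/s:
    dp/dt = U k+ (1-p)^2 - k- p."""
    _check_U(U)
    p = float(p)
    return U * rates.kplus * (1.0 - p) ** 2 - rates.kminus * p


def _arcoth(x: float) -> float:
    # arcoth(x) = artanh(1/x), |x| > 1
    return math.atanh(1.0 / x)


@dataclass(frozen=True)
class ClosedFormSolution:
    """Exact solution of dp/dt = U k+ (1-p)^2 - k- p with p(0) = p0.

    ``branch`` records which analytic continuation applies: ``tanh`` when
    p0 > Pb (relaxation from above), ``coth`` when p0 < Pb (growth from
    below; the tanh-form integration constant would be complex),
    ``constant`` when p0 = Pb, and ``irreversible`` when k- = 0.
    ``rate_scale`` = Delta k+ U (1/s) sets the relaxation time; ``c`` is the
    integration constant fixed by the initial condition.
    """

    p0: float
    Pb: float
    kappa_bar: float
    Delta: float
    branch: str
    c: float
    rate_scale: float
    kplus: float
    U: float

    def p(self, t):
        """Evaluate p(t); accepts scalars or arrays of times (s >= 0)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("time t must be >= 0")
        if self.branch == "constant":
            out = np.full_like(t, self.Pb)
        elif self.branch == "irreversible":
            out = 1.0 - 1.0 / (1.0 / (1.0 - self.p0) + self.kplus * self.U * t)
        else:
            arg = np.minimum(self.rate_scale * t + self.c, HYP_ARG_MAX)
            if self.branch == "tanh":
                out = 1.0 + self.kappa_bar - self.Delta * np.tanh(arg)
            else:  # coth
                out = 1.0 + self.kappa_bar - self.Delta / np.tanh(arg)
            # past the clamp both branches are at the asymptote exactly
            out = np.where(self.rate_scale * t + self.c > HYP_ARG_MAX, self.Pb, out)
        return out if out.ndim else float(out)


def solve_p(p0: float, rates: RateConstants, U: float) -> ClosedFormSolution:
    """Construct the closed-form solution of the bonding-probability ODE."""
    _check_U(U)
    p0 = float(p0)
    if not 0.0 <= p0 < 1.0:
        raise DomainError(f"initial bonding probability p0={p0!r} outside [0, 1)")
    if rates.kminus == 0.0:
        return ClosedFormSolution(
            p0=p0, Pb=1.0, kappa_bar=0.0, Delta=0.0, branch="irreversible",
            c=0.0, rate_scale=rates.kplus * U, kplus=rates.kplus, U=U,
        )
    kb = rates.kappa_bar(U)
    Delta = rates.delta(U)
    Pb = 1.0 / (1.0 + kb + Delta)  # stable form of 1 + kb - Delta
    rate_scale = Delta * rates.kplus * U
    if abs(p0 - Pb) <= BRANCH_TOL:
        branch, c = "constant", 0.0
    else:
        arg0 = (1.0 + kb - p0) / Delta  # = 1 at p0 = Pb
        if p0 > Pb:
            branch, c = "tanh", math.atanh(arg0)
        else:
            branch, c = "coth", _arcoth(arg0)
    return ClosedFormSolution(
        p0=p0, Pb=Pb, kappa_bar=kb, Delta=Delta, branch=branch, c=c,
        rate_scale=rate_scale, kplus=rates.kplus, U=U,
    )


def p_closed_form(t, p0: float, rates: RateConstants, U: float):
    """Bonding probability at time(s) ``t`` for initial condition ``p0``.

    Monotone in t toward the steady state Pb, bounded between p0 and Pb.
    """
    return solve_p(p0, rates, U).p(t)


def critical_concentration(rates: RateConstants) -> float:
    """Free-monomer concentration in the [U] -> infinity limit: Cc = kappa."""
    return rates.kappa


def dXn_dt(Xn: float, rates: RateConstants, U: float) -> float:
    """Growth rate of the number-average degree of polymerization,
    dX̄n/dt = k+ U - k- X̄n (X̄n - 1).

    Obtained from the bonding-probability ODE by the chain rule with
    X̄n = 1/(1-p): dX̄n/dt = (1-p)^-2 dp/dt. In the irreversible case the
    growth is linear at rate k+ U for all X̄n.
    """
    _check_U(U)
    Xn = float(Xn)
    if Xn < 1.0:
        raise DomainError(f"degree of polymerization Xn={Xn!r} must be >= 1")
    return rates.kplus * U - rates.kminus * Xn * (Xn - 1.0)


def rate_from_thermo(kminus: float, dG: float, T: float, U: float) -> RateConstants:
    """Infer k+ from an unbonding rate and bond free energy:
    k+ = k- / kappa(dG, T, U).

    The resulting steady-state bonding probability equals the Boltzmann
    probability at (dG, T) by construction.
    """
    kminus = float(kminus)
    if not kminus > 0:
        raise DomainError("cannot infer kplus from kminus = 0 (kappa would vanish)")
    kappa = kappa_from_energy(dG, T, U)
    rates = RateConstants(kplus=kminus / kappa, kminus=kminus)
    # construction guarantees agreement; assert cheaply for early fault detection
    assert abs(steady_state_probability(rates, U) - prob_from_energy(dG, T)) < 1e-9
    return rates
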