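"""Numerical integration of the truncated mass-action ODE system for k-mer
concentrations.

The infinite reaction family P_i + P_j <-> P_(i+j) is truncated by excluding
a priori every reaction that would produce a chain longer than d (rather
than deleting long chains after the fact, which would leak mass and drive
the system to zero). The resulting d-dimensional system is

    dx_k/dt = sum_{l=1}^{d-k} (2 k- x_{k+l} - 2 k+ x_k x_l)
            + sum_{l=1}^{k-1} k+ x_l x_{k-l}  -  (k-1) k- x_k,

which conserves the total monomer-unit concentration U = sum_k k x_k
exactly. The factor 2 in the first sum reflects that a k-mer can be either
partner of a bonding event (and either fragment of a scission).

The right-hand side is evaluated in O(d log d) via prefix sums and an FFT
self-convolution fallback to numpy's direct convolution; an analytic
Jacobian is supplied to the stiff integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConsistencyError, DomainError, NumericalError
from .kinetics import RateConstants, steady_state_probability

__all__ = [
    "TruncatedSystem",
    "Trajectory",
    "monomers",
    "flory_schulz_init",
    "rhs",
    "naive_deletion_rhs",
    "jacobian",
    "integrate",
    "steady_state",
    "bonding_probability_of_state",
]

#: default truncation-length cap; the RHS costs O(d^2) per Jacobian
D_CAP = 2000

#: mass-conservation tolerance required of trajectories (relative)
MASS_TOL = 1e-6


def monomers(U: float, d: int) -> np.ndarray:
    """All-monomer initial condition: x_1 = U, x_k = 0 for k > 1."""
    x0 = np.zeros(int(d))
    x0[0] = float(U)
    return x0


def flory_schulz_init(p: float, U: float, d: int) -> np.ndarray:
    """Flory-Schulz initial condition on the finite length grid 1..d.

    The infinite distribution is truncated at d and then rescaled
    proportionally so the total monomer-unit mass is exactly U (the tail
    mass is redistributed across all lengths in proportion).
    """
    if not 0.0 <= p < 1.0:
        raise DomainError(f"p={p!r} outside [0, 1)")
    k = np.arange(1, int(d) + 1, dtype=float)
    x = (1.0 - p) ** 2 * p ** (k - 1.0) * float(U)
    mass = float(k @ x)
    if mass == 0.0:
        raise DomainError("degenerate initial distribution")
    return x * (float(U) / mass)


@dataclass(frozen=True)
class TruncatedSystem:
    """A d-dimensional truncation of the polymerization network.

    ``x0`` holds initial k-mer concentrations (mol/L) for k = 1..d at
    indices 0..d-1. The conserved total monomer-unit concentration U is
    derived from x0.
    """

    d: int
    rates: RateConstants
    x0: np.ndarray

    def __post_init__(self) -> None:
        if self.d < 1:
            raise DomainError(f"truncation length d={self.d} must be >= 1")
        if self.d > D_CAP:
            raise DomainError(
                f"d={self.d} exceeds the default cap {D_CAP}; construct with a "
                "smaller d or build the system manually"
            )
        x0 = np.asarray(self.x0, dtype=float)
        if x0.shape != (self.d,):
            raise DomainError(f"x0 must have shape ({self.d},), got {x0.shape}")
        if np.any(x0 < 0):
            raise DomainError("initial concentrations must be nonnegative")
        object.__setattr__(self, "x0", x0)
        if not self.U > 0:
            raise DomainError("total monomer-unit mass of x0 must be positive")

    @property
    def U(self) -> float:
        k = np.arange(1, self.d + 1, dtype=float)
        return float(k @ self.x0)


@dataclass(frozen=True)
class Trajectory:
    """Time evolution of a truncated system: times (s, strictly increasing,
    starting at 0) and the matrix of states (len(times) x d, mol/L)."""

    times: np.ndarray
    states: np.ndarray
    U: float

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def mass_drift(self) -> float:
        """Maximum relative deviation of total monomer-unit mass from U."""
        k = np.arange(1, self.states.shape[1] + 1, dtype=float)
        masses = self.states @ k
        return float(np.max(np.abs(masses - self.U)) / self.U)

    def bonding_probabilities(self) -> np.ndarray:
        """p(t) extracted from each state as (U - total molecules)/U."""
        total = self.states.sum(axis=1)
        return np.clip((self.U - total) / self.U, 0.0, 1.0)


def rhs(x: np.ndarray, rates: RateConstants, d: int | None = None) -> np.ndarray:
    """Mass-action right-hand side of the truncated system.

    Annihilates the mass functional exactly: sum_k k * rhs_k = 0.
    """
    x = np.asarray(x, dtype=float)
    if d is None:
        d = x.size
    if x.shape != (d,):
        raise DomainError(f"state must have shape ({d},)")
    if np.any(x < 0):
        raise DomainError("concentrations must be nonnegative")
    return _rhs_unchecked(x, rates.kplus, rates.kminus)


def _rhs_unchecked(x: np.ndarray, kp: float, km: float) -> np.ndarray:
    d = x.size
    if d == 1:
        return np.zeros(1)
    # prefix[m] = sum_{l=1}^{m} x_l ; suffix[k] = sum_{j=k+1}^{d} x_j
    csum = np.cumsum(x)
    total = csum[-1]
    suffix = total - csum  # suffix[k-1] = sum_{j>k} x_j
    prefix_dmk = csum[::-1].copy()
    prefix_dmk[-1] = 0.0  # k = d: empty partner sum
    # prefix_dmk[k-1] = sum_{l=1}^{d-k} x_l = csum[d-k-1] for k < d
    prefix_dmk[:-1] = csum[d - 2 :: -1]
    conv = np.convolve(x, x)[: d - 1]  # conv[k-2] = sum_{l=1}^{k-1} x_l x_{k-l}
    out = 2.0 * km * suffix - 2.0 * kp * x * prefix_dmk
    out[1:] += kp * conv
    k = np.arange(1, d + 1, dtype=float)
    out -= (k - 1.0) * km * x
    return out


def naive_deletion_rhs(x: np.ndarray, rates: RateConstants) -> np.ndarray:
    """The *wrong* truncation, kept as a documented counterexample.

    Keeps the infinite-system equation but zeroes all lengths above d, i.e.
    chains that grow past d are silently deleted. Mass is not conserved:
    every over-length bonding event removes material permanently and the
    system decays toward x = 0.
    """
    x = np.asarray(x, dtype=float)
    d = x.size
    kp, km = rates.kplus, rates.kminus
    total = float(x.sum())
    csum = np.cumsum(x)
    suffix = total - csum
    conv = np.convolve(x, x)[: d - 1]
    out = 2.0 * km * suffix - 2.0 * kp * x * total  # partner sum over ALL lengths
    out[1:] += kp * conv
    k = np.arange(1, d + 1, dtype=float)
    out -= (k - 1.0) * km * x
    return out


def jacobian(x: np.ndarray, rates: RateConstants) -> np.ndarray:
    """Dense analytic Jacobian of :func:`rhs` at state x."""
    x = np.asarray(x, dtype=float)
    d = x.size
    kp, km = rates.kplus, rates.kminus
    J = np.zeros((d, d))
    csum = np.cumsum(x)
    prefix_dmk = np.zeros(d)
    if d > 1:
        prefix_dmk[:-1] = csum[d - 2 :: -1]
    kk = np.arange(1, d + 1)
    # dissociation gain: +2 k- for every m > k
    J += 2.0 * km * (kk[None, :] > kk[:, None])
    # bonding loss: -2 k+ (delta_km * prefix + x_k * [m <= d-k])
    J[np.diag_indices(d)] -= 2.0 * kp * prefix_dmk
    J -= 2.0 * kp * x[:, None] * (kk[None, :] <= (d - kk)[:, None])
    # formation gain: +2 k+ x_{k-m} for 1 <= m <= k-1
    rows, cols = np.tril_indices(d, k=-1)  # k > m (0-based: row > col)
    J[rows, cols] += 2.0 * kp * x[rows - cols - 1]
    # scission loss of k itself
    J[np.diag_indices(d)] -= (kk - 1.0) * km
    return J


def integrate(
    system: TruncatedSystem,
    t_end: float,
    rtol: float = 1e-8,
    atol: float | None = None,
    n_points: int = 200,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the truncated system to ``t_end`` seconds.

    Uses an adaptive stiff-capable solver with the analytic Jacobian. Output
    times are logarithmically spaced by default (the relaxation time
    1/(Delta k+ U) typically spans decades), always including t = 0.
    """
    if not t_end > 0:
        raise DomainError(f"t_end={t_end!r} must be > 0")
    if atol is None:
        atol = 1e-12 * system.U
    if t_eval is None:
        t_eval = np.concatenate(
            [[0.0], np.geomspace(t_end * 1e-6, t_end, int(n_points))]
        )
    rates = system.rates
    sol = solve_ivp(
        lambda t, x: _rhs_unchecked(x, rates.kplus, rates.kminus),
        (0.0, float(t_end)),
        system.x0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=lambda t, x: jacobian(x, rates),
    )
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    traj = Trajectory(times=sol.t, states=sol.y.T, U=system.U)
    drift = traj.mass_drift()
    if drift > MASS_TOL:
        raise NumericalError(
            f"mass conservation violated along trajectory (relative drift {drift:.3e})"
        )
    return traj


@dataclass
class SteadyStateResult:
    """Steady state of a truncated system with convergence diagnostics."""

    x: np.ndarray
    residual: float
    t_elapsed: float
    converged: bool
    warning: str | None = None


def steady_state(
    system: TruncatedSystem,
    tol: float = 1e-10,
    rtol: float = 1e-10,
) -> SteadyStateResult:
    """Integrate until the RHS residual is negligible.

    Convergence criterion: ||rhs(x)|| <= tol * k+ * U * ||x||. Integration
    proceeds in geometrically growing time chunks up to a cap of
    100/(Delta k+ U) model seconds (100 relaxation times); if the residual
    criterion is still unmet the state is returned with a warning rather
    than raising.
    """
    rates, U, d = system.rates, system.U, system.d
    if d == 1:
        return SteadyStateResult(x=system.x0.copy(), residual=0.0, t_elapsed=0.0, converged=True)
    kb = rates.kappa_bar(U)
    Delta = math.sqrt(kb * (2.0 + kb))
    rate_scale = Delta * rates.kplus * U if Delta > 0 else rates.kplus * U
    t_cap = 100.0 / rate_scale
    scale = rates.kplus * U

    x = system.x0.copy()
    t = 0.0
    t_chunk = 0.1 / rate_scale
    while t < t_cap:
        t_next = min(t + t_chunk, t_cap)
        sol = solve_ivp(
            lambda tt, xx: _rhs_unchecked(xx, rates.kplus, rates.kminus),
            (t, t_next),
            x,
            method="LSODA",
            rtol=rtol,
            atol=1e-14 * U,
            jac=lambda tt, xx: jacobian(xx, rates),
        )
        if not sol.success:
            raise NumericalError(f"steady-state integration failed: {sol.message}")
        x = sol.y[:, -1]
        t = t_next
        t_chunk *= 2.0
        res = float(np.linalg.norm(_rhs_unchecked(x, rates.kplus, rates.kminus)))
        if res <= tol * scale * float(np.linalg.norm(x)):
            return SteadyStateResult(x=x, residual=res, t_elapsed=t, converged=True)
    res = float(np.linalg.norm(_rhs_unchecked(x, rates.kplus, rates.kminus)))
    return SteadyStateResult(
        x=x, residual=res, t_elapsed=t, converged=False,
        warning=f"residual {res:.3e} above tolerance at the time cap {t_cap:.3e} s",
    )


def bonding_probability_of_state(x: np.ndarray, U: float) -> float:
    """Bonding probability of an arbitrary length distribution.

    Every molecule carries exactly one unbound A terminus, so the bond
    concentration is [AB] = U - sum_k x_k and p = (U - sum_k x_k)/U.
    The state's monomer-unit mass must match U to 1e-3 relative.
    """
    x = np.asarray(x, dtype=float)
    k = np.arange(1, x.size + 1, dtype=float)
    mass = float(k @ x)
    if abs(mass - U) > 1e-3 * U:
        raise ConsistencyError(
            f"state mass {mass!r} inconsistent with declared U={U!r}"
        )
    return float(np.clip((U - x.sum()) / U, 0.0, 1.0))


def detailed_balance_steady_state(rates: RateConstants, U: float, d: int) -> np.ndarray:
    """Closed-form steady state of the truncated system via detailed balance.

    At equilibrium every reaction pair balances: k+ x_i x_j = k- x_{i+j},
    forcing the finite geometric form x_k = a (a/kappa)^(k-1). The free
    monomer concentration a is fixed by the mass constraint
    sum_{k=1}^{d} k x_k = U, solved here by bisection. Used as an
    independent oracle for the integrator and exposed for convenience.
    """
    from scipy.optimize import brentq

    if rates.kminus == 0.0:
        raise DomainError("detailed balance requires kminus > 0")
    kappa = rates.kappa
    k = np.arange(1, d + 1, dtype=float)

    def mass(a: float) -> float:
        r = a / kappa
        return float(np.sum(k * a * r ** (k - 1.0)))

    hi = float(U)
    lo = 0.0
    a = brentq(lambda a: mass(a) - U, lo, hi, xtol=1e-300, rtol=1e-15)
    return a * (a / kappa) ** (k - 1.0)
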