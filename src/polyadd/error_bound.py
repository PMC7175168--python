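"""Lower bound on the error of any mass-preserving finite truncation of the
polymer length distribution.

A Flory-Schulz distribution assigns nonzero concentration to every length,
so any simulation state restricted to lengths 1..d differs from it. The
nearest (in l2) d-dimensional vector with the correct total monomer-unit
mass is the orthogonal projection obtained by least squares: drop the tail
y = n(d+1..inf), then add the minimum-norm correction delta_x whose mass
equals the tail mass My. All three pieces have closed forms for a geometric
distribution:

    My            = U (1 + d(1-p)) p^d
    ||y||^2       = (1-p)^4 U^2 p^(2d) / (1-p^2)
    ||delta_x||^2 = My^2 / S,   S = sum_{k<=d} k^2 = d(d+1)(2d+1)/6

giving the relative l2 error lower bound

    E(p, d) = p^d sqrt(1 + 6 (1+d(1-p))^2 (1-p^2) / (d(d+1)(2d+1) (1-p)^4)),

strictly greater than, but asymptotically equal to, the lax bound p^d.
Inverting E for d gives the minimum truncation length compatible with a
target relative error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "TruncationErrorReport",
    "tail_mass",
    "tail_norm_sq",
    "norm_sq",
    "correction_norm_sq",
    "relative_error_bound",
    "project",
    "min_d_lax",
    "min_d_full",
    "report",
]


def _check_pd(p: float, d: int) -> tuple[float, int]:
    p = float(p)
    if not 0.0 <= p < 1.0:
        raise DomainError(f"p={p!r} outside [0, 1)")
    d = int(d)
    if d < 1:
        raise DomainError(f"truncation length d={d} must be >= 1")
    return p, d


def tail_mass(p: float, U: float, d: int) -> float:
    """Monomer-unit mass beyond length d: My = U (1 + d(1-p)) p^d, mol/L."""
    p, d = _check_pd(p, d)
    return float(U) * (1.0 + d * (1.0 - p)) * p**d


def tail_norm_sq(p: float, U: float, d: int) -> float:
    """Squared l2 norm of the dropped tail: (1-p)^4 U^2 p^(2d) / (1-p^2)."""
    p, d = _check_pd(p, d)
    if p == 0.0:
        return 0.0
    return (1.0 - p) ** 4 * float(U) ** 2 * p ** (2 * d) / (1.0 - p**2)


def norm_sq(p: float, U: float) -> float:
    """Squared l2 norm of the full distribution: (1-p)^4 U^2 / (1-p^2)."""
    p = float(p)
    if not 0.0 <= p < 1.0:
        raise DomainError(f"p={p!r} outside [0, 1)")
    return (1.0 - p) ** 4 * float(U) ** 2 / (1.0 - p**2)


def _sum_sq(d: int) -> float:
    return d * (d + 1) * (2 * d + 1) / 6.0


def correction_norm_sq(p: float, U: float, d: int) -> float:
    """Squared norm of the minimum mass-restoring correction: My^2 / S."""
    p, d = _check_pd(p, d)
    return tail_mass(p, U, d) ** 2 / _sum_sq(d)


def relative_error_bound(p: float, d: int) -> float:
    """Relative l2 truncation-error lower bound E(p, d); independent of U.

    E = sqrt(||delta_x||^2 + ||y||^2) / ||n||; any length-d state with the
    correct total mass lies at least this far (relatively) from the full
    geometric distribution. Strictly exceeds the lax bound p^d.
    """
    p, d = _check_pd(p, d)
    if p == 0.0:
        return 0.0
    ratio = (
        6.0
        * (1.0 + d * (1.0 - p)) ** 2
        * (1.0 - p**2)
        / (d * (d + 1) * (2 * d + 1) * (1.0 - p) ** 4)
    )
    return p**d * math.sqrt(1.0 + ratio)


def project(n_vec: np.ndarray, d: int, U: float) -> np.ndarray:
    """Project a length distribution onto mass-U vectors supported on 1..d.

    Returns x + delta_x where x is the head of ``n_vec`` and
    delta_x_k = k * My / S with My the missing tail mass and
    S = d(d+1)(2d+1)/6; this is the minimum-norm correction restoring the
    total mass to exactly U.
    """
    n_vec = np.asarray(n_vec, dtype=float)
    K = n_vec.size
    d = int(d)
    if K <= d:
        raise DomainError(f"input must extend beyond d={d} (got length {K})")
    k_full = np.arange(1, K + 1, dtype=float)
    x = n_vec[:d]
    k = k_full[:d]
    My = float(U) - float(k @ x)
    delta_x = k * (My / _sum_sq(d))
    return x + delta_x


def min_d_lax(Pb: float, target_E: float) -> int:
    """Truncation-length threshold from the lax bound p^d: log_Pb(E*).

    Any d below this produces relative error above ``target_E``. Rounded to
    the nearest integer (the conventional report); use :func:`report` for
    the un-rounded real threshold.
    """
    return round(_lax_threshold(Pb, target_E))


def _lax_threshold(Pb: float, target_E: float) -> float:
    Pb, target_E = float(Pb), float(target_E)
    if not 0.0 < Pb < 1.0:
        raise DomainError(f"Pb={Pb!r} must lie in (0, 1)")
    if not 0.0 < target_E < 1.0:
        raise DomainError(f"target_E={target_E!r} must lie in (0, 1)")
    return math.log(target_E) / math.log(Pb)


def min_d_full(Pb: float, target_E: float) -> int:
    """Smallest d with E(Pb, d) < target_E, by doubling plus bisection.

    Always at least the (un-rounded) lax threshold, since E > p^d.
    """
    thresh = _lax_threshold(Pb, target_E)  # validates inputs
    # E > Pb^d, so every d <= thresh has E >= target_E: start the bracket there
    lo = max(1, int(math.floor(thresh)))
    if relative_error_bound(Pb, lo) < target_E:  # only possible for lo = 1
        return lo
    hi = lo + 1
    while relative_error_bound(Pb, hi) >= target_E:
        lo = hi
        hi *= 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if relative_error_bound(Pb, mid) < target_E:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class TruncationErrorReport:
    """All truncation-error statistics for one (p, U, d) triple."""

    p: float
    U: float
    d: int
    tail_mass: float
    tail_norm_sq: float
    correction_norm_sq: float
    E: float
    lax: float


def report(p: float, U: float, d: int) -> TruncationErrorReport:
    """Assemble the full :class:`TruncationErrorReport` for (p, U, d)."""
    p, d = _check_pd(p, d)
    return TruncationErrorReport(
        p=p,
        U=float(U),
        d=d,
        tail_mass=tail_mass(p, U, d),
        tail_norm_sq=tail_norm_sq(p, U, d),
        correction_norm_sq=correction_norm_sq(p, U, d),
        E=relative_error_bound(p, d),
        lax=p**d,
    )
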