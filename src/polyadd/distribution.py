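"""Flory-Schulz (geometric) polymer length distribution and equilibrium statistics.

In a well-mixed linear step-growth system where every bond site is occupied
independently with probability ``p``, the length of a randomly chosen molecule
is geometric: rho(k) = (1-p) p**(k-1) for k >= 1 (k = 1 is the monomer).
Given the conserved total monomer-unit concentration [U], the molar
concentration of k-mers is n(k) = (1-p)**2 p**(k-1) [U], and all the
equilibrium observables used by experimentalists (yield, mass-spectrum mode,
number-average degree of polymerization) are closed-form functions of ``p``.

Concentrations are mol/L, masses g/L, molar masses g/mol by convention; no
unit conversion is performed anywhere in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "FlorySchulzState",
    "length_pmf",
    "concentrations",
    "polymer_yield",
    "mass_distribution",
    "mass_mode",
    "mode_to_p",
    "number_average_dp",
    "default_kmax",
]

#: hard cap on automatically chosen distribution vector lengths
KMAX_CAP = 10**6

#: relative tail mass below which an automatically chosen kmax stops
TAIL_TOL = 1e-12


def _check_p(p: float, *, allow_zero: bool = True) -> float:
    p = float(p)
    lo_ok = p >= 0.0 if allow_zero else p > 0.0
    if not (lo_ok and p < 1.0):
        bound = "[0, 1)" if allow_zero else "(0, 1)"
        raise DomainError(f"bonding probability p={p!r} outside {bound}")
    return p


@dataclass(frozen=True)
class FlorySchulzState:
    """Instantaneous Flory-Schulz state of a polymerizing solution.

    Parameters
    ----------
    p
        Bonding probability, the single distribution parameter; 0 <= p < 1.
        p = 1 is rejected because it implies infinite mean length.
    U
        Total concentration of monomer units (bound or free), mol/L.
    m0
        Monomer molar mass in g/mol; optional, required only for mass
        distributions.
    """

    p: float
    U: float
    m0: float | None = None

    def __post_init__(self) -> None:
        _check_p(self.p)
        if not self.U > 0:
            raise DomainError(f"total monomer-unit concentration U={self.U!r} must be > 0")
        if self.m0 is not None and not self.m0 > 0:
            raise DomainError(f"monomer molar mass m0={self.m0!r} must be > 0")

    @property
    def n_star(self) -> float:
        """Total molecule (reactant) concentration n* = (1-p) U, mol/L."""
        return (1.0 - self.p) * self.U

    @property
    def bond_concentration(self) -> float:
        """Concentration of formed bonds [AB] = p U, mol/L (n* + [AB] = U)."""
        return self.p * self.U

    def default_kmax(self) -> int:
        return default_kmax(self.p, tail_tol=TAIL_TOL)


def default_kmax(p: float, tail_tol: float = TAIL_TOL, cap: int = KMAX_CAP) -> int:
    """Smallest K whose tail mass beyond K is below ``tail_tol`` * U, capped.

    The tail mass fraction beyond K is (1 + K(1-p)) p**K (see the
    error-bound module); we grow K geometrically then bisect.
    """
    p = _check_p(p)
    if p == 0.0:
        return 1

    def tail_frac(k: int) -> float:
        return (1.0 + k * (1.0 - p)) * p**k

    hi = 1
    while tail_frac(hi) >= tail_tol:
        hi *= 2
        if hi >= cap:
            return cap
    lo = hi // 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tail_frac(mid) < tail_tol:
            hi = mid
        else:
            lo = mid
    return hi


def length_pmf(p: float, k) -> float | np.ndarray:
    """Probability that a randomly selected molecule is a k-mer.

    rho(k) = (1-p) p**(k-1); sums to 1 over k = 1, 2, ... with partial-sum
    defect exactly p**K.
    """
    p = _check_p(p)
    karr = np.asarray(k)
    if not np.issubdtype(karr.dtype, np.integer) and not np.all(karr == np.floor(karr)):
        raise DomainError("polymer length k must be integral")
    if np.any(karr < 1):
        raise DomainError("polymer length k must be >= 1")
    out = (1.0 - p) * p ** (karr.astype(float) - 1.0)
    return out if out.ndim else float(out)


def concentrations(state: FlorySchulzState, kmax: int | None = None) -> np.ndarray:
    """Concentration vector n(k) = (1-p)^2 p^(k-1) [U] for k = 1..kmax, mol/L.

    Index 0 of the returned array is the monomer (k = 1). When ``kmax`` is
    omitted it defaults to the smallest length whose tail mass is below
    1e-12 * U (capped at 1e6).
    """
    if kmax is None:
        kmax = state.default_kmax()
    kmax = int(kmax)
    if kmax < 1:
        raise DomainError(f"kmax={kmax} must be >= 1")
    k = np.arange(1, kmax + 1, dtype=float)
    return (1.0 - state.p) ** 2 * state.p ** (k - 1.0) * state.U


def polymer_yield(Pb: float) -> float:
    """Equilibrium mass fraction converted to polymers: eta = 1 - (1-Pb)^2.

    Algebraically identical to Pb (2 - Pb). The concentration-based analogue
    (fraction of molecules that are polymers... of converted monomers) is
    simply Pb itself.
    """
    Pb = float(Pb)
    if not 0.0 <= Pb <= 1.0:
        raise DomainError(f"bonding probability Pb={Pb!r} outside [0, 1]")
    return 1.0 - (1.0 - Pb) ** 2


def mass_distribution(state: FlorySchulzState, kmax: int | None = None) -> np.ndarray:
    """Mass-per-length vector m(k) = k m0 n(k), g/L; sums to m0 U as kmax grows."""
    if state.m0 is None:
        raise ConfigurationError("mass_distribution requires a monomer molar mass m0")
    n = concentrations(state, kmax)
    k = np.arange(1, n.size + 1, dtype=float)
    return k * state.m0 * n


def mass_mode(p: float) -> float:
    """Continuous mode k* = -1/ln(p) of the mass distribution m(k).

    Undefined at p = 0 (monomer-dominated spectrum has no interior peak);
    callers must handle that case explicitly.
    """
    p = _check_p(p, allow_zero=False)
    return -1.0 / math.log(p)


def mode_to_p(kstar: float) -> float:
    """Bonding probability implied by a mass-spectrum modal length: p = e^(-1/k*)."""
    kstar = float(kstar)
    if not kstar > 0:
        raise DomainError(f"modal length kstar={kstar!r} must be > 0")
    return math.exp(-1.0 / kstar)


def number_average_dp(p: float) -> float:
    """Number-average degree of polymerization X̄n = 1/(1-p) (Carothers relation)."""
    p = _check_p(p)
    return 1.0 / (1.0 - p)


def write_distribution_csv(
    state: FlorySchulzState,
    path: str | Path,
    kmax: int | None = None,
    kind: str = "concentration",
) -> None:
    """Serialize a distribution vector to CSV plus a JSON parameter sidecar.

    ``kind`` selects ``concentration`` (mol/L) or ``mass`` (g/L) columns.
    The sidecar <path>.json records {p, U, m0, kmax} so the CSV is
    regenerable from its metadata alone.
    """
    if kind == "concentration":
        vec = concentrations(state, kmax)
    elif kind == "mass":
        vec = mass_distribution(state, kmax)
    else:
        raise ConfigurationError(f"unknown distribution kind {kind!r}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"k,{kind}\n")
        for i, v in enumerate(vec, start=1):
            fh.write(f"{i},{v:.17g}\n")
    sidecar = {"p": state.p, "U": state.U, "m0": state.m0, "kmax": int(vec.size)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1) + "\n")
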