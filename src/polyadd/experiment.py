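"""Interpretation of experimental observables through the polyaddition model,
plus synthetic fixtures with known ground truth.

An HPLC-style oligomer "mass spectrum" — signal proportional to the total
mass of material at each length — peaks at k* = -1/ln(p) when the underlying
length distribution is Flory-Schulz. Matching the observed peak position
(or fitting the full geometric decay) therefore yields the bonding
probability p, from which yield, free energy of bond formation, mean degree
of polymerization, and (with a second temperature) the enthalpy/entropy
split and critical temperature all follow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import distribution as dist
from .errors import DomainError
from .thermodynamics import (
    Regime,
    classify_regime,
    decompose_enthalpy_entropy,
    energy_from_prob,
)

__all__ = [
    "MassSpectrum",
    "SpectrumFit",
    "fit_p_from_spectrum",
    "interpret",
    "two_temperature_analysis",
    "generate_population",
    "generate_spectrum",
]


@dataclass(frozen=True)
class MassSpectrum:
    """A length-binned oligomer mass spectrum.

    ``signal`` is in arbitrary units proportional to mass per length;
    ``T`` is the measurement temperature in kelvin (optional, used when
    converting a fitted p into a bond free energy).
    """

    lengths: np.ndarray
    signal: np.ndarray
    T: float | None = None

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=int)
        signal = np.asarray(self.signal, dtype=float)
        if lengths.size < 2:
            raise DomainError("a spectrum needs at least 2 length bins")
        if lengths.shape != signal.shape:
            raise DomainError("lengths and signal must have equal shapes")
        if np.any(np.diff(lengths) <= 0):
            raise DomainError("lengths must be strictly increasing")
        if np.any(lengths < 1):
            raise DomainError("lengths must be >= 1")
        if np.any(signal < 0):
            raise DomainError("signal must be nonnegative")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "signal", signal)

    @classmethod
    def from_csv(cls, path: str | Path, T: float | None = None) -> "MassSpectrum":
        """Read a two-column `k,signal` CSV; metadata JSON sidecar optional."""
        import pandas as pd

        df = pd.read_csv(path)
        if T is None:
            sidecar = Path(str(path) + ".json")
            if sidecar.exists():
                T = json.loads(sidecar.read_text()).get("temperature_K")
        return cls(lengths=df["k"].to_numpy(), signal=df["signal"].to_numpy(), T=T)

    def to_csv(self, path: str | Path, m0: float | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("k,signal\n")
            for k, s in zip(self.lengths, self.signal):
                fh.write(f"{k},{s:.17g}\n")
        meta = {"temperature_K": self.T, "m0": m0}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1) + "\n")


@dataclass(frozen=True)
class SpectrumFit:
    """Result of fitting a bonding probability to a mass spectrum."""

    p: float
    method: str
    kstar: float | None = None  # argmax peak position (argmax method)
    residual: float | None = None  # weighted RMS log-residual (wls method)
    n_used: int | None = None  # points entering the regression


def fit_p_from_spectrum(spec: MassSpectrum, method: str = "argmax") -> SpectrumFit:
    """Estimate the bonding probability p from a mass spectrum.

    method="argmax"
        Take the peak position k^* (smallest length on ties) and invert the
        mode relation: p = e^(-1/k^*). Robust but quantizes p to the set
        {e^(-1/k)}.
    method="wls"
        The model mass m(k) = k m0 (1-p)^2 p^(k-1) U implies
        log(signal/k) = const + (k-1) log p: a weighted linear regression
        of log(signal/k) on k with weights equal to the signal itself.
        Nonpositive signal bins are excluded.
    """
    signal = spec.signal
    if np.all(signal == signal[0]):
        raise DomainError("flat spectrum: no mode and no decay to fit")
    if method == "argmax":
        kstar = int(spec.lengths[int(np.argmax(signal))])
        return SpectrumFit(p=dist.mode_to_p(kstar), method="argmax", kstar=float(kstar))
    if method == "wls":
        pos = signal > 0
        k = spec.lengths[pos].astype(float)
        if k.size < 2:
            raise DomainError("need at least 2 positive-signal bins for wls")
        y = np.log(signal[pos] / k)
        w = signal[pos]
        # weighted least squares on y = a + b (k-1)
        X = np.column_stack([np.ones_like(k), k - 1.0])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        b = coef[1]
        if b >= 0:
            raise DomainError("spectrum does not decay geometrically (fitted p >= 1)")
        resid = y - X @ coef
        rms = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
        return SpectrumFit(p=float(np.exp(b)), method="wls", residual=rms, n_used=int(k.size))
    raise DomainError(f"unknown fit method {method!r}")


@dataclass(frozen=True)
class Interpretation:
    """Equilibrium observables implied by a bonding probability."""

    p: float
    T: float
    dG: float  # bond free energy, kcal/mol
    eta: float  # polymer yield (mass fraction)
    Xn: float  # number-average degree of polymerization
    kstar: float  # continuous mode of the mass distribution


def interpret(p: float, T: float, U: float | None = None) -> Interpretation:
    """Convert an equilibrium bonding probability into report quantities.

    At equilibrium p -> Pb, so the Boltzmann relation gives the bond free
    energy directly; yield, mean length and mass-spectrum mode follow from
    the distribution module. ``U`` is accepted for symmetry but the four
    reported quantities are all intensive in this model.
    """
    del U  # intensive quantities only
    return Interpretation(
        p=float(p),
        T=float(T),
        dG=energy_from_prob(p, T),
        eta=dist.polymer_yield(p),
        Xn=dist.number_average_dp(p),
        kstar=dist.mass_mode(p),
    )


@dataclass(frozen=True)
class TwoTemperatureResult:
    dG1: float
    dH: float
    dS: float
    regime: Regime
    Tc: float | None  # kelvin; None when favorability never switches


def two_temperature_analysis(
    p1: float, T1: float, dG2: float, T2: float
) -> TwoTemperatureResult:
    """Enthalpy/entropy split from one fitted probability and one reference
    free energy at a second temperature.

    dG1 is recovered from p1 at T1 at full precision, then the two-point
    linear system dG = dH - T dS is solved and the temperature regime (and
    critical temperature, when defined) classified.
    """
    dG1 = energy_from_prob(p1, T1)
    dH, dS = decompose_enthalpy_entropy(dG1, T1, dG2, T2)
    regime, Tc = classify_regime(dH, dS)
    return TwoTemperatureResult(dG1=dG1, dH=dH, dS=dS, regime=regime, Tc=Tc)


def generate_population(p: float, n_molecules: int, seed: int) -> np.ndarray:
    """Sample molecule lengths from a Flory-Schulz population.

    Chain length is the number of Bernoulli(p) bond successes up to the
    first failure, i.e. geometric with success probability 1-p on support
    {1, 2, ...}. Reproducible for a fixed seed.
    """
    p = float(p)
    if not 0.0 <= p < 1.0:
        raise DomainError(f"p={p!r} outside [0, 1)")
    if n_molecules < 1:
        raise DomainError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.geometric(1.0 - p, size=int(n_molecules))


def generate_spectrum(
    p: float,
    m0: float,
    kmax: int,
    noise_cv: float = 0.0,
    seed: int = 0,
    U: float = 1.0,
    T: float | None = None,
) -> MassSpectrum:
    """Synthesize a noisy HPLC-style mass spectrum from known ground truth.

    signal_k = m(k) (1 + eps_k) with eps_k i.i.d. Gaussian of standard
    deviation ``noise_cv`` (multiplicative noise: chromatographic peak-area
    uncertainty scales with the signal), clipped at -0.99 so signals stay
    positive.
    """
    if not 0.0 < p < 1.0:
        raise DomainError(f"p={p!r} must lie in (0, 1) for a spectrum")
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    state = dist.FlorySchulzState(p=p, U=U, m0=m0)
    m = dist.mass_distribution(state, kmax)
    rng = np.random.default_rng(seed)
    eps = np.clip(rng.normal(0.0, noise_cv, size=m.size) if noise_cv > 0 else 0.0, -0.99, None)
    return MassSpectrum(
        lengths=np.arange(1, m.size + 1), signal=m * (1.0 + eps), T=T
    )
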