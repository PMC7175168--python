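# polyadd

Equilibrium and kinetics of reversible linear step-growth polymerization
("polyaddition"), with an emphasis on the regime relevant to nonenzymatic
RNA-like oligomerization: a solution of bifunctional monomers that join
end-to-end and hydrolyze back, producing a geometric (Flory–Schulz)
distribution of chain lengths governed by a single bonding probability.

The package is aimed at researchers who simulate or measure oligomer length
distributions — e.g. in origins-of-life chemistry — and need to move
quantitatively between rate constants, bond thermodynamics, time courses,
finite-length simulations, and experimental observables such as mass spectra
and polymer yield.

## The model

Monomers at total unit concentration `U` (mol/L of monomer units) carry one
A-end and one B-end. Any A-end can condense with any B-end at rate constant
`k+` (L mol⁻¹ s⁻¹); every bond hydrolyzes at rate `k−` (s⁻¹). Because all
bonds are equivalent, the equilibrium state is fully described by the
probability `p` that a given bond site is occupied, and the k-mer
concentrations are geometric:

```
n(k) = (1 − p)² p^(k−1) U          (Flory–Schulz distribution)
```

The package provides, in closed form wherever one exists:

- **distribution** — `n(k)`, molecule count `n* = (1−p)U`, bond
  concentration `pU`, number-average length `X̄n = 1/(1−p)`, mass-spectrum
  mode `k* = −1/ln p`, polymer yield `η = 1 − (1−p)²`.
- **thermodynamics** — `p = σ(−ΔG/RT)` (logistic), the hydrolysis/ligation
  ratio `κ = k−/k+` from `ΔG`, enthalpy/entropy decomposition from two
  temperatures, and the regime classification with critical temperature
  `Tc = ΔH/ΔS`.
- **kinetics** — steady state `Pb = 1 + κ̄ − √(κ̄(2+κ̄))` with
  `κ̄ = κ/(2U)`, and the exact Riccati solution `p(t)` (tanh/coth branches,
  irreversible limit) from any initial `p₀`.
- **simulator** — the truncated d-dimensional mass-action ODE system with a
  mass-conserving right-hand side, analytic Jacobian, stiff integration
  (LSODA), steady-state driver, and an independent detailed-balance
  closed-form steady state for validation.
- **error bound** — a rigorous closed-form lower bound `E(p, d) > p^d` on
  the relative ℓ² error that *any* mass-conserving length-d truncation must
  incur, plus the minimum `d` needed to reach a target accuracy.
- **experiment** — fitting `p` from an oligomer mass spectrum (peak
  position, or weighted log-linear regression), converting to
  `ΔG`, yield, and mean length, and synthetic spectrum generation.

## Worked example

A mass spectrum of an ice-eutectic polymerization experiment peaks at the
dimer. What does that say about the chemistry?

```python
import math
import polyadd as pa

p = pa.mode_to_p(2.0)                      # peak at k* = 2  ->  p = e^(-1/2)
rep = pa.interpret(p, T=255.15)            # measured at -18 C
print(f"p = {p:.4f}, yield = {rep.eta*100:.1f}%, dG = {rep.dG:.3f} kcal/mol")

res = pa.two_temperature_analysis(p, 255.15, dG2=3.3, T2=298.15)
print(f"dH = {res.dH:.1f} kcal/mol, dS = {res.dS:.4f} kcal/(mol K), "
      f"Tc = {res.Tc - 273.15:.1f} C")
```

prints

```
p = 0.6065, yield = 84.5%, dG = -0.219 kcal/mol
dH = -21.1 kcal/mol, dS = -0.0818 kcal/(mol K), Tc = -15.3 C
```

So a dimer-peaked spectrum implies ~61% bonding, ~85% of the mass in
polymers, and a phosphodiester bond that is mildly *favorable*
(−0.2 kcal/mol) at −18 °C even though it is unfavorable (+3.3 kcal/mol) at
25 °C — the enthalpy/entropy split places the crossover at about −15 °C.

On the kinetic side, under reference conditions (`U = 1 M`,
`k+ = 7.4e-5`, `k− = 1e-6`):

```python
rates = pa.RateConstants(kplus=7.4e-5, kminus=1e-6)
sol = pa.solve_p(p0=0.0, rates=rates, U=1.0)
print(f"Pb = {sol.Pb:.4f}, relaxation time ~ {1/sol.rate_scale:.2e} s")
```

```
Pb = 0.8903, relaxation time ~ 1.16e+05 s
```

i.e. 89% bonding at equilibrium, reached on a ~day timescale.

More narrative walkthroughs live in `examples/` (one script per
capability); each prints its numbers with a line on what they mean:

```
python examples/equilibrium_distribution.py
python examples/closed_form_dynamics.py
python examples/truncated_simulation.py
python examples/truncation_bound.py
python examples/spectrum_interpretation.py
```

## Command-line interface

A thin CLI wraps the library for one-off calculations and reproducible
artifact generation:

```
polyadd steady-state            # Pb, yield, X̄n from rates/thermo params
polyadd dynamics                # closed-form p(t) trajectory -> CSV
polyadd simulate                # truncated ODE integration -> CSV
polyadd bound                   # truncation-error bound / minimum d
polyadd thermo                  # regime classification, Tc
polyadd analyze                 # fit p from a spectrum CSV
polyadd fixtures                # generate synthetic spectra
```

All commands accept `--config config.yaml`, write JSON/CSV artifacts with
the resolved parameters and seed embedded, and use exit codes 2 (usage),
3 (domain), 4 (numerical failure).

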