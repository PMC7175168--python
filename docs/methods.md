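# Methods

## Model and assumptions

The system is an ideally mixed solution of bifunctional monomers (one A-end,
one B-end per unit) undergoing reversible linear step-growth polymerization:

- **Equal reactivity.** Every A/B end pair condenses with the same rate
  constant `k+` regardless of chain length, and every bond hydrolyzes with
  the same rate `k−`. No cyclization, no branching, no side reactions.
- **Mass action.** Chain–chain ligation of a j-mer and a k-mer proceeds at
  rate `k+ x_j x_k` per ordered end pair; a k-mer hydrolyzes at rate
  `(k−1) k− x_k` (one event per bond).
- **Well-mixed, isothermal, closed.** Total monomer-unit concentration
  `U = Σ k·x_k` is conserved exactly.

Under equal reactivity the equilibrium/steady-state length distribution is
Flory–Schulz: bond sites are occupied independently with probability `p`, so
`n(k) = (1−p)² p^(k−1) U`. The full infinite-dimensional kinetics then
collapse onto a single ODE for `p`:

```
dp/dt = U k+ (1−p)² − k− p          (Riccati)
```

whose stationary point is `Pb = 1 + κ̄ − √(κ̄(2+κ̄))` with
`κ = k−/k+`, `κ̄ = κ/(2U)`, and whose solution is a shifted hyperbolic
tangent (or cotangent, depending on which side of `Pb` the initial
condition sits). The solver selects among four branches: `tanh`
(`p₀ > Pb` side of the arctanh domain), `coth` (analytic continuation when
the arctanh argument exceeds 1, i.e. `p₀ < Pb` — the usual all-monomer
start), `constant` (`|p₀ − Pb|` below 1e−12), and `irreversible` (`k− = 0`,
where `p(t) = 1 − 1/(1/(1−p₀) + k+ U t)`).

Thermodynamics enters through the per-bond free energy:
`p = σ(−ΔG/RT)` with the logistic `σ`, and `κ = U e^g σ(g)` with
`g = ΔG/RT`, so that kinetic and thermodynamic parameterizations are two
coordinates for the same steady state. Two measurements
`(ΔG₁,T₁), (ΔG₂,T₂)` determine `ΔH` and `ΔS` by the linear relation
`ΔG = ΔH − TΔS`; the sign pattern of `(ΔH, ΔS)` classifies the bond into
four regimes (always/never favorable, favorable below/above
`Tc = ΔH/ΔS`).

## Parameters, units, defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| `U` | total monomer-unit concentration | mol/L | 1.0 |
| `k+` (`kplus`) | ligation rate constant | L mol⁻¹ s⁻¹ | derived from `ΔG` |
| `k−` (`kminus`) | hydrolysis rate constant | s⁻¹ | 1e−6 |
| `ΔG` (`dg`) | bond free energy | kcal/mol | −1.5 |
| `T` (`temp_c`) | temperature | °C | 85 |
| `d` | truncation length (max chain) | — | 100 |
| `p0` | initial bonding probability | — | 0 (all monomer) |
| `R` | gas constant | kcal mol⁻¹ K⁻¹ | 1.987204e−3 |

The defaults are a reference condition motivated by nonenzymatic RNA
chemistry at elevated temperature: at `U = 1 M`, `ΔG = −1.5 kcal/mol`,
`T = 85 °C` the bonding probability is 0.89 and, with `k− = 1e−6 s⁻¹`
(bond half-life ~8 days), the implied ligation constant is
`k+ ≈ 7.4e−5 L mol⁻¹ s⁻¹` and equilibration takes ~1e5–1e6 s. `k+` and
`ΔG` are redundant at fixed `k−` and `U`; supplying both explicitly is a
configuration error.

## Truncated simulation

The simulator integrates the d-dimensional projection

```
dx_k/dt =  Σ_{l=1}^{d−k} (2k− x_{k+l} − 2k+ x_k x_l)
         + Σ_{l=1}^{k−1} k+ x_l x_{k−l}  −  (k−1) k− x_k
```

which conserves `Σ k·x_k` *exactly* (the cross terms cancel in pairs). The
obvious alternative — simply deleting reactions that would form chains
longer than d — leaks mass; `naive_deletion_rhs` is kept as a documented
counterexample (its steady state retains only ~2.5% of the initial mass at
d = 10 under reference conditions).

Numerics: the quadratic terms are evaluated in O(d log d) with prefix/suffix
sums and `np.convolve`; the Jacobian is analytic and dense; integration uses
LSODA (`scipy.integrate.solve_ivp`) with `rtol = 1e−8`,
`atol = 1e−12·U`, output on a geometric time grid including `t = 0`.
Integration raises a numerical error if the solver fails or relative mass
drift exceeds 1e−6. The steady-state driver integrates in chunks, doubling
the horizon until `‖f(x)‖ ≤ tol·k+·U·‖x‖`, with a cap of
`100/(Δ k+ U)` (100 relaxation times). `d` is capped at 2000 (dense
Jacobian memory). Truncated initial conditions are renormalized
proportionally in mass so `Σ k·x_k = U` holds exactly at `t = 0`.

Validation oracles (in the test suite, not the library): brute-force
enumeration of every ordered reaction pair for d ≤ 8; the exact quadratic
equilibrium at d = 2; and the detailed-balance closed form
`x_k = a(a/κ)^(k−1)` with `a` found by Brent root-finding on the mass
constraint, which the integrated steady state matches to relative 1e−6 or
better for d ∈ {10, 25, 50}.

## Truncation-error lower bound

For any mass-conserving simulation truncated at length d, the steady state
must differ from the true (infinite) Flory–Schulz distribution by at least

```
E(p, d) = p^d √(1 + 6(1 + d(1−p))²(1−p²) / (d(d+1)(2d+1)(1−p)⁴))
```

in relative ℓ² norm. The construction: the true tail (k > d) has mass
`M_y = U(1 + d(1−p))p^d` and squared norm `(1−p)⁴U²p^(2d)/(1−p²)`; the
*closest* mass-conserving truncated state adds the mass back as a
correction proportional to `k` (the constrained-least-squares minimizer),
with squared norm `M_y²/S`, `S = d(d+1)(2d+1)/6`. `E` is reported as a
ratio of norms (not squared norms) so it reads directly as a relative
error; it strictly dominates the "lax" bound `p^d` (the neglected tail
alone). The minimum usable d for a target error `E*` is `round(log_p E*)`
for the lax bound (nearest-integer convention) and is found by doubling
plus bisection on the monotone full bound. Worked strong-bond case:
`ΔG = −3.5 kcal/mol` at 85 °C gives `Pb = 0.99274`; the lax bound rules out
d < 632 and the full bound d < 700 at 1% error.

## Experimental observables and synthetic data

A mass spectrum is modeled as signal ∝ mass distribution
`m(k) = k·n(k)·m₀`, whose mode is `k* = −1/ln p` — hence the inversion
`p = e^(−1/k*)`. Two fitters are provided: `argmax` (peak position,
smallest length on ties; robust, coarse) and `wls` (weighted least squares
of `log(signal/k)` on `k−1` with the signal itself as weight, recovering
`log p` as the slope; exact on noiseless data, median error < 0.02 at 5%
multiplicative noise over 100 seeds).

The synthetic generators emulate, not reproduce, real data:
`generate_spectrum` applies i.i.d. multiplicative Gaussian noise
(coefficient of variation `noise_cv`, clipped at −99%) to the exact mass
distribution — a stand-in for HPLC/MS peak-intensity scatter, with no
baseline, ionization-efficiency, or resolution effects;
`generate_population` draws geometric chain lengths — ideal sampling with
no length-dependent detection bias. They are for testing and demonstration
only.

## Numerical and design choices

- **Stable steady state.** `Pb = 1 + κ̄ − √(κ̄(2+κ̄))` cancels
  catastrophically for large `κ̄`; the implementation uses the rationalized
  equivalent `Pb = 1/(1 + κ̄ + √(κ̄(2+κ̄)))`.
- **Logistic via `scipy.special.expit` / `log_expit`** rather than a
  hand-rolled piecewise exponential; saturation to exactly 0/1 in float64
  occurs for `|ΔG/RT| ≳ 36` and is treated as a domain limit, not hidden.
- **Hyperbolic argument clamp at 350** in the closed-form `p(t)`: beyond
  that `tanh`/`coth` are 1 to machine precision, so `Pb` is returned
  exactly, avoiding overflow at astronomically large `t`.
- **Branch tolerance 1e−12** on `|p₀ − Pb|` for the constant branch.
- **Mean-length rate.** The number-average length obeys
  `dX̄n/dt = k+U − k− X̄n(X̄n − 1)`, the exact chain-rule consequence of the
  Riccati equation via `X̄n = 1/(1−p)`; a factor-2 variant sometimes quoted
  for the hydrolysis term is inconsistent with that derivation and is not
  used.
- **Reproducibility.** All CSV/JSON artifacts serialize floats at 17
  significant digits and embed the resolved parameters and seed; reruns are
  byte-identical.

## Limitations

- No cyclization, branching, sequence effects, or length-dependent
  reactivity; `p` fully determines the state only under equal reactivity.
- The closed-form dynamics assume the length distribution stays geometric
  along the trajectory (exact from an all-monomer or geometric start).
- Thermodynamics uses a temperature-independent `(ΔH, ΔS)` pair (no heat
  capacity term), so the two-point decomposition degrades over wide
  temperature spans.
- The error bound is a lower bound on the best possible truncated
  steady state; actual simulation error can be larger, never smaller.
- Dense-Jacobian integration limits the truncation to `d ≤ 2000`.
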