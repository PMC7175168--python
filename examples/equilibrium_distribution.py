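"""Equilibrium length statistics of a step-growth polymer solution.

Builds the Flory-Schulz state for a bonding probability of 0.89 at 1 M total
monomer units and prints the quantities an experimentalist would report.
"""

import numpy as np

import polyadd as pa

state = pa.FlorySchulzState(p=0.89, U=1.0, m0=320.0)

n = pa.concentrations(state, kmax=10)
print("k-mer concentrations n(k), mol/L, k = 1..10:")
for k, c in enumerate(n, start=1):
    print(f"  k={k:2d}  {c:.5f}")

print(f"\ntotal molecule concentration n* = {state.n_star:.4f} mol/L")
print(f"bond concentration [AB]         = {state.bond_concentration:.4f} mol/L")
print(f"polymer yield (mass fraction)   = {pa.polymer_yield(state.p):.4f}")
print(f"number-average length X̄n       = {pa.number_average_dp(state.p):.2f}")
print(f"mass-spectrum mode k*           = {pa.mass_mode(state.p):.2f}")

# Each bond site is occupied independently with probability p, so lengths are
# geometric: concentrations fall by the factor p per extra monomer, the mean
# length is 1/(1-p), and the mass spectrum peaks near -1/ln(p).
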