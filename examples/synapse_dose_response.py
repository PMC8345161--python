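"""Checkpoint engagement vs antibody concentration in the immune synapse.

Solves the PD-1:PD-L1:antibody equilibrium cubic over a nivolumab grid and
prints the bound fraction x, the bond count, and the Hill modifier H that
gates killing and exhaustion.  H near 1 means a fully engaged checkpoint
(T cells suppressed); H near 0 means the antibody has displaced the bonds.
"""
import numpy as np

from spatialqsp import SynapseParams, default_registry, solve_synapse

params = SynapseParams.from_registry(default_registry())
c_ifng = 1.0  # ng/mL local interferon-gamma; induces PD-L1 on the target

print(f"{'nivo (M)':>10} {'x':>8} {'bonds':>8} {'H':>7}")
for nivo in [0.0, 1e-11, 1e-10, 1e-9, 1e-8, 1e-7]:
    res = solve_synapse(params, c_ifng, nivo)
    print(f"{nivo:10.0e} {res.x:8.4f} {res.bonds:8.1f} {res.H:7.4f}")

print()
print("x is the fraction of synaptic PD-L1 bound to PD-1; H is the")
print("inhibition applied to killing -- the untreated synapse suppresses")
print("most killing, therapeutic exposure (~1e-7 M) releases it.")
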