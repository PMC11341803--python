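# molcond

Linear-response conductance of molecules from a Liouville quantum master
equation — for computational biophysicists and molecular-electronics
researchers who want to locate and quantify the conducting pathways of
large molecules (protein nanowires in particular) from semi-empirical
electronic structure.

Protein junctions conduct surprisingly well: nanosiemens over nanometers,
nearly temperature-independent below ~100 K, and with little distance
decay.  Pure coherent-tunneling theory (Landauer–Büttiker) and pure hopping
theory (Marcus) each capture only a limit.  This package implements a
phenomenological master-equation treatment that interpolates between them:
a single electron in the molecular-orbital basis exchanges energy with an
Ohmic phonon bath whose rates obey detailed balance, so that with no
contacts attached the density matrix relaxes to the Fermi–Dirac
distribution, and two contact orbitals L, R with escape strengths Γ_L, Γ_R
drive a steady-state current at small bias.

## The model

In the eigenbasis {E_i, Ψ^i} of the (Löwdin-orthogonalized) single-electron
Hamiltonian, the density matrix evolves as

    dρ^ij/dt = -(i/ħ)(E_i-E_j)ρ^ij - (1/2ħ)Σ_r(Γ^ir ρ^rj + ρ^ir Γ^rj)
               + R^ij(ρ) + J^ij,

where R enforces Pauli-blocked bath transitions with rates
γ^ij = γ(ω_ij)·Σ_n|Ψ_n^i|²|Ψ_n^j|² and the Ohmic spectral density
γ(ω) = ηħω e^{-|ω|/ω_c}/(e^{ħω/kT}-1).  Linearizing around equilibrium
under a bias U gives the conductance as a contraction of the inverse of the
linearized evolution superoperator L^{ijpq} with the contact orbitals —
evaluated here by two linear solves, never a dense inverse.

When bath relaxation outpaces escape into the contacts, the conductance
splits into three mechanisms,

    G = G_LB + G_T + G_M,
    G_LB = (2e²/h)·T                     coherent tunneling (Breit–Wigner T)
    G_T  = (2e²/ħ)·Z_L Z_R/(Z_L+Z_R)     thermal excitation
    G_M  = (e²/h)·[w_L T_R + w_R T_L]    tunnel-then-thermalize,

with thermal weights Z_{L/R} = Σ_k Γ_{L/R}|Ψ^k_{L/R}|²/4kT·cosh²((μ-E_k)/2kT)
and exit probabilities w_{L/R} = Z_{L/R}/(Z_L+Z_R).  This decomposition is
the workhorse for large systems (per-pair cost linear in the level window).
Spatially continuous analogues 𝒵(r) and 𝒯(r), built from the LCAO
molecular orbitals on a 3-D grid, visualize the thermally and
tunneling-accessible regions; their high-value overlap marks the conductive
core of a molecule.

A time-domain integrator of the full nonlinear master equation provides the
ground truth: the U → 0 steady-state current must (and does, to better than
0.01%) reproduce the superoperator formula.

## Worked example

```python
import numpy as np
from molcond import (BathSpec, ContactPair, ElectronicStructure,
                     ModelSpec, full_conductance, make_model,
                     three_term_conductance)

# 3-site donor-bridge-acceptor wire, 1 eV barrier, 0.3 eV hopping,
# contacts on the end sites with Γ = 1 meV, protein Ohmic bath at 300 K
raw = make_model(ModelSpec(kind="dba_wire", n_sites=3, barrier=1.0, hopping=0.3))
es = ElectronicStructure.from_raw(raw, n_electrons=4)
bath = BathSpec(temperature_K=300.0)
contacts = ContactPair(site_L=0, site_R=2, Gamma_L=1e-3, Gamma_R=1e-3)
full = full_conductance(es, contacts, bath, window=np.arange(3))
print(f"G (full superoperator) = {full.G_nS:.4f} nS")

# fast-relaxation regime: a 0.2 eV two-level system with weak contacts,
# where the three-mechanism decomposition reproduces the full result
raw2 = make_model(ModelSpec(kind="two_level", gap=0.2))
es2 = ElectronicStructure.from_raw(raw2, n_electrons=2)
bath2 = BathSpec(temperature_K=300.0, cutoff_ev=0.5)
c2 = ContactPair(0, 1, Gamma_L=1e-6, Gamma_R=1e-6)
f2 = full_conductance(es2, c2, bath2, window=np.arange(2))
a2 = three_term_conductance(es2, c2, kt=bath2.kt, window=np.arange(2))
print(f"two-level: full = {f2.G_nS:.5f} nS, G_LB+G_T+G_M = {a2.G_nS:.5f} nS")
print(f"  G_LB = {a2.G_LB_nS:.3e} nS, G_T = {a2.G_T_nS:.3e} nS, "
      f"G_M = {a2.G_M_nS:.3e} nS")
```

prints

    G (full superoperator) = 0.0390 nS
    two-level: full = 0.18878 nS, G_LB+G_T+G_M = 0.18879 nS
      G_LB = 3.874e-06 nS, G_T = 1.888e-01 nS, G_M = 1.937e-06 nS

Both totals sit in the experimentally familiar sub-nanosiemens range.  In
the weak-contact two-level system, bath relaxation is much faster than
escape, the decomposition matches the full superoperator result to four
digits, and the thermal mechanism G_T dominates at room temperature while
coherent tunneling across the 0.2 eV gap is five orders of magnitude
weaker — the generic situation for off-resonant molecular wires.

A command-line interface mirrors the library (`conduct full`,
`conduct approx`, `conduct pairs`, `conduct map`, `conduct make-model`,
`conduct simulate`, `conduct sweep-distance`, `conduct sweep-temperature`);
run `conduct --help`.

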