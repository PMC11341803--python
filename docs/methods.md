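# Methods

## Model

A single electron in a molecule is described in the atomic-orbital basis by
a real symmetric Hamiltonian H (eV) and overlap matrix S, as produced by
semi-empirical LCAO codes (extended-Hückel level).  A Löwdin
orthogonalization H̃ = S^{-1/2} H S^{-1/2} gives an orthonormal orbital
basis while preserving the generalized spectrum of (H, S); "contact
orbital" below always means a Löwdin orbital.  Diagonalizing H̃ yields
molecular levels {E_i} and real eigenvectors {Ψ_n^i}.

The reduced density matrix ρ^{ij} in the level basis obeys a Liouville-type
master equation containing (i) coherent evolution, (ii) anti-commutator
escape into two contacts, Γ^{ij} = Γ_L Ψ_L^iΨ_L^j + Γ_R Ψ_R^iΨ_R^j, (iii) a
nonlinear Pauli-blocking relaxation term R(ρ) with level-to-level rates
γ^{ij} = γ(ω_ij)·Σ_n|Ψ_n^i|²|Ψ_n^j|², and (iv) an injected current J.  The
bath spectral density is Ohmic with exponential cutoff and satisfies the
detailed-balance identity γ(ω)/γ(-ω) = e^{-ħω/kT} exactly, which is what
makes the Fermi-Dirac state the unique equilibrium of R: we verified
algebraically (and the test suite verifies numerically) that the gain and
loss terms cancel identically at ρ^{ij} = δ_ij F(E_i, μ).

Key assumptions: single-electron picture (closed shell, doubly occupied
levels; no cotunneling or correlated many-body effects); weak
electron–phonon coupling (a warning fires when the largest γ^{ij} exceeds
the smallest level spacing); linear response in the bias U.

### Linearized operator and the conductance

Linearizing the master equation around equilibrium gives the superoperator

    L^{ijpq} = -i(E_i-E_j)δ_ipδ_jq - ½(Γ^{ip}δ_jq + δ_ipΓ^{qj})
               + ½(γ̃^{ip}+γ̃^{jp})δ_ijδ_pq - ½Σ_r(γ̃^{ri}+γ̃^{rj})δ_ipδ_jq,

with γ̃^{ij} = γ^{ij}(1-F_i)/(1-F_j).  We verified by direct
differentiation that this is exactly the Jacobian of the nonlinear
relaxation term at equilibrium — the detailed-balance identities
Σ_r γ̃^{ri} = Σ_p[γ^{ip}F_p + γ^{pi}(1-F_p)] and
(1-F_i)γ^{ip} + F_iγ^{pi} = γ^{ip}(1-F_i)/(1-F_p) make the two coincide — so
the linear and nonlinear code paths validate each other rather than sharing
algebra.

The conductance is a contraction of L^{-1} between the contact dyads
Ψ_X^iΨ_X^j, weighted by the occupancy response D^i(μ): the Fermi derivative
f(E,μ) = 1/(4kT cosh²((E-μ)/2kT)) convolved with each level's
lifetime-broadened Lorentzian of width Γ^i.  Two conventions are possible
for where D attaches to the pair indices; only the symmetrized weight
½(D^p + D^q) yields a real conductance, and it equals the real part of the
one-sided convention identically.  We evaluate the symmetrized form; the
one-sided form's imaginary remainder is spurious (it is odd under the
conjugation symmetry of L) and can reach ~10⁻³ relative on small
asymmetric systems.

The contraction is computed via two linear solves of L (LU), never a dense
inverse; pair indices (i, j) are flattened row-major, k = i·N_w + j.  A
window of levels around the HOMO/LUMO (default ±20 levels; the
visualization maps use ±5 kT) truncates all sums; the superoperator is
dense complex (N_w², N_w²), capped at N_w = 80 by default.

### Three-mechanism decomposition

In the regime where bath relaxation is fast compared to contact escape, the
conductance separates into coherent tunneling (G_LB, Breit–Wigner),
thermal-excitation transport (G_T) and a mixed tunnel-then-thermalize term
(G_M).  The standard form of G_T carries 2e²/ħ where the other two carry h —
a factor 2π asymmetry that we keep as defined; a clearly marked
`harmonize_hbar` flag (default off) switches G_T to an h-based prefactor
for sensitivity analysis only, and the choice is echoed in result metadata.

Thermal weights underflow below ~50 K for eV-scale gaps, so Z_L, Z_R and
all derived ratios are computed in log space (log-sum-exp); results carry
log10 conductances alongside linear values, keeping the G_M
low-temperature plateau and the Arrhenius slope of G_T measurable at 10 K.

## Time-domain oracle

`dynamics` integrates the full nonlinear master equation and provides the
package's ground truth:

* closed-system relaxation is integrated in the interaction picture (with
  Γ = 0 the bath couples each coherence only to itself and the
  populations, so dropping the -i(E_i-E_j) rotation changes nothing but
  removes the oscillations that force small steps); stationarity is always
  checked on the original equation at ‖dρ/dt‖_max < 10⁻¹²;
* the biased steady state is computed in *deviation* variables
  δρ = ρ - ρ_eq, for which the dynamics is exactly
  dδρ/dt = Lδρ + J + Q(δρ) with a known quadratic remainder Q — necessary
  because δρ/ρ_eq can be below machine precision;
* the stationary linearized equation is solved along two independent
  routes: time propagation of the inhomogeneous flow by matrix-exponential
  doubling (augmented generator [[L, J],[0, 0]], repeated squaring — no
  linear solve on this path) and a direct LU solve; they must agree to
  10⁻⁸ relative;
* the nonlinear stationary state follows by fixed-point iteration
  s ← -L⁻¹(J + Q(s)), and the conductance is the net contact current
  I = (e/ħ)Tr(Γ_R δρ) + (e²U/ħ)Σ_iΓ_R^{ii}D^i (escape minus injection; the
  left-contact expression agrees in steady state by a trace identity of L,
  which is asserted), Richardson-extrapolated over two bias values
  (default eU = 0.5 and 1 meV).

On every toy family tested, the oracle and the superoperator contraction
agree to ~10⁻⁶ relative — far inside the 1% tolerance the validation
tests assert — which is strong evidence that the contraction is the exact
linear-response current of the master equation.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| η | dimensionless bath coupling | 1.46 | or derived from E_R via η = 2πE_R/ħω_c |
| ħω_c | bath cutoff energy | 0.0185 eV | protein-typical; toy tests often use 0.5 eV so eV-scale gaps relax on simulable timescales |
| T | temperature | 300 K | kT = 8.617333262×10⁻⁵·T eV; T < 1 K floored to 1 K unless `allow_low_T` |
| Γ_L, Γ_R | contact escape strengths | 0.1 eV | pair-distribution convention |
| μ | chemical potential | midgap | (E_HOMO+E_LUMO)/2; always overridable, flagged in metadata — 𝒯(r) diverges if a level sits exactly at μ |
| window | levels kept | HOMO-20 … LUMO+20 | maps use ±5 kT |
| grid spacing | map resolution | 1.5 Å | margin 3 Å beyond the bounding box |
| isovalue rule | surface threshold | top 5% (𝒵), top 20% (𝒯) | quantile of strictly positive voxels, linear interpolation |

γ(0) is set to its analytic limit ηkT (the defining quotient is 0/0 there).
At T = 0 only emission survives.  Near-singular superoperators (levels with
no relaxation path) fall back to a Tikhonov-regularized solve with ridge
10⁻¹²·‖L‖ and a warning.  D^i uses adaptive quadrature in whichever
variable makes the integrand smooth (Lorentzian angle for Γ^i ≲ 4 kT, the
μ ± 45 kT Fermi window otherwise), relative tolerance 10⁻⁹ with a guard
against outright non-convergence.

## Synthetic systems

The generators emulate exported quantum-chemistry matrices with known
physics: uniform tight-binding chains, donor–bridge–acceptor (DBA) wires
with a tunable barrier, disordered wires, two-level systems, and a toy
Slater-orbital molecule whose overlap matrix is analytic (1s STO integrals)
and whose Hamiltonian follows the Wolfsberg–Helmholz rule
H_rs = 1.75·S_rs·(H_rr+H_ss)/2 with a standard single-ζ parameter table —
a reproduction choice, not fitted to anything.  Defaults (1.5 Å spacing,
~1 eV frontier gaps) put the toys on protein-like scales.

What the toys do *not* emulate: real heme/porphyrin electronic structure,
eigenvector statistics of 10⁴-orbital proteins, structural disorder of
cryo-EM ensembles.  Passing tests therefore demonstrate correctness of the
formulas and their numerics, not agreement with any particular measured
protein conductance.

Two model-physics points surfaced by testing, useful when designing
numerical experiments:

* exponential distance decay of G_LB requires *localized* frontier
  orbitals with evanescent tails.  Delocalized band states give no decay
  (their amplitude products are distance-independent), and in a DBA wire
  the decay region ends where bridge-band contributions put a floor under
  the tunneling sum.  The decay tests probe donor→bridge-site pairs inside
  the tail region, where the slope has the closed form β = 2κ/a with
  cosh(κa) = (E_barrier - μ)/2t;
* donor→acceptor transport through a degenerate end pair is *resonant*
  (the frontier doublet straddles μ), so it does not decay with barrier
  height — the correct probe for barrier suppression is donor→bridge.

## Known limitations

* Exact degeneracies: the level-wise rates γ^{ij}, broadenings Γ^i and
  responses D^i are not covariant under orthogonal rotations inside a
  degenerate multiplet (the usual secular-form ambiguity), so conductance
  through exactly degenerate levels depends on the eigenbasis the solver
  returns.  Eigenvector signs are fixed deterministically (largest-
  magnitude component positive) so results are reproducible; genuinely
  degenerate multiplets should be interpreted with care.
* The Ohmic-bath parameters are phenomenological; with the protein cutoff
  (0.0185 eV) transitions across eV-scale gaps are astronomically slow,
  which is physical but makes the fast-relaxation decomposition
  inapplicable to isolated wide-gap systems.
* Linear response only; no cotunneling; contacts are wide-band
  (energy-independent Γ).
* Spatial maps evaluate molecular orbitals with the original (non-Löwdin)
  Slater basis functions; for the identity-overlap toys the two frames
  coincide, and for real systems the map is a visualization aid, not an
  observable.

## Problem sizes

The shipped tests and the acceptance script run on systems of 2–24
orbitals (superoperator windows ≤ 6 levels for the time-domain
comparisons, 20-site wires for the decay fits, 175-voxel grids for the
maps).  These sizes were chosen so every oracle — brute-force quadruple
loops, trapezoid quadrature, matrix-exponential propagation — is exact and
cheap; all of the physics checks are size-independent statements.
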