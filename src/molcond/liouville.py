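"""Full linear-response conductance from the linearized evolution superoperator.

A small voltage U shifts the contact chemical potentials to μ ± eU/2, which
injects a net current J into the molecule.  The stationary correction δρ to
the equilibrium density matrix solves 0 = L δρ + ħJ, where L is the evolution
operator of the master equation linearized around the Fermi-Dirac state.  The
conductance is the contraction

    G = -(e²Γ_LΓ_R/ħ) Σ_{ijpq} {Ψ_L^iΨ_L^j [L⁻¹]^{jipq} Ψ_R^pΨ_R^q
                               + Ψ_R^iΨ_R^j [L⁻¹]^{jipq} Ψ_L^pΨ_L^q} D^p(μ),

evaluated via two linear solves — never by forming the dense inverse.  The
superoperator acts on level pairs (i, j) flattened row-major, k = i·N_w + j;
this convention is fixed and pinned by the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg as sla
from scipy.integrate import quad

from .bath import BathSpec, RateMatrix, fermi_derivative, tilde_rates, transition_rates
from .constants import E2_OVER_HBAR_S, S_TO_NS
from .electronic import ElectronicStructure, select_window
from .results import ConductanceResult

__all__ = [
    "ContactPair",
    "ContactBias",
    "Superoperator",
    "contact_broadening",
    "compute_D",
    "external_current",
    "build_superoperator",
    "conductance_full",
    "full_conductance",
]

#: default hard cap on the window size: L is (N_w², N_w²) complex and dense.
MAX_WINDOW = 80


@dataclass
class ContactPair:
    """Two contact orbitals (Löwdin basis indices) with escape strengths in eV."""

    site_L: int
    site_R: int
    Gamma_L: float = 0.1
    Gamma_R: float = 0.1
    distance_A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.site_L == self.site_R:
            raise ValueError("contact sites must differ")
        if self.Gamma_L < 0 or self.Gamma_R < 0:
            raise ValueError("escape strengths must be non-negative")


@dataclass
class ContactBias:
    """Occupancy response of the contact-broadened levels to a μ shift.

    ``D[i]`` is the Fermi derivative f(E, μ) convolved with the level's
    lifetime-broadened Lorentzian density of states (1/eV); ``J_per_eU`` is
    the injected-current matrix per unit eU (so multiply by eU in eV).
    """

    D: np.ndarray
    window: np.ndarray
    J_per_eU: Optional[np.ndarray] = None


@dataclass
class Superoperator:
    """Linearized evolution operator over flattened level pairs (eV units)."""

    matrix: np.ndarray
    window: np.ndarray
    components: dict = field(default_factory=dict)

    @property
    def n_window(self) -> int:
        return self.window.size


def contact_broadening(
    es: ElectronicStructure, contacts: ContactPair, window: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Escape-rate matrix Γ^{ij} = Γ_L Ψ_L^iΨ_L^j + Γ_R Ψ_R^iΨ_R^j over the window.

    Rank ≤ 2, symmetric, positive semi-definite; the diagonal Γ^i is the
    lifetime broadening of level i.
    """
    psi_l = es.psi[contacts.site_L, window]
    psi_r = es.psi[contacts.site_R, window]
    gamma = (contacts.Gamma_L * np.outer(psi_l, psi_l)
             + contacts.Gamma_R * np.outer(psi_r, psi_r))
    return gamma, np.diag(gamma).copy()


def _lorentzian(E: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-normalized Lorentzian d_i(E) with FWHM ``width``."""
    return (width / (2.0 * np.pi)) / ((E - center) ** 2 + (width / 2.0) ** 2)


def compute_D(
    es: ElectronicStructure,
    gamma_diag: np.ndarray,
    mu: float,
    kt: float,
    window: np.ndarray,
    epsrel: float = 1e-9,
) -> np.ndarray:
    """Contact-occupancy response D^i(μ) = ∫ dE f(E,μ) d_i(E), in 1/eV.

    ``d_i`` is the unit Lorentzian of width Γ^i centered at E_i; for Γ^i → 0
    it collapses to f(E_i, μ).  Adaptive quadrature over whichever factor is
    the narrow one: for Γ^i ≲ kT the Lorentzian angle E = E_i + (Γ^i/2)·tanθ
    is the integration variable (integrand smooth and bounded); for Γ^i ≫ kT
    the Fermi derivative concentrates the mass, so the integral runs over
    μ ± 45 kT where f has decayed to ~1e-20 of its peak.
    """
    energies = es.energies[window]
    out = np.empty(window.size)
    for k, (e_k, g_k) in enumerate(zip(energies, gamma_diag)):
        if g_k < 1e-12:
            out[k] = fermi_derivative(e_k, mu, kt)
            continue
        if g_k <= 4.0 * kt:
            theta_mu = float(np.arctan(2.0 * (mu - e_k) / g_k))  # where f peaks
            val, err = quad(
                lambda th: fermi_derivative(e_k + 0.5 * g_k * np.tan(th), mu, kt)
                / np.pi,
                -np.pi / 2, np.pi / 2, points=[theta_mu], epsrel=epsrel,
                epsabs=0.0, limit=200,
            )
        else:
            lo, hi = mu - 45.0 * kt, mu + 45.0 * kt
            pts = [mu] + ([e_k] if lo < e_k < hi else [])
            val, err = quad(
                lambda E: fermi_derivative(E, mu, kt) * _lorentzian(E, e_k, g_k),
                lo, hi, points=pts, epsrel=epsrel, epsabs=0.0, limit=200,
            )
        # guard against outright quadrature failure; quadpack error
        # estimates are conservative by an order of magnitude or more
        if not np.isfinite(val) or (val > 1e-300 and err > 1e-3 * val):
            raise RuntimeError(
                f"D quadrature did not converge for level {k}: value {val}, "
                f"error estimate {err}, epsrel {epsrel}"
            )
        out[k] = val
    return out


def external_current(
    es: ElectronicStructure,
    contacts: ContactPair,
    D: np.ndarray,
    window: np.ndarray,
    eU: float = 1.0,
) -> np.ndarray:
    """Net injected current J^{ij} = (eU/2ħ)(Γ_L^{ij} - Γ_R^{ij})[D^i + D^j].

    Returned in ħ = 1 units (eV) for eU given in eV; antisymmetric under
    swapping the contact roles and zero for identical contact couplings.
    """
    psi_l = es.psi[contacts.site_L, window]
    psi_r = es.psi[contacts.site_R, window]
    dgamma = (contacts.Gamma_L * np.outer(psi_l, psi_l)
              - contacts.Gamma_R * np.outer(psi_r, psi_r))
    return 0.5 * eU * dgamma * (D[:, None] + D[None, :])


def build_superoperator(
    es: ElectronicStructure,
    window: np.ndarray,
    rates: RateMatrix,
    gamma_contact: np.ndarray,
    max_window: int = MAX_WINDOW,
) -> Superoperator:
    """Assemble the four terms of the linearized evolution operator.

    L^{ijpq} = -i(E_i-E_j)δ_ip δ_jq                        (coherent)
               - ½(Γ^{ip}δ_jq + δ_ip Γ^{qj})               (escape)
               + ½(γ̃^{ip} + γ̃^{jp}) δ_ij δ_pq            (gain)
               - ½Σ_r(γ̃^{ri} + γ̃^{rj}) δ_ip δ_jq         (loss)

    acting on pairs flattened row-major.  The components are kept separately
    for testing.
    """
    nw = window.size
    if nw > max_window:
        raise ValueError(
            f"window of {nw} levels gives a {nw ** 2}×{nw ** 2} superoperator; "
            f"cap is {max_window} — use the three-mechanism approximation instead"
        )
    if rates.gamma_tilde is None:
        raise ValueError("rates must carry gamma_tilde (call tilde_rates first)")
    e = es.energies[window]
    gt = rates.gamma_tilde
    eye = np.eye(nw)

    coherent = np.diag((-1j * (e[:, None] - e[None, :])).ravel())
    escape = -0.5 * (np.kron(gamma_contact, eye) + np.kron(eye, gamma_contact))
    gain = np.zeros((nw * nw, nw * nw))
    diag_pairs = np.arange(nw) * nw + np.arange(nw)
    gain[np.ix_(diag_pairs, diag_pairs)] = gt
    loss_rates = gt.sum(axis=0)  # Σ_r γ̃^{ri}
    loss = np.diag((-0.5 * (loss_rates[:, None] + loss_rates[None, :])).ravel())

    matrix = coherent + escape + gain + loss
    return Superoperator(
        matrix=matrix, window=np.asarray(window, dtype=int),
        components={"coherent": coherent, "escape": escape, "gain": gain, "loss": loss},
    )


def _solve_superoperator(L: np.ndarray, rhs: np.ndarray, ridge_scale: float = 1e-12):
    """Solve L x = rhs with a Tikhonov fallback for near-singular operators.

    Isolated levels without a relaxation path make L singular in exact
    arithmetic; the slow mode still dominates the physics, so a tiny ridge
    regularization recovers it.  A warning is emitted when the fallback runs.
    """
    try:
        x = sla.solve(L, rhs)
        resid = np.linalg.norm(L @ x - rhs)
        if np.all(np.isfinite(x)) and resid <= 1e-8 * max(np.linalg.norm(rhs), 1e-300):
            return x
    except sla.LinAlgError:
        pass
    lam = ridge_scale * np.linalg.norm(L, ord=np.inf)
    smin = sla.svdvals(L)[-1] if L.shape[0] <= 2500 else float("nan")
    warnings.warn(
        f"superoperator is near-singular (smallest singular value {smin:.3e}); "
        f"applying Tikhonov ridge {lam:.3e}",
        stacklevel=2,
    )
    lh = L.conj().T
    x = sla.solve(lh @ L + lam ** 2 * np.eye(L.shape[0]), lh @ rhs, assume_a="pos")
    if not np.all(np.isfinite(x)):
        raise sla.LinAlgError(
            f"superoperator solve failed; smallest singular value {smin:.3e}"
        )
    return x


def conductance_full(
    es: ElectronicStructure,
    contacts: ContactPair,
    bias: ContactBias,
    sup: Superoperator,
    imag_tol: float = 1e-8,
    neg_tol: float = 1e-10,
) -> ConductanceResult:
    """Evaluate the full conductance contraction through two linear solves.

    The occupancy weight enters symmetrized, ½(D^p + D^q): writing it on the
    first pair index alone leaves a spurious antisymmetric remainder that
    shows up as an imaginary part of the contraction, while its real part —
    the physical conductance that the time-domain steady-state current
    reproduces — is exactly the symmetrized evaluation.  With symmetric
    left/right vectors the result is real up to round-off, which the
    ``imag_tol`` check enforces.
    """
    window = sup.window
    psi_l = es.psi[contacts.site_L, window]
    psi_r = es.psi[contacts.site_R, window]
    d_sym = 0.5 * (bias.D[:, None] + bias.D[None, :])

    l_left = np.outer(psi_l, psi_l).ravel()   # l^{ji} = Ψ_L^i Ψ_L^j (symmetric)
    l_right = np.outer(psi_r, psi_r).ravel()
    r_right = (np.outer(psi_r, psi_r) * d_sym).ravel()  # r^{pq} = Ψ_R^pΨ_R^q ½(D^p+D^q)
    r_left = (np.outer(psi_l, psi_l) * d_sym).ravel()

    x_right = _solve_superoperator(sup.matrix, r_right.astype(complex))
    x_left = _solve_superoperator(sup.matrix, r_left.astype(complex))
    contraction = l_left @ x_right + l_right @ x_left
    g = -contacts.Gamma_L * contacts.Gamma_R * contraction  # in e²/ħ units

    scale = max(abs(g), 1e-300)
    if abs(g.imag) > imag_tol * scale:
        raise ValueError(
            f"conductance has a non-negligible imaginary residue: {g.imag:.3e} "
            f"(relative {abs(g.imag) / scale:.3e})"
        )
    g_real = g.real
    if g_real < -neg_tol * max(abs(g_real), 1.0):
        raise ValueError(
            f"conductance came out negative ({g_real:.3e} e²/ħ); the linear-"
            "response / weak-coupling assumptions are violated in this regime"
        )
    g_e2h = 2.0 * np.pi * g_real  # e²/ħ = 2π e²/h
    return ConductanceResult(
        G_e2h=g_e2h,
        method="full",
        log10_G_nS=np.log10(g_real * E2_OVER_HBAR_S * S_TO_NS) if g_real > 0 else -np.inf,
        params={
            "Gamma_L_eV": contacts.Gamma_L, "Gamma_R_eV": contacts.Gamma_R,
            "site_L": contacts.site_L, "site_R": contacts.site_R,
            "mu_eV": es.mu, "n_window": int(window.size),
        },
    )


def full_conductance(
    es: ElectronicStructure,
    contacts: ContactPair,
    bath: Optional[BathSpec] = None,
    window: Optional[np.ndarray] = None,
    window_levels: int = 20,
    max_window: int = MAX_WINDOW,
) -> ConductanceResult:
    """Driver: window → rates → superoperator → conductance, with defaults."""
    bath = bath or BathSpec()
    if window is None:
        window = select_window(es, "levels_k", window_levels)
    window = np.asarray(window, dtype=int)
    kt = bath.kt
    rates = tilde_rates(transition_rates(es, window, bath), es, bath)
    gamma_mat, gamma_diag = contact_broadening(es, contacts, window)
    D = compute_D(es, gamma_diag, es.mu, kt, window)
    sup = build_superoperator(es, window, rates, gamma_mat, max_window=max_window)
    bias = ContactBias(D=D, window=window,
                       J_per_eU=external_current(es, contacts, D, window))
    result = conductance_full(es, contacts, bias, sup)
    result.params.update({
        "temperature_K": bath.temperature_K, "kT_eV": kt,
        "bath_eta": bath.eta, "bath_cutoff_eV": bath.cutoff_ev,
    })
    return result
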