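"""Superoperator assembly, contact bias terms and the full conductance."""

import numpy as np
import pytest

from molcond.bath import BathSpec, fermi_derivative, tilde_rates, transition_rates
from molcond.constants import K_B
from molcond.electronic import ElectronicStructure, select_window
from molcond.liouville import (
    ContactBias,
    ContactPair,
    build_superoperator,
    compute_D,
    conductance_full,
    contact_broadening,
    external_current,
    full_conductance,
)

from conftest import random_es


def brute_force_L(e, gamma_contact, gt):
    """Naive quadruple-loop assembly of the linearized evolution operator."""
    nw = e.size
    L = np.zeros((nw, nw, nw, nw), dtype=complex)
    for i in range(nw):
        for j in range(nw):
            for p in range(nw):
                for q in range(nw):
                    val = 0.0j
                    if i == p and j == q:
                        val += -1j * (e[i] - e[j])
                        val += -0.5 * sum(gt[r, i] + gt[r, j] for r in range(nw))
                    if j == q:
                        val += -0.5 * gamma_contact[i, p]
                    if i == p:
                        val += -0.5 * gamma_contact[q, j]
                    if i == j and p == q:
                        val += 0.5 * (gt[i, p] + gt[j, p])
                    L[i, j, p, q] += val
    return L.reshape(nw * nw, nw * nw)


class TestContactBroadening:
    def test_localized_level_carries_full_gamma(self):
        psi = np.eye(3)
        es = ElectronicStructure(energies=np.arange(3.0), psi=psi, mu=0.5,
                                 homo_index=0, lumo_index=1)
        contacts = ContactPair(0, 2, Gamma_L=0.3, Gamma_R=0.7)
        _, diag = contact_broadening(es, contacts, np.arange(3))
        assert diag[0] == pytest.approx(0.3)
        assert diag[2] == pytest.approx(0.7)

    def test_rank_at_most_two_and_psd(self, chain_es):
        contacts = ContactPair(0, 7, 0.2, 0.4)
        gmat, _ = contact_broadening(chain_es, contacts, np.arange(8))
        evals = np.linalg.eigvalsh(gmat)
        assert (evals > -1e-14).all()
        assert (np.abs(evals) > 1e-12).sum() <= 2

    def test_trace_is_total_coupling(self, chain_es):
        # completeness over the full level set: Σ_i Γ^i = Γ_L + Γ_R
        contacts = ContactPair(1, 5, 0.13, 0.29)
        _, diag = contact_broadening(chain_es, contacts, np.arange(8))
        assert diag.sum() == pytest.approx(0.13 + 0.29, rel=1e-12)


class TestComputeD:
    def test_zero_broadening_gives_fermi_derivative(self, two_level_es):
        kt = K_B * 300.0
        D = compute_D(two_level_es, np.zeros(2), two_level_es.mu, kt, np.arange(2))
        expected = fermi_derivative(two_level_es.energies, two_level_es.mu, kt)
        assert np.allclose(D, expected, rtol=1e-12)

    def test_cold_limit_gives_lorentzian_at_mu(self, two_level_es):
        # kT ≪ Γ: f acts as a delta at μ, so D → d_i(μ)
        g = 0.2
        kt = 1e-5
        D = compute_D(two_level_es, np.full(2, g), two_level_es.mu, kt, np.arange(2))
        e = two_level_es.energies
        d_mu = (g / (2 * np.pi)) / ((two_level_es.mu - e) ** 2 + (g / 2) ** 2)
        assert np.allclose(D, d_mu, rtol=1e-4)

    def test_against_brute_force_trapezoid(self, two_level_es):
        kt = K_B * 300.0
        es = two_level_es.with_mu(two_level_es.energies[0])  # level at μ
        g = kt
        D = compute_D(es, np.full(2, g), es.mu, kt, np.arange(2))
        grid = np.linspace(es.mu - 50 * kt, es.mu + 50 * kt, 1_000_001)
        for k, e_k in enumerate(es.energies):
            lor = (g / (2 * np.pi)) / ((grid - e_k) ** 2 + (g / 2) ** 2)
            ref = np.trapezoid(fermi_derivative(grid, es.mu, kt) * lor, grid)
            assert D[k] == pytest.approx(ref, rel=1e-6)


class TestSuperoperator:
    def test_single_level_scalar(self, rng):
        es = random_es(rng, 1, mu=0.0)
        es = ElectronicStructure(energies=np.array([1.0]), psi=np.eye(1), mu=0.0,
                                 homo_index=0, lumo_index=0)
        bath = BathSpec(temperature_K=300.0, cutoff_ev=1.0)
        window = np.array([0])
        rates = tilde_rates(transition_rates(es, window, bath,
                                             warn_weak_coupling=False), es, bath)
        gmat = np.array([[0.37]])
        sup = build_superoperator(es, window, rates, gmat)
        assert sup.matrix.shape == (1, 1)
        assert sup.matrix[0, 0] == pytest.approx(-0.37)

    def test_matches_quadruple_loop(self, rng):
        es = random_es(rng, 4)
        bath = BathSpec(temperature_K=300.0, cutoff_ev=0.5)
        window = np.arange(4)
        rates = tilde_rates(transition_rates(es, window, bath,
                                             warn_weak_coupling=False), es, bath)
        contacts = ContactPair(0, 3, 0.05, 0.08)
        gmat, _ = contact_broadening(es, contacts, window)
        sup = build_superoperator(es, window, rates, gmat)
        ref = brute_force_L(es.energies, gmat, rates.gamma_tilde)
        assert np.abs(sup.matrix - ref).max() < 1e-12
        # action on a random perturbation matches too
        drho = rng.normal(size=(16,)) + 1j * rng.normal(size=(16,))
        assert np.abs(sup.matrix @ drho - ref @ drho).max() < 1e-12

    def test_relaxation_part_conserves_population(self, rng):
        # Γ = 0: column sums of the diagonal-pair sector of gain+loss vanish
        es = random_es(rng, 5)
        bath = BathSpec(temperature_K=300.0, cutoff_ev=0.5)
        window = np.arange(5)
        rates = tilde_rates(transition_rates(es, window, bath,
                                             warn_weak_coupling=False), es, bath)
        sup = build_superoperator(es, window, rates, np.zeros((5, 5)))
        relax = sup.components["gain"] + sup.components["loss"]
        diag_pairs = np.arange(5) * 5 + np.arange(5)
        col_sums = relax[np.ix_(diag_pairs, diag_pairs)].sum(axis=0)
        assert np.abs(col_sums).max() < 1e-14

    def test_spectrum_is_stable(self, rng):
        es = random_es(rng, 4)
        bath = BathSpec(temperature_K=300.0, cutoff_ev=0.5)
        window = np.arange(4)
        rates = tilde_rates(transition_rates(es, window, bath,
                                             warn_weak_coupling=False), es, bath)
        contacts = ContactPair(0, 3, 0.01, 0.01)
        gmat, _ = contact_broadening(es, contacts, window)
        sup = build_superoperator(es, window, rates, gmat)
        assert np.linalg.eigvals(sup.matrix).real.max() < 1e-12

    def test_window_cap_enforced(self, rng):
        es = random_es(rng, 10)
        bath = BathSpec(temperature_K=300.0, cutoff_ev=0.5)
        window = np.arange(10)
        rates = tilde_rates(transition_rates(es, window, bath,
                                             warn_weak_coupling=False), es, bath)
        with pytest.raises(ValueError, match="three-mechanism"):
            build_superoperator(es, window, rates, np.zeros((10, 10)), max_window=8)


class TestExternalCurrent:
    def test_zero_for_identical_couplings(self, two_level_es):
        # Γ_L^{ij} = Γ_R^{ij} element-wise requires the same site; emulate by
        # antisymmetry: swapping L and R flips the sign
        window = np.arange(2)
        D = np.array([0.3, 0.2])
        c1 = ContactPair(0, 1, 0.1, 0.1)
        c2 = ContactPair(1, 0, 0.1, 0.1)
        j1 = external_current(two_level_es, c1, D, window)
        j2 = external_current(two_level_es, c2, D, window)
        assert np.allclose(j1, -j2, atol=1e-15)

    def test_zero_bias_gives_zero(self, two_level_es):
        j = external_current(two_level_es, ContactPair(0, 1, 0.1, 0.1),
                             np.array([0.3, 0.2]), np.arange(2), eU=0.0)
        assert np.all(j == 0.0)

    def test_against_naive_loop(self, rng):
        es = random_es(rng, 4)
        window = np.arange(4)
        D = rng.random(4)
        contacts = ContactPair(1, 2, 0.07, 0.11)
        j = external_current(es, contacts, D, window, eU=0.5)
        psi_l, psi_r = es.psi[1], es.psi[2]
        for i in range(4):
            for jx in range(4):
                gl = 0.07 * psi_l[i] * psi_l[jx]
                gr = 0.11 * psi_r[i] * psi_r[jx]
                expected = 0.5 / 2.0 * (gl - gr) * (D[i] + D[jx])
                assert j[i, jx] == pytest.approx(expected, abs=1e-15)


class TestConductanceFull:
    def _setup(self, es, contacts, bath, window):
        rates = tilde_rates(transition_rates(es, window, bath,
                                             warn_weak_coupling=False), es, bath)
        gmat, gdiag = contact_broadening(es, contacts, window)
        D = compute_D(es, gdiag, es.mu, bath.kt, window)
        sup = build_superoperator(es, window, rates, gmat)
        return ContactBias(D=D, window=window), sup

    def test_zero_left_coupling_zero_conductance(self, two_level_es, warm_bath):
        contacts = ContactPair(0, 1, 0.0, 0.1)
        window = np.arange(2)
        bias, sup = self._setup(two_level_es, contacts, warm_bath, window)
        res = conductance_full(two_level_es, contacts, bias, sup)
        assert res.G_e2h == 0.0

    def test_contact_swap_symmetry(self, dba_es, warm_bath):
        window = select_window(dba_es, "levels_k", 20)
        r1 = full_conductance(dba_es, ContactPair(0, 4, 0.02, 0.05), warm_bath,
                              window=window)
        r2 = full_conductance(dba_es, ContactPair(4, 0, 0.05, 0.02), warm_bath,
                              window=window)
        assert r1.G_e2h == pytest.approx(r2.G_e2h, rel=1e-9)

    def test_invariant_under_eigenvector_gauge(self, warm_bath, rng):
        """Sign flips of individual eigenvectors (the solver's only gauge
        freedom on a non-degenerate spectrum) leave G exactly unchanged, so
        the deterministic sign rule makes results reproducible.  Rotations
        inside an exactly degenerate multiplet are NOT a symmetry of the
        method: the bath overlap factors and per-level broadenings Γ^i are
        defined level-wise, an intrinsic secular-form ambiguity documented
        in the methods note."""
        es_a = random_es(rng, 4)
        flips = np.diag([1.0, -1.0, -1.0, 1.0])
        es_b = ElectronicStructure(es_a.energies.copy(), es_a.psi @ flips,
                                   es_a.mu, es_a.homo_index, es_a.lumo_index)
        contacts = ContactPair(0, 3, 0.03, 0.03)
        window = np.arange(4)
        g_a = full_conductance(es_a, contacts, warm_bath, window=window).G_e2h
        g_b = full_conductance(es_b, contacts, warm_bath, window=window).G_e2h
        assert g_b == pytest.approx(g_a, rel=1e-12)

    def test_nonnegative_on_random_instances(self):
        bath = BathSpec(temperature_K=300.0, cutoff_ev=0.5)
        for seed in range(25):
            rng = np.random.default_rng(seed)
            es = random_es(rng, 5)
            contacts = ContactPair(0, 4, 0.02, 0.03)
            res = full_conductance(es, contacts, bath, window=np.arange(5))
            assert res.G_e2h >= -1e-12

    def test_matches_one_sided_contraction_real_part(self, rng):
        """Brute force: contract the naive L⁻¹ with the one-sided vectors
        (occupancy weight on the first pair index) and compare the real
        part against the two-solve implementation."""
        es = random_es(rng, 4)
        bath = BathSpec(temperature_K=300.0, cutoff_ev=0.5)
        contacts = ContactPair(0, 3, 0.04, 0.09)
        window = np.arange(4)
        bias, sup = self._setup(es, contacts, bath, window)
        res = conductance_full(es, contacts, bias, sup)

        rates = tilde_rates(transition_rates(es, window, bath,
                                             warn_weak_coupling=False), es, bath)
        gmat, _ = contact_broadening(es, contacts, window)
        L_inv = np.linalg.inv(
            brute_force_L(es.energies, gmat, rates.gamma_tilde)
        ).reshape(4, 4, 4, 4)
        psi_l, psi_r = es.psi[0], es.psi[3]
        total = 0.0j
        for i in range(4):
            for j in range(4):
                for p in range(4):
                    for q in range(4):
                        total += (psi_l[i] * psi_l[j] * L_inv[j, i, p, q]
                                  * psi_r[p] * psi_r[q]) * bias.D[p]
                        total += (psi_r[i] * psi_r[j] * L_inv[j, i, p, q]
                                  * psi_l[p] * psi_l[q]) * bias.D[p]
        g_ref = 2 * np.pi * (-contacts.Gamma_L * contacts.Gamma_R * total).real
        assert res.G_e2h == pytest.approx(g_ref, rel=1e-12)


def _eig(h):
    from molcond.electronic import solve_eigensystem

    return solve_eigensystem(h)
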