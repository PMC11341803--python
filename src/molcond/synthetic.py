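"""Synthetic model molecules with known physics.

Tight-binding chains, donor-bridge-acceptor wires, disordered wires and
two-level systems, plus a toy Slater-orbital system with an analytic overlap
matrix and an extended-Hückel-like Hamiltonian.  These stand in for exported
quantum-chemistry matrices of real molecules: every generated system carries
atom coordinates and per-orbital metadata, so the spatial maps and the
distance/temperature sweep protocols run end-to-end on them.

Default toy parameters place a HOMO-LUMO gap of order 1 eV (a protein-like
scale) straddled by the chemical potential, with 1.5 Å site spacing so that
distance sweeps span tens of Å with tens of atoms.  These are package
choices for realistic-looking toys, not values taken from any particular
molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .constants import BOHR_A
from .electronic import OrbitalMeta, RawSystem

__all__ = [
    "ModelSpec",
    "make_model",
    "make_toy_sto_system",
    "sto_1s_overlap",
    "EHT_PARAMS",
]

#: minimal extended-Hückel parameter table: element -> (H_ii in eV, ζ in 1/Bohr).
#: Standard single-ζ valence s parameters; a reproduction choice, not fitted here.
EHT_PARAMS = {
    "H": (-13.6, 1.3),
    "C": (-21.4, 1.625),
    "N": (-26.0, 1.95),
    "O": (-32.3, 2.275),
}

#: Wolfsberg-Helmholz constant for H_rs = K S_rs (H_rr + H_ss)/2.
WOLFSBERG_HELMHOLZ_K = 1.75


@dataclass
class ModelSpec:
    """Recipe for a model Hamiltonian.

    ``kind``: uniform_chain | dba_wire | disordered_wire | two_level.
    Site energies and hoppings in eV, geometry collinear along x with the
    given spacing in Å.  ``n_electrons`` defaults to half filling.
    """

    kind: Literal["uniform_chain", "dba_wire", "disordered_wire", "two_level"]
    n_sites: int = 10
    epsilon: float = 0.0
    hopping: float = 0.5
    barrier: float = 3.0          # dba_wire bridge height above donor/acceptor
    disorder_W: float = 1.0       # disordered_wire box width
    gap: float = 1.0              # two_level splitting Δ
    spacing_A: float = 1.5
    n_electrons: Optional[int] = None
    seed: int = 0
    overlap: Literal["identity", "gaussian"] = "identity"
    element: str = "C"

    def __post_init__(self) -> None:
        if self.kind == "two_level":
            self.n_sites = 2
        if self.n_sites < 2:
            raise ValueError("need at least two sites")
        if self.spacing_A <= 0:
            raise ValueError("spacing must be positive")
        if self.n_electrons is None:
            self.n_electrons = self.n_sites if self.n_sites % 2 == 0 else self.n_sites + 1


def _chain_meta(n: int, spacing: float, element: str) -> list[OrbitalMeta]:
    return [
        OrbitalMeta(atom_index=i, element=element, label="1s",
                    position=np.array([i * spacing, 0.0, 0.0]))
        for i in range(n)
    ]


def _gaussian_overlap(positions: np.ndarray, decay_A: float = 1.0) -> np.ndarray:
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    s = np.exp(-((d / decay_A) ** 2))
    # Gaussian kernels are positive definite for any geometry
    return s


def make_model(spec: ModelSpec) -> RawSystem:
    """Build the RawSystem for a model recipe (deterministic under the seed)."""
    n = spec.n_sites
    eps = np.full(n, spec.epsilon, dtype=float)
    if spec.kind == "uniform_chain":
        t = np.full(n - 1, spec.hopping)
    elif spec.kind == "dba_wire":
        eps[1:-1] = spec.epsilon + spec.barrier
        t = np.full(n - 1, spec.hopping)
    elif spec.kind == "disordered_wire":
        rng = np.random.default_rng(spec.seed)
        eps = spec.epsilon + spec.disorder_W * (rng.random(n) - 0.5)
        t = np.full(n - 1, spec.hopping)
    elif spec.kind == "two_level":
        t = np.array([spec.gap / 2.0])
    else:
        raise ValueError(f"unknown model kind {spec.kind!r}")

    h = np.diag(eps)
    h[np.arange(n - 1), np.arange(1, n)] = -t
    h[np.arange(1, n), np.arange(n - 1)] = -t
    meta = _chain_meta(n, spec.spacing_A, spec.element)
    if spec.overlap == "identity":
        s = np.eye(n)
    else:
        s = _gaussian_overlap(np.array([m.position for m in meta]))
    return RawSystem(H=h, S=s, orbital_meta=meta)


def _aux_A(n: int, p: float) -> float:
    """A_n(p) = ∫_1^∞ λⁿ e^{-pλ} dλ."""
    # recursion A_n = e^{-p}/p + n/p · A_{n-1}
    a = np.exp(-p) / p
    for k in range(1, n + 1):
        a = np.exp(-p) / p + k * a / p
    return a


def _aux_B(n: int, q: float) -> float:
    """B_n(q) = ∫_{-1}^{1} μⁿ e^{-qμ} dμ."""
    if abs(q) < 1e-8:
        return 2.0 / (n + 1) if n % 2 == 0 else 0.0
    if n == 0:
        return (np.exp(q) - np.exp(-q)) / q
    # B_n = (e^q - (-1)^n e^{-q})/q ... use recursion B_n = ((-1)^n e^{q} - e^{-q})/q + n/q B_{n-1}
    b = _aux_B(0, q)
    for k in range(1, n + 1):
        b = ((-1) ** k * np.exp(q) - np.exp(-q)) / q + k * b / q
    return b


def sto_1s_overlap(zeta_a: float, zeta_b: float, R: float) -> float:
    """Analytic overlap of two 1s Slater orbitals (ζ in 1/Å, R in Å).

    Uses the equal-exponent closed form when ζ_a ≈ ζ_b, otherwise the
    prolate-spheroidal auxiliary-integral expansion.
    """
    if R == 0.0:
        if abs(zeta_a - zeta_b) < 1e-12:
            return 1.0
        return float((2 * np.sqrt(zeta_a * zeta_b) / (zeta_a + zeta_b)) ** 3)
    if abs(zeta_a - zeta_b) < 1e-10 * (zeta_a + zeta_b):
        zr = 0.5 * (zeta_a + zeta_b) * R
        return float(np.exp(-zr) * (1.0 + zr + zr ** 2 / 3.0))
    p = 0.5 * R * (zeta_a + zeta_b)
    q = 0.5 * R * (zeta_a - zeta_b)
    pref = (zeta_a * zeta_b) ** 1.5 * (R / 2.0) ** 3 * 2.0
    return float(pref * (_aux_A(2, p) * _aux_B(0, q) - _aux_A(0, p) * _aux_B(2, q)))


def make_toy_sto_system(
    n_atoms: int,
    elements: Optional[Sequence[str]] = None,
    spacing_A: float = 1.5,
    wh_constant: float = WOLFSBERG_HELMHOLZ_K,
) -> RawSystem:
    """Collinear toy molecule with one s-type Slater orbital per atom.

    Overlaps are analytic 1s-STO integrals; the Hamiltonian follows the
    extended-Hückel rule H_rs = K·S_rs·(H_rr + H_ss)/2 with the standard
    Wolfsberg-Helmholz K = 1.75 and tabulated on-site energies.
    """
    if elements is None:
        elements = ["C"] * n_atoms
    elements = [e.capitalize() for e in elements]
    if len(elements) != n_atoms:
        raise ValueError("element pattern length must equal n_atoms")
    meta = []
    for i, el in enumerate(elements):
        if el not in EHT_PARAMS:
            raise ValueError(f"no parameters for element {el!r}")
        _, zeta_bohr = EHT_PARAMS[el]
        meta.append(OrbitalMeta(
            atom_index=i, element=el, label="1s", zeta=zeta_bohr,
            position=np.array([i * spacing_A, 0.0, 0.0]),
        ))
    zeta_per_A = np.array([m.zeta / BOHR_A for m in meta])
    h_on = np.array([EHT_PARAMS[el][0] for el in elements])
    pos = np.array([m.position for m in meta])

    n = n_atoms
    s = np.eye(n)
    h = np.diag(h_on)
    for a in range(n):
        for b in range(a + 1, n):
            r = float(np.linalg.norm(pos[a] - pos[b]))
            s_ab = sto_1s_overlap(zeta_per_A[a], zeta_per_A[b], r)
            s[a, b] = s[b, a] = s_ab
            h_ab = 0.5 * wh_constant * s_ab * (h_on[a] + h_on[b])
            h[a, b] = h[b, a] = h_ab
    return RawSystem(H=h, S=s, orbital_meta=meta)
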