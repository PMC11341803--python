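"""Single-electron LCAO electronic structure.

Turns a (Hamiltonian, overlap) pair from a semi-empirical LCAO calculation
(e.g. an extended-Hückel export) into an orthonormal eigenbasis with a
chemical potential and HOMO/LUMO bookkeeping.  The overlap is removed by
Löwdin's symmetric orthogonalization H̃ = S^{-1/2} H S^{-1/2}, which
preserves the generalized spectrum of (H, S) while keeping one orbital per
basis function, so contact sites remain identifiable orbitals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import scipy.linalg as sla

from .constants import kT as thermal_energy

__all__ = [
    "OrbitalMeta",
    "RawSystem",
    "ElectronicStructure",
    "lowdin_orthogonalize",
    "solve_eigensystem",
    "assign_levels",
    "select_window",
]

_SYM_TOL = 1e-8


@dataclass
class OrbitalMeta:
    """Per-orbital record: which atom hosts it and what it looks like."""

    atom_index: int
    element: str = "C"
    label: str = "1s"  # n,l,m label, e.g. "1s", "2px"
    zeta: float = 1.625  # Slater exponent, 1/Bohr unless noted
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))  # Å
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.element.upper() == "H":
            self.is_hydrogen = True


@dataclass
class RawSystem:
    """Orbital-basis Hamiltonian (eV) and overlap with per-orbital metadata."""

    H: np.ndarray
    S: np.ndarray
    orbital_meta: list[OrbitalMeta]

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        n = self.H.shape[0]
        if self.H.shape != (n, n) or self.S.shape != (n, n):
            raise ValueError("H and S must be square matrices of equal size")
        if len(self.orbital_meta) != n:
            raise ValueError(
                f"orbital_meta has {len(self.orbital_meta)} entries for {n} orbitals"
            )
        _check_symmetric(self.H, "H")
        _check_symmetric(self.S, "S")

    @property
    def n_orbitals(self) -> int:
        return self.H.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of host-atom coordinates in Å."""
        return np.array([m.position for m in self.orbital_meta])

    @property
    def hydrogen_mask(self) -> np.ndarray:
        return np.array([m.is_hydrogen for m in self.orbital_meta], dtype=bool)


@dataclass
class ElectronicStructure:
    """Orthonormal eigenbasis with chemical potential.

    ``psi[:, i]`` is the i-th molecular orbital expressed over the
    (orthogonalized) atomic orbitals; ``energies`` ascend.
    """

    energies: np.ndarray
    psi: np.ndarray
    mu: float
    homo_index: int
    lumo_index: int
    basis: Literal["orthogonal", "lowdin"] = "orthogonal"
    system: Optional[RawSystem] = None

    @property
    def n_levels(self) -> int:
        return self.energies.size

    def with_mu(self, mu: float) -> "ElectronicStructure":
        return ElectronicStructure(
            self.energies, self.psi, mu, self.homo_index, self.lumo_index,
            self.basis, self.system,
        )

    @classmethod
    def from_raw(
        cls,
        raw: RawSystem,
        n_electrons: int,
        mu: Optional[float] = None,
        homo_shift: int = 0,
    ) -> "ElectronicStructure":
        """Löwdin-orthogonalize, diagonalize and place the chemical potential."""
        if np.allclose(raw.S, np.eye(raw.n_orbitals)):
            h = raw.H
            basis: Literal["orthogonal", "lowdin"] = "orthogonal"
        else:
            h = lowdin_orthogonalize(raw)
            basis = "lowdin"
        energies, psi = solve_eigensystem(h)
        homo, lumo, mu_auto = assign_levels(energies, n_electrons, homo_shift=homo_shift)
        return cls(energies, psi, mu_auto if mu is None else float(mu),
                   homo, lumo, basis, raw)


def _check_symmetric(a: np.ndarray, name: str, tol: float = _SYM_TOL) -> None:
    scale = max(np.abs(a).max(), 1.0)
    if np.abs(a - a.T).max() > tol * scale:
        raise ValueError(f"{name} is not symmetric within tolerance {tol}")


def lowdin_orthogonalize(raw: RawSystem) -> np.ndarray:
    """Symmetric orthogonalization H̃ = S^{-1/2} H S^{-1/2}.

    Raises if S is not positive definite (reports its smallest eigenvalue,
    which is what goes wrong with near-linearly-dependent basis sets).
    """
    s_eval, s_evec = sla.eigh(raw.S)
    if s_eval[0] <= 0.0:
        raise ValueError(
            f"overlap matrix is not positive definite: smallest eigenvalue "
            f"{s_eval[0]:.3e}"
        )
    s_inv_half = (s_evec / np.sqrt(s_eval)) @ s_evec.T
    h_tilde = s_inv_half @ raw.H @ s_inv_half
    return 0.5 * (h_tilde + h_tilde.T)


def solve_eigensystem(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Diagonalize a real symmetric Hamiltonian.

    Returns ascending eigenvalues and orthonormal eigenvectors (columns).
    Sign convention: the largest-magnitude component of each eigenvector is
    made positive (ties resolved to the lowest index by ``argmax``), so
    serialized results are reproducible across LAPACK builds.
    """
    h = np.asarray(h, dtype=float)
    _check_symmetric(h, "Hamiltonian")
    energies, psi = sla.eigh(0.5 * (h + h.T))
    for i in range(psi.shape[1]):
        k = int(np.argmax(np.abs(psi[:, i])))
        if psi[k, i] < 0:
            psi[:, i] = -psi[:, i]
    return energies, psi


def assign_levels(
    energies: np.ndarray,
    n_electrons: int,
    homo_shift: int = 0,
    mu: Optional[float] = None,
) -> tuple[int, int, float]:
    """Locate HOMO/LUMO from the electron count and place μ.

    Levels are doubly occupied (closed shell), so ``homo = n_electrons/2 - 1``
    (0-based).  ``homo_shift`` moves the HOMO by whole levels, which is how
    spurious extra electrons in a prepared structure are corrected.  By
    default μ sits at midgap, the unique symmetric choice; pass ``mu`` to
    override.
    """
    energies = np.asarray(energies, dtype=float)
    n = energies.size
    if n_electrons <= 0 or n_electrons % 2:
        raise ValueError("n_electrons must be a positive even integer (closed shell)")
    if n_electrons > 2 * n:
        raise ValueError(f"{n_electrons} electrons do not fit in {n} levels")
    homo = n_electrons // 2 - 1 + homo_shift
    if not 0 <= homo < n - 1:
        raise ValueError(
            f"HOMO index {homo} leaves no LUMO among {n} levels "
            "(completely filled or shifted out of range)"
        )
    lumo = homo + 1
    if mu is None:
        mu = 0.5 * (energies[homo] + energies[lumo])
    return homo, lumo, float(mu)


def select_window(
    es: ElectronicStructure,
    mode: Literal["levels_k", "energy_kT"] = "levels_k",
    size: float = 20,
    temperature_K: float = 300.0,
) -> np.ndarray:
    """Level indices kept in rate/conductance sums.

    ``levels_k``: ``size`` levels below the HOMO through ``size`` above the
    LUMO, clipped to the spectrum.  ``energy_kT``: all levels within
    ``size·kT`` of the HOMO (below) and LUMO (above) energies — the window
    used for visualization.
    """
    n = es.n_levels
    if mode == "levels_k":
        k = int(size)
        lo = max(es.homo_index - k, 0)
        hi = min(es.lumo_index + k, n - 1)
        return np.arange(lo, hi + 1)
    if mode == "energy_kT":
        kt = thermal_energy(temperature_K)
        lo_e = es.energies[es.homo_index] - size * kt
        hi_e = es.energies[es.lumo_index] + size * kt
        return np.nonzero((es.energies >= lo_e) & (es.energies <= hi_e))[0]
    raise ValueError(f"unknown window mode {mode!r}")
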