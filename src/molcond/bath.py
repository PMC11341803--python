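"""Ohmic phonon bath: spectral density and level-to-level relaxation rates.

The molecule exchanges energy with a harmonic environment described by an
Ohmic spectral density with exponential cutoff,

    γ(ω) = η ħω e^{-|ω|/ω_c} / (e^{ħω/kT} - 1),

which obeys the detailed-balance identity γ(ω)/γ(-ω) = e^{-ħω/kT}: upward
(absorbing) transitions are Boltzmann-suppressed relative to downward ones,
so relaxation drives level occupations toward the Fermi-Dirac distribution.
Level-to-level rates weight γ by how much two molecular orbitals overlap in
real space, Σ_n |Ψ_n^i|²|Ψ_n^j|².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .constants import K_B
from .electronic import ElectronicStructure

__all__ = [
    "BathSpec",
    "RateMatrix",
    "fermi",
    "fermi_derivative",
    "spectral_density",
    "transition_rates",
    "tilde_rates",
]

#: default cutoff energy ħω_c for protein environments, eV
DEFAULT_CUTOFF_EV = 0.0185
#: default dimensionless coupling η = 2π E_R / ħω_c
DEFAULT_ETA = 1.46


def fermi(E, mu: float, kt: float):
    """Fermi-Dirac distribution F(E, μ) = 1/(1 + e^{(E-μ)/kT}).

    Handles kT = 0 as the step-function limit (F = 1/2 at E = μ).
    """
    E = np.asarray(E, dtype=float)
    if kt <= 0.0:
        out = np.where(E < mu, 1.0, np.where(E > mu, 0.0, 0.5))
        return out if out.ndim else float(out)
    out = expit(-(E - mu) / kt)
    return out if np.ndim(out) else float(out)


def fermi_derivative(E, mu: float, kt: float):
    """f(E, μ) = ∂F/∂μ = 1/(4kT cosh²((E-μ)/2kT)), units 1/eV."""
    E = np.asarray(E, dtype=float)
    if kt <= 0.0:
        raise ValueError("fermi_derivative is a delta function at kT = 0")
    x = (E - mu) / (2.0 * kt)
    # 1/cosh²(x) = 4 e^{-2|x|} / (1 + e^{-2|x|})²  — underflow-safe
    e = np.exp(-2.0 * np.abs(x))
    out = e / (kt * (1.0 + e) ** 2)
    return out if out.ndim else float(out)


@dataclass
class BathSpec:
    """Ohmic bath parameters.

    ``eta`` is the dimensionless coupling; ``cutoff_ev`` stores ħω_c in eV;
    ``temperature_K`` the bath temperature.  Alternatively supply the
    reorganization energy ``E_R`` (eV) and η is derived as 2π E_R / ħω_c.
    """

    eta: float = DEFAULT_ETA
    cutoff_ev: float = DEFAULT_CUTOFF_EV
    temperature_K: float = 300.0
    E_R: Optional[float] = None
    allow_low_T: bool = False

    def __post_init__(self) -> None:
        if self.E_R is not None:
            self.eta = 2.0 * np.pi * self.E_R / self.cutoff_ev
        if self.eta <= 0 or self.cutoff_ev <= 0:
            raise ValueError("eta and cutoff must be positive")
        if self.temperature_K < 0:
            raise ValueError("temperature must be >= 0")

    @property
    def kt(self) -> float:
        """Thermal energy in eV (with the optional 1 K floor applied)."""
        t = self.temperature_K
        if not self.allow_low_T and t < 1.0:
            t = 1.0
        return K_B * t


@dataclass
class RateMatrix:
    """Bath-induced transition rates over a level window (in eV, i.e. ħ·rate).

    ``gamma[i, j]`` is the rate for the j → i transition; ``gamma_tilde`` are
    the Fermi-blocking-corrected rates entering the linearized evolution
    operator.  Indices are positions within ``window``.
    """

    gamma: np.ndarray
    window: np.ndarray
    gamma_tilde: Optional[np.ndarray] = None


def spectral_density(energy_ev, bath: BathSpec):
    """Ohmic bath rate γ at transition energy ħω (eV); returns eV.

    The closed-form quotient is 0/0 at ω = 0; the analytic limit is η·kT.  At T = 0
    only emission survives: γ = η|ħω|e^{-|ħω|/ħω_c} for ħω < 0, else 0.
    """
    x = np.asarray(energy_ev, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    cut = np.exp(-np.abs(x) / bath.cutoff_ev)
    kt = K_B * bath.temperature_K
    if kt == 0.0:
        out = np.where(x < 0, bath.eta * np.abs(x) * cut, 0.0)
        return float(out[0]) if scalar else out
    out = np.empty_like(x)
    small = np.abs(x) < 1e-12 * kt
    out[small] = bath.eta * kt
    xs = x[~small]
    # x/(e^{x/kT}-1), evaluated stably on both signs
    with np.errstate(over="ignore"):
        out[~small] = bath.eta * xs / np.expm1(xs / kt) * cut[~small]
    return float(out[0]) if scalar else out


def _overlap_factor(psi: np.ndarray) -> np.ndarray:
    """Σ_n |Ψ_n^i|² |Ψ_n^j|² for columns of psi — in (0, 1]."""
    p = psi ** 2
    return p.T @ p


def transition_rates(
    es: ElectronicStructure,
    window: np.ndarray,
    bath: BathSpec,
    warn_weak_coupling: bool = True,
) -> RateMatrix:
    """Level-to-level rates γ^{ij} = γ(E_i - E_j)·Σ_n|Ψ_n^i|²|Ψ_n^j|²."""
    window = np.asarray(window, dtype=int)
    if window.size and (window.min() < 0 or window.max() >= es.n_levels):
        raise IndexError("window indices out of range")
    e = es.energies[window]
    psi = es.psi[:, window]
    de = e[:, None] - e[None, :]
    gamma = spectral_density(de, bath) * _overlap_factor(psi)
    if warn_weak_coupling and window.size > 1:
        spacing = np.diff(np.sort(e))
        spacing = spacing[spacing > 1e-12]
        if spacing.size and gamma.max() > spacing.min():
            warnings.warn(
                "max bath rate exceeds the smallest level spacing; the "
                "weak-coupling master equation is marginal here",
                stacklevel=2,
            )
    return RateMatrix(gamma=gamma, window=window)


def tilde_rates(rates: RateMatrix, es: ElectronicStructure, bath: BathSpec) -> RateMatrix:
    """Rates entering the linearized operator: γ̃^{ij} = γ^{ij}(1-F_i)/(1-F_j).

    These absorb the Pauli-blocking factors of the equilibrium state.  They
    reduce to γ when the window sits far above μ (F → 0) and are undefined at
    T = 0 with occupied levels in the window.
    """
    kt = bath.kt
    if kt <= 0.0:
        raise ValueError(
            "tilde rates diverge at T = 0 with occupied levels; "
            "use a small positive temperature (or leave allow_low_T unset)"
        )
    e = es.energies[rates.window]
    one_minus_f = expit((e - es.mu) / kt)  # 1 - F(E)
    if np.any(one_minus_f <= 0.0):
        raise ValueError("1 - F underflowed to zero; raise the temperature floor")
    gt = rates.gamma * (one_minus_f[:, None] / one_minus_f[None, :])
    return RateMatrix(gamma=rates.gamma, window=rates.window, gamma_tilde=gt)
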