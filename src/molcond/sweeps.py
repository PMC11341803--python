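"""Sampling protocols: pair distributions, distance profiles, temperature scans.

Conductance between randomly chosen orbital pairs is lognormal-like, so all
distribution summaries work on log10 values.  Distance profiles average
log10 G over pairs whose host-atom separation falls within ±0.1 Å of a bin
center (centers are separations rounded to 0.1 Å); the tunneling term decays
as G_LB ∝ e^{-βd} and β is recovered by ordinary least squares on ln G_LB.
Temperature scans locate the crossover where the mixed mechanism overtakes
the thermally activated one as the dominant term at low temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .approx import pairwise_G
from .constants import kT as thermal_energy
from .electronic import ElectronicStructure, RawSystem

__all__ = [
    "sample_pairs",
    "distance_profile",
    "fit_beta",
    "BetaFit",
    "temperature_scan",
    "find_crossover",
]


def sample_pairs(
    structure: RawSystem,
    n_pairs: int,
    d_range: tuple[float, float] = (0.0, np.inf),
    exclude_hydrogen: bool = False,
    restrict_to: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform sample (without replacement) of eligible orbital pairs.

    Eligibility: both orbitals in ``restrict_to`` (if given), neither on a
    hydrogen when ``exclude_hydrogen``, host-atom distance within the
    inclusive ``d_range``.  Deterministic under ``seed``; if fewer eligible
    pairs exist than requested, all are returned with a warning.
    """
    positions = structure.positions
    n = structure.n_orbitals
    allowed = np.ones(n, dtype=bool)
    if exclude_hydrogen:
        allowed &= ~structure.hydrogen_mask
    if restrict_to is not None:
        mask = np.zeros(n, dtype=bool)
        mask[np.asarray(restrict_to, dtype=int)] = True
        allowed &= mask
    idx = np.nonzero(allowed)[0]
    a_idx, b_idx = np.triu_indices(idx.size, k=1)
    a, b = idx[a_idx], idx[b_idx]
    d = np.linalg.norm(positions[a] - positions[b], axis=1)
    keep = (d >= d_range[0]) & (d <= d_range[1])
    a, b, d = a[keep], b[keep], d[keep]

    rng = np.random.default_rng(seed)
    if a.size > n_pairs:
        pick = rng.choice(a.size, size=n_pairs, replace=False)
        pick.sort()
        a, b, d = a[pick], b[pick], d[pick]
    elif a.size < n_pairs:
        import warnings

        warnings.warn(
            f"only {a.size} eligible pairs for {n_pairs} requested; returning all",
            stacklevel=2,
        )
    return pd.DataFrame({"site_L": a, "site_R": b, "distance_A": d, "seed": seed})


def conductance_table(
    es: ElectronicStructure,
    pairs: pd.DataFrame,
    Gamma_L: float = 0.1,
    Gamma_R: float = 0.1,
    temperature_K: float = 300.0,
    window: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Three-mechanism conductance for every sampled pair (joined table)."""
    kt = thermal_energy(temperature_K)
    table = pairwise_G(es, list(zip(pairs["site_L"], pairs["site_R"])),
                       Gamma_L, Gamma_R, kt, window=window)
    table["distance_A"] = pairs["distance_A"].to_numpy()
    return table


def distance_profile(
    samples: pd.DataFrame,
    bin_tolerance: float = 0.1,
    terms: Sequence[str] = ("G", "G_LB", "G_T", "G_M"),
) -> pd.DataFrame:
    """Mean log10 conductance per distance bin.

    Bin centers are the observed distances rounded to the 0.1 Å grid; a pair
    contributes to a center when |d - center| ≤ ``bin_tolerance``.  Only
    strictly positive conductances enter the log mean; the number dropped is
    reported per bin.  Empty bins are omitted.
    """
    d = samples["distance_A"].to_numpy()
    centers = np.unique(np.round(d, 1))
    rows = []
    for c in centers:
        sel = np.abs(d - c) <= bin_tolerance + 1e-12
        if not sel.any():
            continue
        row = {"distance_A": float(c), "n": int(sel.sum())}
        for term in terms:
            logs = samples[f"log10_{term}_nS"].to_numpy()[sel]
            finite = logs[np.isfinite(logs)]
            row[f"mean_log10_{term}_nS"] = (
                float(finite.mean()) if finite.size else np.nan
            )
            row[f"n_dropped_{term}"] = int(sel.sum() - finite.size)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BetaFit:
    """Exponential-decay fit ln G = intercept - β d."""

    beta: float          # 1/Å
    beta_stderr: float
    intercept: float     # ln(G/nS) at d = 0
    r_squared: float
    n_points: int


def fit_beta(
    profile: pd.DataFrame,
    term: str = "G_LB",
) -> BetaFit:
    """OLS fit of ln G(term) versus distance on a binned profile."""
    col = f"mean_log10_{term}_nS"
    ok = profile[np.isfinite(profile[col])]
    if len(ok) < 3:
        raise ValueError(f"need at least 3 bins to fit a decay, got {len(ok)}")
    ln10 = np.log(10.0)
    res = linregress(ok["distance_A"], ok[col] * ln10)
    return BetaFit(
        beta=float(-res.slope),
        beta_stderr=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        n_points=len(ok),
    )


def temperature_scan(
    es: ElectronicStructure,
    pairs: pd.DataFrame,
    T_grid: Sequence[float],
    Gamma_L: float = 0.1,
    Gamma_R: float = 0.1,
    window: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Mean log10 conductance per mechanism across a temperature grid."""
    rows = []
    for t in T_grid:
        table = conductance_table(es, pairs, Gamma_L, Gamma_R, t, window)
        row = {"T_K": float(t)}
        for term in ("G", "G_LB", "G_T", "G_M"):
            logs = table[f"log10_{term}_nS"].to_numpy()
            finite = logs[np.isfinite(logs)]
            row[f"mean_log10_{term}_nS"] = (
                float(finite.mean()) if finite.size else -np.inf
            )
        rows.append(row)
    return pd.DataFrame(rows)


def find_crossover(
    scan: pd.DataFrame,
    term_a: str = "G_M",
    term_b: str = "G_T",
) -> Optional[float]:
    """Temperature where mean log10 of two mechanisms cross (interpolated).

    Returns the lowest-temperature crossing, or None if the curves never
    cross on the grid.
    """
    t = scan["T_K"].to_numpy()
    diff = (scan[f"mean_log10_{term_a}_nS"].to_numpy()
            - scan[f"mean_log10_{term_b}_nS"].to_numpy())
    order = np.argsort(t)
    t, diff = t[order], diff[order]
    finite = np.isfinite(diff)
    t, diff = t[finite], diff[finite]
    for k in range(t.size - 1):
        if diff[k] == 0.0:
            return float(t[k])
        if diff[k] * diff[k + 1] < 0:
            frac = diff[k] / (diff[k] - diff[k + 1])
            return float(t[k] + frac * (t[k + 1] - t[k]))
    return None
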