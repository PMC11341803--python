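"""Spatial conductivity indicators 𝒵(r) and 𝒯(r) on a rectangular grid.

𝒵(r) = Σ_k |Ψ^k(r)|² / cosh²((μ-E_k)/2kT) marks regions thermally
accessible from the frontier levels; 𝒯(r) = Σ_k |Ψ^k(r)|⁴ / (μ-E_k)² marks
regions reachable by off-resonant tunneling.  Molecular orbitals Ψ^k(r) are
LCAO sums of Slater-type atomic orbitals evaluated on the grid; the level
sums run over orbitals within a few kT of the HOMO and LUMO, which is where
the weights are non-negligible.  Regions where both functions are large are
the conductive core of the molecule.

Maps are written as Gaussian cube (default, widest tool support) or OpenDX
text, both loadable by VMD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .constants import BOHR_A, K_B
from .electronic import ElectronicStructure, OrbitalMeta, select_window

__all__ = [
    "SlaterOrbital",
    "VolumetricMap",
    "make_grid",
    "evaluate_mo",
    "z_map",
    "t_map",
    "percentile_isovalue",
    "write_cube",
    "read_cube",
    "write_dx",
    "read_dx",
]

_ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "Fe": 26}

#: default STO cutoff radius in Å; a 1s STO with ζ ≈ 2/Å is < 1e-6 beyond it.
DEFAULT_CUTOFF_A = 7.0


@dataclass
class SlaterOrbital:
    """Single Slater-type orbital φ(r) = N r^{n-1} e^{-ζr} Y_lm(r̂).

    ``zeta`` is in 1/Å (convert tabulated per-Bohr exponents with
    ``zeta_bohr / BOHR_A``); real spherical harmonics are used, so l ≤ 1 is
    currently supported (s and p).
    """

    center: np.ndarray
    n: int = 1
    l: int = 0
    m: int = 0
    zeta: float = 3.07  # 1/Å, carbon-like
    unit: Literal["inv_A"] = "inv_A"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.l not in (0, 1):
            raise NotImplementedError("only s and p Slater orbitals are implemented")
        if self.l == 1 and self.m not in (-1, 0, 1):
            raise ValueError("p orbital needs m in {-1, 0, 1}")
        if self.n < self.l + 1:
            raise ValueError("need n >= l + 1")

    @property
    def normalization(self) -> float:
        """Radial normalization constant (Å^{-3/2} together with Y_lm)."""
        from math import factorial

        return (2.0 * self.zeta) ** (self.n + 0.5) / np.sqrt(factorial(2 * self.n))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate on an (..., 3) array of Å coordinates."""
        d = points - self.center
        r = np.linalg.norm(d, axis=-1)
        radial = self.normalization * r ** (self.n - 1) * np.exp(-self.zeta * r)
        if self.l == 0:
            return radial / np.sqrt(4.0 * np.pi)
        with np.errstate(invalid="ignore", divide="ignore"):
            axis = {0: 2, 1: 0, -1: 1}[self.m]  # m=0→z, 1→x, -1→y
            ang = np.where(r > 0, d[..., axis] / np.where(r > 0, r, 1.0), 0.0)
        return radial * np.sqrt(3.0 / (4.0 * np.pi)) * ang


@dataclass
class VolumetricMap:
    """Scalar field sampled on a rectangular grid (Å metadata)."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    kind: Literal["Z", "T", "mo", "generic"] = "generic"
    atoms: list = field(default_factory=list)  # (element, position) pairs

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def points(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of grid-point coordinates in Å."""
        axes = [self.origin[k] + self.spacing * np.arange(self.dims[k])
                for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


def make_grid(
    positions: np.ndarray,
    spacing: float = 1.5,
    margin: float = 3.0,
) -> VolumetricMap:
    """Empty grid covering the atomic bounding box plus a margin (Å)."""
    positions = np.atleast_2d(positions)
    lo = positions.min(axis=0) - margin
    hi = positions.max(axis=0) + margin
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    return VolumetricMap(origin=lo, spacing=spacing, values=np.zeros(tuple(dims)))


def _orbitals_from_meta(meta: Sequence[OrbitalMeta]) -> list[SlaterOrbital]:
    orbs = []
    for m in meta:
        n = int(m.label[0]) if m.label and m.label[0].isdigit() else 1
        orbs.append(SlaterOrbital(center=m.position, n=n, l=0,
                                  zeta=m.zeta / BOHR_A))
    return orbs


def evaluate_mo(
    coefficients: np.ndarray,
    orbitals: Sequence[SlaterOrbital],
    grid: VolumetricMap,
    cutoff_A: float = DEFAULT_CUTOFF_A,
) -> np.ndarray:
    """LCAO molecular orbital Ψ(r) = Σ_r W_r φ_r(r) sampled on the grid.

    Grid points farther than ``cutoff_A`` from an orbital's center skip that
    orbital (the STO tail is negligible there).
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.size != len(orbitals):
        raise ValueError("coefficient length must equal the basis size")
    pts = grid.points()
    out = np.zeros(grid.dims)
    lo, hi = pts.reshape(-1, 3).min(axis=0), pts.reshape(-1, 3).max(axis=0)
    any_inside = False
    for w, orb in zip(coefficients, orbitals):
        if np.all((orb.center >= lo - cutoff_A) & (orb.center <= hi + cutoff_A)):
            any_inside = True
        if w == 0.0:
            continue
        d = pts - orb.center
        mask = np.einsum("...k,...k->...", d, d) <= cutoff_A ** 2
        if not mask.any():
            continue
        out[mask] += w * orb(pts[mask])
    if not any_inside:
        warnings.warn("grid does not cover any orbital center", stacklevel=2)
    return out


def _window_mos(es, grid, window, cutoff_A):
    if es.system is None:
        raise ValueError("electronic structure carries no orbital metadata")
    orbitals = _orbitals_from_meta(es.system.orbital_meta)
    return [evaluate_mo(es.psi[:, k], orbitals, grid, cutoff_A) for k in window]


def z_map(
    es: ElectronicStructure,
    grid: Optional[VolumetricMap] = None,
    kt: float = 0.025,
    window: Optional[np.ndarray] = None,
    window_kT: float = 5.0,
    cutoff_A: float = DEFAULT_CUTOFF_A,
) -> VolumetricMap:
    """Thermal accessibility map 𝒵(r); levels within ``window_kT``·kT of the gap."""
    if grid is None:
        grid = make_grid(es.system.positions)
    if window is None:
        window = select_window(es, "energy_kT", window_kT, kt / K_B)
    window = np.asarray(window, dtype=int)
    values = np.zeros(grid.dims)
    for k, mo in zip(window, _window_mos(es, grid, window, cutoff_A)):
        x = (es.mu - es.energies[k]) / (2.0 * kt)
        values += mo ** 2 / np.cosh(x) ** 2 if abs(x) < 350 else 0.0
    return VolumetricMap(origin=grid.origin, spacing=grid.spacing,
                         values=values, kind="Z", atoms=_atom_list(es))


def t_map(
    es: ElectronicStructure,
    grid: Optional[VolumetricMap] = None,
    window: Optional[np.ndarray] = None,
    window_kT: float = 5.0,
    kt: float = 0.025,
    cutoff_A: float = DEFAULT_CUTOFF_A,
) -> VolumetricMap:
    """Tunneling accessibility map 𝒯(r) = Σ_k |Ψ^k(r)|⁴/(μ-E_k)²."""
    if grid is None:
        grid = make_grid(es.system.positions)
    if window is None:
        window = select_window(es, "energy_kT", window_kT, kt / K_B)
    window = np.asarray(window, dtype=int)
    gaps = es.mu - es.energies[window]
    if np.any(np.abs(gaps) < 1e-9):
        raise ValueError(
            "a level sits at the chemical potential; 𝒯 diverges there — "
            "shift μ slightly or drop the level from the window"
        )
    values = np.zeros(grid.dims)
    for gap, mo in zip(gaps, _window_mos(es, grid, window, cutoff_A)):
        values += mo ** 4 / gap ** 2
    return VolumetricMap(origin=grid.origin, spacing=grid.spacing,
                         values=values, kind="T", atoms=_atom_list(es))


def _atom_list(es) -> list:
    if es.system is None:
        return []
    seen = {}
    for m in es.system.orbital_meta:
        seen.setdefault(m.atom_index, (m.element, m.position))
    return [seen[k] for k in sorted(seen)]


def percentile_isovalue(vmap: VolumetricMap, top_fraction: Optional[float] = None) -> float:
    """Isovalue enclosing the highest ``top_fraction`` of non-zero voxels.

    Defaults follow the visualization convention: top 5% for 𝒵 and top 20%
    for 𝒯.  Linear-interpolation quantile over strictly positive values.
    """
    if top_fraction is None:
        top_fraction = {"Z": 0.05, "T": 0.20}.get(vmap.kind, 0.05)
    positive = vmap.values[vmap.values > 0]
    if positive.size == 0:
        raise ValueError("map has no positive voxels")
    return float(np.quantile(positive, 1.0 - top_fraction))


# ---------------------------------------------------------------------------
# volumetric file formats


def write_cube(path, vmap: VolumetricMap, comment: str = "molcond volumetric map") -> None:
    """Gaussian cube file (lengths converted to Bohr, as the format requires)."""
    nx, ny, nz = vmap.dims
    sp = vmap.spacing / BOHR_A
    origin = vmap.origin / BOHR_A
    atoms = vmap.atoms or [("C", vmap.origin)]
    with open(path, "w") as fh:
        fh.write(f"{comment}\n{vmap.kind} map, grid spacing {vmap.spacing} A\n")
        fh.write(f"{len(atoms):5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {sp:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {sp:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {sp:12.6f}\n")
        for element, pos in atoms:
            z = _ELEMENT_Z.get(str(element).capitalize(), 6)
            p = np.asarray(pos, dtype=float) / BOHR_A
            fh.write(f"{z:5d} {0.0:12.6f} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}\n")
        buf = []
        flat_all = vmap.values.ravel()  # x slowest, z fastest — cube order
        for i, v in enumerate(flat_all):
            buf.append(f"{v:13.5E}")
            if len(buf) == 6 or i == flat_all.size - 1:
                fh.write(" ".join(buf) + "\n")
                buf = []


def read_cube(path) -> VolumetricMap:
    with open(path) as fh:
        fh.readline()
        kind_line = fh.readline().split(",")[0].split()
        kind = kind_line[0] if kind_line and kind_line[0] in ("Z", "T") else "generic"
        natoms_line = fh.readline().split()
        natoms = int(natoms_line[0])
        origin = np.array(natoms_line[1:4], dtype=float) * BOHR_A
        dims, spacings = [], []
        for _ in range(3):
            parts = fh.readline().split()
            dims.append(int(parts[0]))
            spacings.append(np.linalg.norm(np.array(parts[1:4], float)) * BOHR_A)
        atoms = []
        inv_z = {v: k for k, v in _ELEMENT_Z.items()}
        for _ in range(abs(natoms)):
            parts = fh.readline().split()
            atoms.append((inv_z.get(int(parts[0]), "C"),
                          np.array(parts[2:5], dtype=float) * BOHR_A))
        data = np.fromstring(fh.read(), sep=" ")
    values = data.reshape(tuple(dims))
    return VolumetricMap(origin=origin, spacing=float(spacings[0]),
                         values=values, kind=kind, atoms=atoms)


def write_dx(path, vmap: VolumetricMap) -> None:
    """OpenDX scalar field, the layout VMD and gridData read."""
    nx, ny, nz = vmap.dims
    sp = vmap.spacing
    o = vmap.origin
    n = vmap.values.size
    with open(path, "w") as fh:
        fh.write(f"# molcond {vmap.kind} map\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.7g} {o[1]:.7g} {o[2]:.7g}\n")
        fh.write(f"delta {sp:.7g} 0 0\ndelta 0 {sp:.7g} 0\ndelta 0 0 {sp:.7g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {n} data follows\n")
        flat = vmap.values.ravel()  # z fastest
        for i in range(0, n, 3):
            fh.write(" ".join(f"{v:.9E}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write(f'object "{vmap.kind} map" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path) -> VolumetricMap:
    dims = None
    origin = None
    deltas = []
    values = []
    reading = False
    n_items = 0
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object 1"):
                dims = tuple(int(x) for x in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array(s.split()[1:4], dtype=float)
            elif s.startswith("delta"):
                deltas.append(np.array(s.split()[1:4], dtype=float))
            elif "data follows" in s:
                n_items = int(s.split("items")[1].split()[0])
                reading = True
            elif reading:
                if s.startswith("attribute") or s.startswith("object"):
                    reading = False
                    continue
                values.extend(float(x) for x in s.split())
    if dims is None or origin is None or len(values) < n_items:
        raise ValueError(f"{path}: malformed DX file")
    spacing = float(deltas[0][0]) if deltas else 1.0
    return VolumetricMap(origin=origin, spacing=spacing,
                         values=np.array(values[:n_items]).reshape(dims))
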