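"""GRID-style probe affinity maps over a regular lattice.

At every point of an axis-aligned grid the interaction energy between the
whole receptor and an idealized chemical probe is evaluated as the sum of a
12-6 Lennard-Jones term, a Coulombic term (constant or distance-dependent
dielectric) and a geometry-based hydrogen-bond term, then capped at
``emax_cap`` so that clash points stay contourable.

Receptor Lennard-Jones parameters come from the PQR radii (``rmin_i``)
plus a small per-element well-depth table; combining rules are
``rmin_ij = rmin_i + rmin_probe`` and ``eps_ij = sqrt(eps_i · eps_probe)``.

The hydrogen-bond term is a 6-4 radial well scaled by a cos^m angular
weight with a 90° cutoff:

    E_hb(d, θ) = [2·emin·(r0/d)^6 − 3·emin·(r0/d)^4] · cos^m(180° − θ)

which has its minimum −emin at d = r0, θ = 180°.  When the receptor
donates, θ is the D–H···A angle measured with the file's hydrogen
positions; when the probe donates, the probe hydrogen is taken as ideally
oriented and directionality enters through the angle at the acceptor's
antecedent heavy atom (antiperiplanar is optimal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .probes import Probe
from .structure import Structure

__all__ = [
    "COULOMB_CONSTANT",
    "GridSpec",
    "AffinityMap",
    "Region",
    "DielectricModel",
    "lj_energy",
    "coulomb_energy",
    "hbond_energy",
    "compute_map",
    "find_regions",
    "residue_decomposition",
    "write_dx",
    "read_dx",
]

# kcal·Å/(mol·e²): Coulomb's constant in the field's customary units.
COULOMB_CONSTANT = 332.0636

# Per-element LJ well depths (kcal/mol) for receptor atoms; package defaults.
ELEMENT_EPS = {
    "H": 0.016,
    "C": 0.086,
    "N": 0.17,
    "O": 0.21,
    "S": 0.25,
    "P": 0.20,
}
DEFAULT_ELEMENT_EPS = 0.10

_MIN_R = 1e-6  # Å floor to keep grid points coincident with atoms finite


@dataclass(frozen=True)
class DielectricModel:
    """Either a constant dielectric or the distance-dependent ε = d·r."""

    kind: Literal["constant", "distance"] = "distance"
    factor: float = 4.0  # ε for constant; d in ε = d·r for distance-dependent

    def epsilon(self, r: np.ndarray | float):
        if self.kind == "constant":
            return self.factor
        if self.kind == "distance":
            return self.factor * r
        raise ValueError(f"unknown dielectric model {self.kind!r}")


@dataclass(frozen=True)
class GridSpec:
    """Regular axis-aligned grid: point (i,j,k) sits at
    ``center + spacing·((i,j,k) − (n−1)/2)``."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    npoints: tuple[int, int, int] = (50, 50, 50)
    spacing: float = 0.5

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(n < 1 for n in self.npoints):
            raise ValueError("npoints must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "npoints", tuple(int(n) for n in self.npoints))

    @property
    def origin(self) -> np.ndarray:
        """Position of point (0, 0, 0): center − spacing·(n−1)/2 per axis."""
        n = np.asarray(self.npoints, dtype=float)
        return np.asarray(self.center) - self.spacing * (n - 1) / 2.0

    @property
    def n_total(self) -> int:
        nx, ny, nz = self.npoints
        return nx * ny * nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        return tuple(o[d] + self.spacing * np.arange(self.npoints[d]) for d in range(3))

    def points(self) -> np.ndarray:
        """(n_total, 3) array of grid-point positions, index [ix, iy, iz]
        flattened in C order (z fastest)."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def point_position(self, idx: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)


@dataclass
class AffinityMap:
    """Probe interaction energies (kcal/mol) on a grid, indexed [ix, iy, iz]."""

    grid: GridSpec
    probe_name: str
    energies: np.ndarray
    emax_cap: float = 5.0

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.shape != self.grid.npoints:
            raise ValueError(f"energies shape {e.shape} != grid npoints {self.grid.npoints}")
        self.energies = e

    @property
    def min_energy(self) -> float:
        return float(self.energies.min())


@dataclass
class Region:
    """A 26-connected cluster of grid points below an energy threshold."""

    member_points: list[tuple[int, int, int]]
    centroid: np.ndarray
    volume: float          # Å³ = count × spacing³
    min_energy: float      # kcal/mol
    min_point: np.ndarray  # position of the deepest point, Å


def lj_energy(eps_ij: float, rmin_ij: float, r) -> float | np.ndarray:
    """12-6 Lennard-Jones energy: eps·[(rmin/r)^12 − 2(rmin/r)^6], kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("lj_energy requires r > 0")
    x6 = (rmin_ij / r) ** 6
    out = eps_ij * (x6 * x6 - 2.0 * x6)
    return float(out) if out.ndim == 0 else out


def coulomb_energy(q1: float, q2: float, r, dielectric: DielectricModel | None = None):
    """Coulomb energy 332.0636·q1·q2/(ε(r)·r) in kcal/mol (q in e, r in Å)."""
    if dielectric is None:
        dielectric = DielectricModel()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("coulomb_energy requires r > 0")
    out = COULOMB_CONSTANT * q1 * q2 / (dielectric.epsilon(r) * r)
    return float(out) if out.ndim == 0 else out


def hbond_energy(d, theta, emin: float = 4.0, r0: float = 2.8, m: int = 2):
    """6-4 radial hydrogen-bond well with cos^m angular weighting.

    ``d`` is the donor–acceptor heavy-atom distance (Å), ``theta`` the
    D–H···A angle in degrees (180° = linear).  Zero for θ < 90°; the
    minimum is −emin at d = r0, θ = 180°.
    """
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(d <= 0):
        raise ValueError("hbond_energy requires d > 0")
    if np.any((theta < 0) | (theta > 180)):
        raise ValueError("theta must lie in [0, 180] degrees")
    radial = 2.0 * emin * (r0 / d) ** 6 - 3.0 * emin * (r0 / d) ** 4
    ang = np.where(theta >= 90.0, np.cos(np.radians(180.0 - theta)) ** m, 0.0)
    out = radial * ang
    return float(out) if out.ndim == 0 else out


def _element_eps(element: str) -> float:
    return ELEMENT_EPS.get(element.capitalize(), DEFAULT_ELEMENT_EPS)


def _hb_topology(receptor: Structure):
    """Classify receptor N/O atoms as hydrogen-bond donors/acceptors.

    Donor: N or O with a hydrogen within 1.2 Å (H position kept for the
    angle).  Acceptor: any O, and N without an attached hydrogen.  The
    antecedent heavy atom (nearest non-H within 1.9 Å) supplies acceptor
    directionality.
    """
    pos = receptor.positions
    elements = [a.element.capitalize() for a in receptor.atoms]
    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    heavy_idx = [i for i, e in enumerate(elements) if e != "H"]
    donors: list[tuple[int, list[int]]] = []   # (heavy atom idx, attached H idxs)
    acceptors: list[tuple[int, int | None]] = []  # (atom idx, antecedent idx)
    for i, e in enumerate(elements):
        if e not in ("N", "O"):
            continue
        attached_h = [
            j for j in h_idx if np.linalg.norm(pos[j] - pos[i]) <= 1.2
        ]
        if attached_h:
            donors.append((i, attached_h))
        antecedent = None
        best = 1.9
        for j in heavy_idx:
            if j == i:
                continue
            d = float(np.linalg.norm(pos[j] - pos[i]))
            if d < best:
                best, antecedent = d, j
        if e == "O" or (e == "N" and not attached_h):
            acceptors.append((i, antecedent))
    return donors, acceptors


def compute_map(
    receptor: Structure,
    probe: Probe,
    grid: GridSpec,
    dielectric: DielectricModel | None = None,
    emax_cap: float = 5.0,
    cutoff: float | None = None,
) -> AffinityMap:
    """Sum probe–receptor LJ + Coulomb + H-bond energies at every grid point.

    ``cutoff`` (Å), when given, zeroes all pair contributions beyond that
    distance; by default no cutoff is applied.  Energies are capped at
    ``emax_cap`` after summation.
    """
    if len(receptor) == 0:
        raise ValueError("receptor is empty")
    needs_params = (probe.charge != 0 and probe.electrostatics) or probe.hb_donor or probe.hb_acceptor
    if needs_params and not receptor.has_charges:
        raise ValueError(
            f"probe {probe.name} needs receptor charges/radii; structure came from plain PDB"
        )
    if dielectric is None:
        dielectric = DielectricModel()

    pts = grid.points()
    pos = receptor.positions
    radii = receptor.radii if receptor.has_charges else np.full(len(receptor), 1.5)
    charges = receptor.charges if receptor.has_charges else np.zeros(len(receptor))
    eps_r = np.array([_element_eps(a.element) for a in receptor.atoms])

    lo, hi = pos.min(axis=0) - 10.0, pos.max(axis=0) + 10.0
    if np.all((pts < lo) | (pts > hi)):
        import warnings

        warnings.warn("grid lies entirely outside the receptor bounding box + 10 Å")

    energies = np.zeros(len(pts))
    use_coulomb = probe.electrostatics and probe.charge != 0.0
    for i in range(len(receptor)):
        r = np.linalg.norm(pts - pos[i], axis=1)
        np.maximum(r, _MIN_R, out=r)
        e = lj_energy(math.sqrt(eps_r[i] * probe.eps), radii[i] + probe.rmin, r)
        if use_coulomb and charges[i] != 0.0:
            e = e + coulomb_energy(probe.charge, charges[i], r, dielectric)
        if cutoff is not None:
            e = np.where(r <= cutoff, e, 0.0)
        energies += e

    if probe.hb_donor or probe.hb_acceptor:
        donors, acceptors = _hb_topology(receptor)
        if probe.hb_donor:
            for acc, ante in acceptors:
                d = np.linalg.norm(pts - pos[acc], axis=1)
                np.maximum(d, _MIN_R, out=d)
                if ante is None:
                    theta = np.full(len(pts), 180.0)
                else:
                    # angle antecedent–acceptor···probe; antiperiplanar optimal
                    v1 = pos[ante] - pos[acc]
                    v2 = pts - pos[acc]
                    cosang = (v2 @ v1) / (np.linalg.norm(v1) * np.maximum(d, _MIN_R))
                    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                e = hbond_energy(d, theta, probe.hb_emin, probe.hb_r0, probe.hb_m)
                if cutoff is not None:
                    e = np.where(d <= cutoff, e, 0.0)
                energies += e
        if probe.hb_acceptor:
            for don, h_list in donors:
                d = np.linalg.norm(pts - pos[don], axis=1)
                np.maximum(d, _MIN_R, out=d)
                # best (most linear) D–H···A angle over the donor's hydrogens
                best = np.zeros(len(pts))
                for h in h_list:
                    v1 = pos[don] - pos[h]
                    v2 = pts - pos[h]
                    norm2 = np.linalg.norm(v2, axis=1)
                    cosang = (v2 @ v1) / (np.linalg.norm(v1) * np.maximum(norm2, _MIN_R))
                    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    best = np.maximum(best, theta)
                e = hbond_energy(d, best, probe.hb_emin, probe.hb_r0, probe.hb_m)
                if cutoff is not None:
                    e = np.where(d <= cutoff, e, 0.0)
                energies += e

    np.minimum(energies, emax_cap, out=energies)
    return AffinityMap(
        grid=grid,
        probe_name=probe.name,
        energies=energies.reshape(grid.npoints),
        emax_cap=emax_cap,
    )


def find_regions(amap: AffinityMap, threshold: float = -2.5) -> list[Region]:
    """Extract 26-connected clusters of points with E ≤ threshold,
    sorted by minimum energy (deepest first)."""
    if threshold >= amap.emax_cap:
        raise ValueError("threshold must be below the energy cap")
    mask = amap.energies <= threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    regions: list[Region] = []
    spacing = amap.grid.spacing
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        coords = amap.grid.origin + spacing * idx.astype(float)
        energies = amap.energies[tuple(idx.T)]
        k = int(np.argmin(energies))
        regions.append(
            Region(
                member_points=[tuple(map(int, p)) for p in idx],
                centroid=coords.mean(axis=0),
                volume=len(idx) * spacing**3,
                min_energy=float(energies[k]),
                min_point=coords[k],
            )
        )
    regions.sort(key=lambda r: r.min_energy)
    return regions


def residue_decomposition(
    receptor: Structure,
    ligand: Structure,
    dielectric: DielectricModel | None = None,
) -> list[tuple[str, float, float, float]]:
    """Per-residue vdW + electrostatic interaction energies with a ligand.

    Both structures must carry PQR charges/radii.  Pair parameters follow
    the map conventions (``rmin_ij = r_i + r_j``, geometric-mean well
    depths); the residue sums add up exactly to the whole-complex
    interaction energy.  Returns ``(residue id, vdW, elec, total)`` tuples
    in receptor residue order, residue id formatted ``chain:resname:seq``.
    """
    if not (receptor.has_charges and ligand.has_charges):
        raise ValueError("residue decomposition requires charges/radii on both structures")
    if dielectric is None:
        dielectric = DielectricModel()
    lig_pos, lig_q, lig_r = ligand.positions, ligand.charges, ligand.radii
    lig_eps = np.array([_element_eps(a.element) for a in ligand.atoms])
    out: list[tuple[str, float, float, float]] = []
    by_res: dict[tuple[str, int, str], list[int]] = {}
    for i, a in enumerate(receptor.atoms):
        by_res.setdefault((a.chain_id, a.residue_seq, a.residue_name), []).append(i)
    pos, q, radii = receptor.positions, receptor.charges, receptor.radii
    eps_r = np.array([_element_eps(a.element) for a in receptor.atoms])
    for (chain, seq, name), idxs in by_res.items():
        vdw = elec = 0.0
        for i in idxs:
            r = np.linalg.norm(lig_pos - pos[i], axis=1)
            np.maximum(r, _MIN_R, out=r)
            vdw += float(np.sum(lj_energy_pairwise(eps_r[i], lig_eps, radii[i] + lig_r, r)))
            elec += float(np.sum(coulomb_energy(q[i], 1.0, r, dielectric) * lig_q))
        out.append((f"{chain}:{name}:{seq}", vdw, elec, vdw + elec))
    return out


def lj_energy_pairwise(eps_i: float, eps_j: np.ndarray, rmin_ij: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized 12-6 LJ for one atom against an array of partners."""
    x6 = (rmin_ij / r) ** 6
    return np.sqrt(eps_i * eps_j) * (x6 * x6 - 2.0 * x6)


# ---------------------------------------------------------------------------
# OpenDX scalar-field I/O (z fastest varying, per the OpenDX standard)

def write_dx(amap: AffinityMap, path: str | Path) -> None:
    path = Path(path)
    nx, ny, nz = amap.grid.npoints
    o = amap.grid.origin
    s = amap.grid.spacing
    lines = [
        f"# OpenDX map: probe {amap.probe_name}, energies kcal/mol, cap {amap.emax_cap}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = amap.energies.ravel(order="C")  # [ix][iy][iz], z fastest = DX order
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append(f'attribute "dep" string "positions"')
    path.write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> AffinityMap:
    path = Path(path)
    counts = origin = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = None
    probe_name = "unknown"
    in_data = False
    for line in path.read_text().splitlines():
        tok = line.split()
        if not tok:
            continue
        if line.startswith("#"):
            if "probe" in tok:
                probe_name = tok[tok.index("probe") + 1].rstrip(",")
            continue
        if in_data and _is_float(tok[0]):
            values.extend(float(t) for t in tok)
            continue
        if tok[0] == "object" and "gridpositions" in tok:
            counts = tuple(int(t) for t in tok[-3:])
        elif tok[0] == "origin":
            origin = [float(t) for t in tok[1:4]]
        elif tok[0] == "delta":
            deltas.append([float(t) for t in tok[1:4]])
        elif tok[0] == "object" and "follows" in tok:
            n_items = int(tok[tok.index("items") + 1])
            in_data = True
        elif tok[0] == "attribute":
            in_data = False
    if counts is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ValueError(f"{path.name}: malformed DX header")
    if len(values) != n_items or n_items != counts[0] * counts[1] * counts[2]:
        raise ValueError(f"{path.name}: expected {n_items} values, got {len(values)}")
    spacing = deltas[0][0]
    if not (
        math.isclose(deltas[1][1], spacing, rel_tol=1e-6)
        and math.isclose(deltas[2][2], spacing, rel_tol=1e-6)
    ):
        raise ValueError(f"{path.name}: anisotropic grids are not supported")
    n = np.asarray(counts, dtype=float)
    center = np.asarray(origin) + spacing * (n - 1) / 2.0
    grid = GridSpec(center=tuple(center), npoints=counts, spacing=spacing)
    energies = np.asarray(values).reshape(counts, order="C")
    return AffinityMap(grid=grid, probe_name=probe_name, energies=energies,
                       emax_cap=float(max(energies.max(), 5.0)))


def _is_float(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True
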