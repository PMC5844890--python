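"""Cα matching, Kabsch superposition and ligand-contact inventories.

Chain correspondence is supplied explicitly (e.g. ``{"D": "B"}`` to fit
the second β-tubulin chain onto the first); Cα atoms are paired by equal
residue number and residue name, and the optimal rigid transform is the
least-squares (Kabsch) solution over all matched pairs, with no outlier
rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Atom, Structure

__all__ = [
    "PairedCoordinates",
    "SuperpositionResult",
    "ContactRecord",
    "match_ca",
    "superpose",
    "apply_transform",
    "contacts",
]


@dataclass
class PairedCoordinates:
    """Matched coordinate pairs for superposition."""

    coords_a: np.ndarray  # (n, 3) Å, moving set
    coords_b: np.ndarray  # (n, 3) Å, reference set
    labels: list[tuple[str, int, str]]  # (chain of a, residue_seq, atom name)

    def __post_init__(self) -> None:
        self.coords_a = np.asarray(self.coords_a, dtype=float)
        self.coords_b = np.asarray(self.coords_b, dtype=float)
        if self.coords_a.shape != self.coords_b.shape:
            raise ValueError("paired coordinate arrays must have equal shape")

    @property
    def n_pairs(self) -> int:
        return len(self.coords_a)


@dataclass
class SuperpositionResult:
    """Optimal rigid transform x ↦ R·x + t of set a onto set b, with RMSD."""

    rotation: np.ndarray   # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float            # Å
    n_pairs: int


@dataclass
class ContactRecord:
    """A receptor residue in contact with the ligand."""

    chain_id: str
    residue_seq: int
    residue_name: str
    min_distance: float           # Å, closest heavy-atom approach
    contact_class: str            # "hydrophobic" or "hbond"
    donor_atom: str | None = None
    acceptor_atom: str | None = None
    hbond_distance: float | None = None  # donor–acceptor heavy-atom Å
    hbond_angle: float | None = None     # D–H···A degrees, if H present


def match_ca(
    a: Structure,
    b: Structure,
    chain_map: Mapping[str, str] | None = None,
) -> PairedCoordinates:
    """Pair Cα atoms across two structures by residue number and name.

    ``chain_map`` maps chains of ``a`` onto chains of ``b``; identity over
    the shared chain ids when omitted.  Residues present in only one chain,
    or whose residue names differ (mutations), are dropped.
    """
    if chain_map is None:
        chains_a = {at.chain_id for at in a.atoms}
        chains_b = {at.chain_id for at in b.atoms}
        chain_map = {c: c for c in sorted(chains_a & chains_b)}

    def ca_index(s: Structure, chains: set[str]) -> dict[tuple[str, int], Atom]:
        out: dict[tuple[str, int], Atom] = {}
        for at in s.atoms:
            if at.name == "CA" and at.element.upper() == "C" and at.chain_id in chains:
                out.setdefault((at.chain_id, at.residue_seq), at)
        return out

    idx_a = ca_index(a, set(chain_map))
    idx_b = ca_index(b, set(chain_map.values()))
    coords_a, coords_b, labels = [], [], []
    for (chain_a, seq), at_a in idx_a.items():
        key_b = (chain_map[chain_a], seq)
        at_b = idx_b.get(key_b)
        if at_b is None or at_b.residue_name != at_a.residue_name:
            continue
        coords_a.append(at_a.position)
        coords_b.append(at_b.position)
        labels.append((chain_a, seq, "CA"))
    if len(coords_a) < 3:
        raise ValueError(f"only {len(coords_a)} Cα pairs matched; need ≥ 3")
    return PairedCoordinates(np.array(coords_a), np.array(coords_b), labels)


def superpose(pairs: PairedCoordinates) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of a onto b (Kabsch)."""
    if pairs.n_pairs < 3:
        raise ValueError("superposition needs at least 3 pairs")
    a, b = pairs.coords_a, pairs.coords_b
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # Degenerate geometry: rank of the centered moving set must be ≥ 2.
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise ValueError("collinear point set; superposition is degenerate")
    rot, _ = Rotation.align_vectors(b0, a0)
    R = rot.as_matrix()
    t = cb - R @ ca
    resid = a0 @ R.T - b0
    rmsd = float(np.sqrt((resid**2).sum() / pairs.n_pairs))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=pairs.n_pairs)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply the fitted rigid transform to an (n, 3) coordinate array."""
    return coords @ result.rotation.T + result.translation


# ---------------------------------------------------------------------------
# Contacts

_HB_ELEMENTS = {"N", "O"}


def contacts(
    receptor: Structure,
    ligand: Structure,
    cutoff: float = 4.0,
    hb_dist_max: float = 3.5,
    hb_angle_min: float = 120.0,
) -> list[ContactRecord]:
    """Inventory receptor residues within ``cutoff`` Å of the ligand.

    A residue is classed ``hbond`` when a receptor N/O and a ligand N/O lie
    within ``hb_dist_max`` Å and, when a donor hydrogen is present in the
    coordinates, the D–H···A angle is ≥ ``hb_angle_min``; otherwise the
    distance criterion alone decides (hydrogen-free crystal structures).
    Heavy atoms only enter the distance screen.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(ligand) == 0:
        raise ValueError("ligand is empty")
    lig_heavy = [a for a in ligand.atoms if a.element.upper() != "H"]
    lig_pos = np.array([a.position for a in lig_heavy])
    lig_h = [a for a in ligand.atoms if a.element.upper() == "H"]

    by_res: dict[tuple[str, int, str], list[Atom]] = {}
    for a in receptor.atoms:
        by_res.setdefault((a.chain_id, a.residue_seq, a.residue_name), []).append(a)

    records: list[ContactRecord] = []
    for (chain, seq, name), atoms in by_res.items():
        heavy = [a for a in atoms if a.element.upper() != "H"]
        if not heavy:
            continue
        pos = np.array([a.position for a in heavy])
        dmat = np.linalg.norm(pos[:, None, :] - lig_pos[None, :, :], axis=2)
        dmin = float(dmat.min())
        if dmin > cutoff:
            continue
        hb = _best_hbond(heavy, atoms, lig_heavy, lig_h, hb_dist_max, hb_angle_min)
        if hb is not None:
            rec_atom, lig_atom, dist, angle = hb
            records.append(
                ContactRecord(
                    chain_id=chain,
                    residue_seq=seq,
                    residue_name=name,
                    min_distance=dmin,
                    contact_class="hbond",
                    donor_atom=rec_atom,
                    acceptor_atom=lig_atom,
                    hbond_distance=dist,
                    hbond_angle=angle,
                )
            )
        else:
            records.append(
                ContactRecord(
                    chain_id=chain,
                    residue_seq=seq,
                    residue_name=name,
                    min_distance=dmin,
                    contact_class="hydrophobic",
                )
            )
    records.sort(key=lambda r: (r.chain_id, r.residue_seq))
    return records


def _attached_h(atom: Atom, h_atoms: Sequence[Atom], rmax: float = 1.2) -> list[Atom]:
    return [h for h in h_atoms if np.linalg.norm(h.position - atom.position) <= rmax]


def _dha_angle(donor: np.ndarray, h: np.ndarray, acceptor: np.ndarray) -> float:
    v1, v2 = donor - h, acceptor - h
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _best_hbond(rec_heavy, rec_all, lig_heavy, lig_h, dist_max, angle_min):
    """Best-scoring donor/acceptor pairing between a residue and the ligand,
    or None.  Either side may donate; geometry is checked with hydrogens
    when they are in the model."""
    rec_h = [a for a in rec_all if a.element.upper() == "H"]
    best = None
    for ra in rec_heavy:
        if ra.element.capitalize() not in _HB_ELEMENTS:
            continue
        for la in lig_heavy:
            if la.element.capitalize() not in _HB_ELEMENTS:
                continue
            d = float(np.linalg.norm(ra.position - la.position))
            if d > dist_max:
                continue
            ok_angle, angle = True, None
            hs = _attached_h(ra, rec_h) + _attached_h(la, lig_h)
            if hs:
                angles = [
                    _dha_angle(dn.position, h.position, ac.position)
                    for h in hs
                    for dn, ac in ((ra, la), (la, ra))
                    if np.linalg.norm(h.position - dn.position) <= 1.2
                ]
                angle = max(angles) if angles else None
                ok_angle = angle is None or angle >= angle_min
            if ok_angle and (best is None or d < best[2]):
                best = (ra.name, la.name, d, angle)
    return best
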