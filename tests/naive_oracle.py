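"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python loops and ``math`` only, so it
shares no code path with the vectorized implementations it checks.
"""

from __future__ import annotations

import math

COULOMB = 332.0636
ELEMENT_EPS = {"H": 0.016, "C": 0.086, "N": 0.17, "O": 0.21, "S": 0.25, "P": 0.20}
MIN_R = 1e-6


def _dist(a, b) -> float:
    return math.sqrt(sum((a[i] - b[i]) ** 2 for i in range(3)))


def _angle_deg(v1, v2) -> float:
    dot = sum(v1[i] * v2[i] for i in range(3))
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    c = max(-1.0, min(1.0, dot / (n1 * n2)))
    return math.degrees(math.acos(c))


def _hb(d: float, theta: float, emin: float, r0: float, m: int) -> float:
    if theta < 90.0:
        return 0.0
    radial = 2.0 * emin * (r0 / d) ** 6 - 3.0 * emin * (r0 / d) ** 4
    return radial * math.cos(math.radians(180.0 - theta)) ** m


def _typing(atoms):
    """(donors, acceptors) with the same chemical rules as the package:
    donor = N/O with H within 1.2 Å; acceptor = any O, or N without H;
    antecedent = nearest non-H heavy atom within 1.9 Å."""
    donors, acceptors = [], []
    for i, a in enumerate(atoms):
        el = a["element"].capitalize()
        if el not in ("N", "O"):
            continue
        hs = [
            j
            for j, b in enumerate(atoms)
            if b["element"].capitalize() == "H" and _dist(a["pos"], b["pos"]) <= 1.2
        ]
        if hs:
            donors.append((i, hs))
        ante, best = None, 1.9
        for j, b in enumerate(atoms):
            if j == i or b["element"].capitalize() == "H":
                continue
            d = _dist(a["pos"], b["pos"])
            if d < best:
                best, ante = d, j
        if el == "O" or (el == "N" and not hs):
            acceptors.append((i, ante))
    return donors, acceptors


def naive_map(
    atoms,
    probe,
    center,
    npoints,
    spacing,
    dielectric_kind="distance",
    dielectric_factor=4.0,
    emax_cap=5.0,
):
    """Per-point double loop over atoms.  ``atoms`` is a list of dicts with
    keys pos, charge, radius, element; ``probe`` is a dict with keys eps,
    rmin, charge, electrostatics, hb_donor, hb_acceptor, hb_emin, hb_r0,
    hb_m.  Returns a nested [ix][iy][iz] list, kcal/mol."""
    nx, ny, nz = npoints
    origin = [center[d] - spacing * (npoints[d] - 1) / 2.0 for d in range(3)]
    donors, acceptors = _typing(atoms)
    out = []
    for ix in range(nx):
        plane = []
        for iy in range(ny):
            row = []
            for iz in range(nz):
                p = [origin[0] + spacing * ix, origin[1] + spacing * iy, origin[2] + spacing * iz]
                e = 0.0
                for a in atoms:
                    r = max(_dist(p, a["pos"]), MIN_R)
                    eps_ij = math.sqrt(
                        ELEMENT_EPS.get(a["element"].capitalize(), 0.10) * probe["eps"]
                    )
                    rmin_ij = a["radius"] + probe["rmin"]
                    x6 = (rmin_ij / r) ** 6
                    e += eps_ij * (x6 * x6 - 2.0 * x6)
                    if probe["electrostatics"] and probe["charge"] != 0.0 and a["charge"] != 0.0:
                        epsr = dielectric_factor * r if dielectric_kind == "distance" else dielectric_factor
                        e += COULOMB * probe["charge"] * a["charge"] / (epsr * r)
                if probe["hb_donor"]:
                    for acc, ante in acceptors:
                        d = max(_dist(p, atoms[acc]["pos"]), MIN_R)
                        if ante is None:
                            theta = 180.0
                        else:
                            v1 = [atoms[ante]["pos"][k] - atoms[acc]["pos"][k] for k in range(3)]
                            v2 = [p[k] - atoms[acc]["pos"][k] for k in range(3)]
                            theta = _angle_deg(v1, v2)
                        e += _hb(d, theta, probe["hb_emin"], probe["hb_r0"], probe["hb_m"])
                if probe["hb_acceptor"]:
                    for don, hs in donors:
                        d = max(_dist(p, atoms[don]["pos"]), MIN_R)
                        best_theta = 0.0
                        for h in hs:
                            v1 = [atoms[don]["pos"][k] - atoms[h]["pos"][k] for k in range(3)]
                            v2 = [p[k] - atoms[h]["pos"][k] for k in range(3)]
                            best_theta = max(best_theta, _angle_deg(v1, v2))
                        e += _hb(d, best_theta, probe["hb_emin"], probe["hb_r0"], probe["hb_m"])
                row.append(min(e, emax_cap))
            plane.append(row)
        out.append(plane)
    return out


def solve_single_fixed_point(Tt: float, Lt: float, Kb: float, iters: int = 10000) -> float:
    """Bound concentration by damped fixed-point iteration (oracle for the
    closed-form quadratic)."""
    cb = 0.0
    for _ in range(iters):
        tf = Tt - cb
        cb_new = Lt * Kb * tf / (1.0 + Kb * tf)
        cb = 0.5 * cb + 0.5 * min(cb_new, Tt, Lt)
    return cb


def competition_scan(Tt, At, Bt, KbA, KbB, n=20_000):
    """Brute-force scan over free receptor Tf minimizing the receptor
    mass-balance residual: log-spaced coarse pass, then a linear refinement
    around the best coarse point."""

    def residual(tf):
        af = At / (1.0 + KbA * tf)
        bf = Bt / (1.0 + KbB * tf)
        return abs(tf * (1.0 + KbA * af + KbB * bf) - Tt)

    lo, hi = Tt * 1e-12, Tt
    best_tf, best_res = None, float("inf")
    for i in range(n + 1):
        tf = lo * (hi / lo) ** (i / n)
        res = residual(tf)
        if res < best_res:
            best_res, best_tf = res, tf
    step = best_tf * ((hi / lo) ** (1.0 / n) - 1.0)
    for i in range(-n // 2, n // 2 + 1):
        tf = best_tf + step * 2.0 * i / n
        if tf <= 0:
            continue
        res = residual(tf)
        if res < best_res:
            best_res, best_tf = res, tf
    return best_tf


def kabsch_svd(a, b):
    """Textbook Kabsch via numpy SVD; returns (R, t, rmsd).  Kept separate
    from the package's scipy-based route."""
    import numpy as np

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    A, B = a - ca, b - cb
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    resid = (A @ R.T) - B
    rmsd = float(np.sqrt((resid**2).sum() / len(a)))
    return R, t, rmsd
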