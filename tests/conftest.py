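from __future__ import annotations

import numpy as np
import pytest

from pocketprobe import synthetic
from pocketprobe.probes import Probe
from pocketprobe.structure import Atom, Structure


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_receptor(rng: np.random.Generator, n_atoms: int, box: float = 8.0,
                    charged: bool = True) -> Structure:
    """Random small receptor with charges/radii, for oracle comparisons."""
    elements = rng.choice(["C", "N", "O", "H", "S"], size=n_atoms)
    atoms = []
    for i in range(n_atoms):
        atoms.append(
            Atom(
                serial=i + 1,
                name=f"{elements[i]}{i + 1}",
                residue_name="RND",
                residue_seq=1 + i // 5,
                chain_id="A",
                element=str(elements[i]),
                position=rng.uniform(-box, box, 3),
                charge=float(rng.uniform(-0.5, 0.5)) if charged else 0.0,
                radius=float(rng.uniform(1.0, 2.0)),
            )
        )
    return Structure(atoms=atoms, source_format="PQR", label="random")


def structure_as_dicts(s: Structure) -> list[dict]:
    return [
        {"pos": list(map(float, a.position)), "charge": a.charge or 0.0,
         "radius": a.radius or 1.5, "element": a.element}
        for a in s.atoms
    ]


def probe_as_dict(p: Probe) -> dict:
    return {
        "eps": p.eps, "rmin": p.rmin, "charge": p.charge,
        "electrostatics": p.electrostatics, "hb_donor": p.hb_donor,
        "hb_acceptor": p.hb_acceptor, "hb_emin": p.hb_emin,
        "hb_r0": p.hb_r0, "hb_m": p.hb_m,
    }


@pytest.fixture
def toy_pocket_structure():
    return synthetic.toy_pocket(synthetic.ToyPocketSpec())
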