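"""Chemical probe definitions for affinity-map calculation.

Five probes are mapped over the binding site: a lipophilic methyl (CH3),
a hydrogen-bond acceptor carbonyl oxygen (O_ACC), a hydrogen-bond donor
ammonium (NH4), a mixed donor/acceptor hydroxyl (OH), and a hydrophobic
probe (the CH3 probe with electrostatics disabled entirely, in the spirit
of GRID's DRY probe).

The Lennard-Jones parameters (well depth ``eps`` in kcal/mol, probe
contribution ``rmin`` to the pair minimum-energy distance in Å), probe
charge, and hydrogen-bond parameters (well depth ``hb_emin``, optimal
heavy-atom separation ``hb_r0``, angular exponent ``hb_m``) are package
defaults, documented here and overridable via :func:`load_probe_file`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = ["Probe", "DEFAULT_PROBES", "get_probe", "load_probe_file"]


@dataclass(frozen=True)
class Probe:
    """Nonbonded + hydrogen-bond parameter bundle for one probe."""

    name: str
    eps: float          # LJ well depth, kcal/mol
    rmin: float         # probe contribution to pair rmin, Å
    charge: float       # e
    hb_donor: bool = False
    hb_acceptor: bool = False
    hb_emin: float = 4.0    # kcal/mol
    hb_r0: float = 2.8      # Å, heavy-atom separation at the minimum
    hb_m: int = 2           # cos^m angular exponent
    electrostatics: bool = True   # False for the DRY-like hydrophobic probe

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("eps must be ≥ 0")
        if self.rmin <= 0:
            raise ValueError("rmin must be > 0")


DEFAULT_PROBES: dict[str, Probe] = {
    "CH3": Probe("CH3", eps=0.15, rmin=2.0, charge=0.0),
    "O_ACC": Probe("O_ACC", eps=0.20, rmin=1.7, charge=0.0, hb_acceptor=True),
    "NH4": Probe("NH4", eps=0.17, rmin=1.85, charge=1.0, hb_donor=True),
    "OH": Probe("OH", eps=0.21, rmin=1.75, charge=0.0, hb_donor=True, hb_acceptor=True),
    "HYDROPHOBIC": Probe("HYDROPHOBIC", eps=0.15, rmin=2.0, charge=0.0, electrostatics=False),
}


def get_probe(name: str) -> Probe:
    """Look up a default probe by name (case-insensitive)."""
    key = name.upper()
    if key not in DEFAULT_PROBES:
        raise KeyError(f"unknown probe {name!r}; choose from {sorted(DEFAULT_PROBES)}")
    return DEFAULT_PROBES[key]


def load_probe_file(path: str | Path) -> dict[str, Probe]:
    """Load probe overrides from a JSON parameter file.

    The file maps probe names to objects with any subset of the Probe fields;
    unspecified fields fall back to the package defaults for that probe name,
    or to CH3-like neutral defaults for new names.
    """
    data = json.loads(Path(path).read_text())
    probes = dict(DEFAULT_PROBES)
    for name, fields in data.items():
        base = probes.get(name.upper(), Probe(name.upper(), eps=0.15, rmin=2.0, charge=0.0))
        unknown = set(fields) - set(base.__dataclass_fields__)
        if unknown:
            raise ValueError(f"probe {name!r}: unknown parameter(s) {sorted(unknown)}")
        probes[name.upper()] = replace(base, **fields)
    return probes
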