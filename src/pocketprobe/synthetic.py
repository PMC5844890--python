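"""Synthetic inputs: toy receptor pockets and simulated binding assays.

The toy pocket stands in for a ligand-free binding site: a ring of neutral
carbon atoms forming a cavity, optionally decorated with charged or
hydrogen-bonding feature atoms whose probe interaction field is known in
closed form, so map calculations can be checked against analytic ground
truth.

The assay simulators reproduce the study designs of the source protocols:
a fluorescence-displacement titration (0.2 µM receptor + 0.2 µM reference
ligand, competitor at 0–70 µM) and a centrifugation competition
(10 µM receptor incubated with 15 µM each of reference and test ligand,
both pre-incubation orders).  Default truths are the published constants
(reference Kb 9.1×10⁷ M⁻¹, test Kb 2.87×10⁸ M⁻¹).  Measurement noise is
multiplicative lognormal, applied independently to each measured quantity
(free and bound fractions are read from separate tube fractions).  Every
generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .equilibria import (
    DEFAULT_COMPETITOR_SERIES_UM,
    CompetitionExperiment,
    TitrationSeries,
    solve_competition,
)
from .structure import Atom, Structure

__all__ = [
    "FeatureAtom",
    "ToyPocketSpec",
    "SimulationDesign",
    "toy_pocket",
    "simulate_displacement",
    "simulate_centrifugation",
]


@dataclass(frozen=True)
class FeatureAtom:
    """A chemically meaningful atom placed inside the toy cavity."""

    element: str
    position: tuple[float, float, float]
    charge: float = 0.0
    radius: float = 1.5
    name: str | None = None  # defaults to the element symbol


@dataclass(frozen=True)
class ToyPocketSpec:
    """Ring-of-carbons cavity with optional feature atoms.

    ``shell_radius`` must exceed typical van der Waals contact distances so
    the cavity interior is accessible; the shell atoms are neutral carbons
    evenly spaced on a circle in the xy plane.
    """

    n_shell_atoms: int = 12
    shell_radius: float = 8.0
    feature_atoms: tuple[FeatureAtom, ...] = ()
    shell_charge: float = 0.0
    shell_atom_radius: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_radius <= 3.4:
            raise ValueError("shell radius must exceed van der Waals contact (~3.4 Å)")
        object.__setattr__(self, "feature_atoms", tuple(self.feature_atoms))
        for i, fa in enumerate(self.feature_atoms):
            for fb in self.feature_atoms[i + 1 :]:
                d = math.dist(fa.position, fb.position)
                if d < 1.0:
                    raise ValueError(
                        f"feature atoms at {fa.position} and {fb.position} overlap (<1 Å)"
                    )


def toy_pocket(spec: ToyPocketSpec) -> Structure:
    """Build the toy pocket Structure (PQR-like: charges and radii set).

    Deterministic for a fixed spec; the seed participates only through the
    spec hash so identical specs give byte-identical PQR output.
    """
    atoms: list[Atom] = []
    serial = 1
    for k in range(spec.n_shell_atoms):
        ang = 2.0 * math.pi * k / spec.n_shell_atoms
        pos = (spec.shell_radius * math.cos(ang), spec.shell_radius * math.sin(ang), 0.0)
        atoms.append(
            Atom(
                serial=serial,
                name="C",
                residue_name="SHL",
                residue_seq=1,
                chain_id="A",
                element="C",
                position=np.array(pos),
                charge=spec.shell_charge,
                radius=spec.shell_atom_radius,
            )
        )
        serial += 1
    for i, fa in enumerate(spec.feature_atoms, start=1):
        atoms.append(
            Atom(
                serial=serial,
                name=fa.name or fa.element.upper(),
                residue_name="FEA",
                residue_seq=1 + i,
                chain_id="A",
                element=fa.element.capitalize(),
                position=np.array(fa.position, dtype=float),
                charge=fa.charge,
                radius=fa.radius,
            )
        )
        serial += 1
    return Structure(atoms=atoms, source_format="PQR", label=f"toy_pocket_seed{spec.seed}")


@dataclass(frozen=True)
class SimulationDesign:
    """Concentration design + truths for a simulated competition assay.

    Defaults are the published centrifugation design: 10 µM receptor,
    15 µM of each ligand, reference Kb 9.1×10⁷ M⁻¹ and test ligand Kb
    2.87×10⁸ M⁻¹, lognormal noise σ = 0.10.
    """

    receptor_total: float = 10e-6         # M
    ref_total: float = 15e-6              # M
    test_total: float = 15e-6             # M
    kb_ref: float = 9.1e7                 # M⁻¹
    kb_test: float = 2.87e8               # M⁻¹
    noise_sigma: float = 0.10             # lognormal σ; 0 disables noise
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.receptor_total, self.ref_total, self.test_total) < 0:
            raise ValueError("totals must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be ≥ 0")
        if self.kb_ref <= 0 or self.kb_test <= 0:
            raise ValueError("binding constants must be positive")


def _noise(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    if sigma == 0:
        return np.ones(n)
    return rng.lognormal(mean=0.0, sigma=sigma, size=n)


def simulate_displacement(
    design: SimulationDesign,
    alpha: float = 1.0,
    beta: float = 0.2,
    gamma: float = 0.05,
    competitor_totals_uM: Sequence[float] = DEFAULT_COMPETITOR_SERIES_UM,
    receptor_total: float = 0.2e-6,
    reference_total: float = 0.2e-6,
) -> TitrationSeries:
    """Simulate a fluorescence-displacement titration.

    Intensities follow F = α·Cf_ref + β·Cb_ref + γ·F0 with (Cf, Cb) of the
    reference ligand from the two-ligand competition equilibrium at each
    competitor total; α and β are per-molar response slopes, scaled
    internally so that intensities are O(1) arbitrary units.  The
    competitor truth is ``design.kb_test``, the reference ``design.kb_ref``.
    """
    totals = np.asarray(competitor_totals_uM, dtype=float) * 1e-6
    rng = np.random.default_rng(design.seed)
    cf = np.empty(len(totals))
    cb = np.empty(len(totals))
    for i, xt in enumerate(totals):
        st = solve_competition(receptor_total, reference_total, xt, design.kb_ref, design.kb_test)
        cf[i], cb[i] = st.Cf[0], st.Cb[0]
    scale = 1.0 / max(reference_total, 1e-12)
    f = alpha * scale * cf + beta * scale * cb + gamma
    f = f * _noise(rng, design.noise_sigma, len(f))
    return TitrationSeries(
        receptor_total=receptor_total,
        reference_total=reference_total,
        competitor_totals=totals,
        intensity=f,
        label=f"sim_displacement_seed{design.seed}",
    )


def simulate_centrifugation(design: SimulationDesign) -> list[CompetitionExperiment]:
    """Simulate centrifugation competition replicates.

    Each replicate is generated in both pre-incubation orders
    (reference-first and test-first); at equilibrium the orders share the
    same state, so the order only labels the tube.  Noise multiplies each
    of the four measured concentrations independently.
    """
    rng = np.random.default_rng(design.seed)
    state = solve_competition(
        design.receptor_total,
        design.ref_total,
        design.test_total,
        design.kb_ref,
        design.kb_test,
    )
    out: list[CompetitionExperiment] = []
    for rep in range(design.replicates):
        for order in ("ref_first", "test_first"):
            nf = _noise(rng, design.noise_sigma, 4)
            out.append(
                CompetitionExperiment(
                    receptor_total=design.receptor_total,
                    ref_total=design.ref_total,
                    test_total=design.test_total,
                    Cf_ref=state.Cf[0] * nf[0],
                    Cb_ref=state.Cb[0] * nf[1],
                    Cf_test=state.Cf[1] * nf[2],
                    Cb_test=state.Cb[1] * nf[3],
                    replicate=rep,
                    order=order,
                )
            )
    return out
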