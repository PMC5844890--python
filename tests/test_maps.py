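import math

import numpy as np
import pytest

from conftest import probe_as_dict, random_receptor, structure_as_dicts
from naive_oracle import naive_map
from pocketprobe import synthetic
from pocketprobe.maps import (
    AffinityMap,
    DielectricModel,
    GridSpec,
    compute_map,
    coulomb_energy,
    find_regions,
    hbond_energy,
    lj_energy,
    read_dx,
    residue_decomposition,
    write_dx,
)
from pocketprobe.probes import DEFAULT_PROBES, Probe, get_probe
from pocketprobe.structure import Atom, Structure


def single_atom_receptor(element="C", charge=0.0, radius=1.7, pos=(0, 0, 0)):
    return Structure(atoms=[
        Atom(serial=1, name=element, residue_name="X", residue_seq=1, chain_id="A",
             element=element, position=np.array(pos, float), charge=charge, radius=radius)
    ])


class TestPairPotentials:
    def test_lj_minimum_at_rmin(self):
        assert lj_energy(0.2, 3.5, 3.5) == pytest.approx(-0.2, rel=1e-12)

    def test_lj_decays(self):
        assert abs(lj_energy(0.2, 3.5, 5 * 3.5)) < 1e-3 * 0.2

    def test_lj_against_formula(self):
        eps, rmin, r = 0.15, 3.8, 3.0
        expect = eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert lj_energy(eps, rmin, r) == pytest.approx(expect, rel=1e-12)

    def test_lj_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            lj_energy(0.1, 3.0, 0.0)

    def test_coulomb_zero_charge(self):
        assert coulomb_energy(0.0, 0.7, 2.5) == 0.0

    def test_coulomb_unit_charges_unit_distance(self):
        e = coulomb_energy(1.0, 1.0, 1.0, DielectricModel("constant", 1.0))
        assert e == pytest.approx(332.0636, rel=1e-9)

    def test_distance_dependent_dielectric_identity(self):
        r = 2.0
        e_dd = coulomb_energy(1.0, -0.5, r, DielectricModel("distance", 4.0))
        e_c1 = coulomb_energy(1.0, -0.5, r, DielectricModel("constant", 1.0))
        assert e_dd == pytest.approx(e_c1 / (4.0 * r), rel=1e-12)

    def test_hbond_minimum_by_construction(self):
        assert hbond_energy(2.8, 180.0, emin=4.0, r0=2.8) == pytest.approx(-4.0, rel=1e-12)

    def test_hbond_angular_cutoff(self):
        assert hbond_energy(2.8, 89.0) == 0.0

    def test_hbond_against_64_cos2_formula(self):
        d, theta, emin, r0, m = 3.2, 150.0, 4.0, 2.8, 2
        radial = 2 * emin * r0**6 / d**6 - 3 * emin * r0**4 / d**4
        expect = radial * math.cos(math.radians(180 - theta)) ** m
        assert hbond_energy(d, theta, emin, r0, m) == pytest.approx(expect, rel=1e-12)

    def test_hbond_rejects_bad_theta(self):
        with pytest.raises(ValueError):
            hbond_energy(2.8, 200.0)


class TestGridSpec:
    def test_default_box(self):
        g = GridSpec()
        assert g.npoints == (50, 50, 50)
        assert g.n_total == 125_000
        assert g.spacing == 0.5
        # edge length (n-1)*spacing = 24.5 Å
        ax = g.axes()[0]
        assert ax[-1] - ax[0] == pytest.approx(24.5)

    def test_point_positions_centered(self):
        g = GridSpec(center=(1.0, 2.0, 3.0), npoints=(5, 5, 5), spacing=0.5)
        assert g.point_position((2, 2, 2)) == pytest.approx([1.0, 2.0, 3.0])
        assert g.points().mean(axis=0) == pytest.approx([1.0, 2.0, 3.0])


class TestComputeMap:
    @pytest.mark.parametrize("probe_name", sorted(DEFAULT_PROBES))
    def test_matches_naive_double_loop(self, rng, probe_name):
        """Vectorized map equals pure-Python double loop for every probe."""
        probe = get_probe(probe_name)
        receptor = random_receptor(rng, 12, box=3.0)
        grid = GridSpec(center=(0.5, -0.5, 0.0), npoints=(5, 5, 5), spacing=1.0)
        amap = compute_map(receptor, probe, grid)
        ref = naive_map(structure_as_dicts(receptor), probe_as_dict(probe),
                        list(grid.center), list(grid.npoints), grid.spacing)
        assert np.asarray(ref) == pytest.approx(amap.energies, abs=1e-9)

    def test_single_atom_equals_lj_curve(self, rng):
        receptor = single_atom_receptor()
        probe = get_probe("CH3")
        grid = GridSpec(npoints=(7, 7, 7), spacing=0.8)
        amap = compute_map(receptor, probe, grid)
        pts = grid.points()
        r = np.maximum(np.linalg.norm(pts, axis=1), 1e-6)
        expect = np.minimum(
            lj_energy(math.sqrt(0.086 * probe.eps), 1.7 + probe.rmin, r), 5.0
        ).reshape(grid.npoints)
        assert amap.energies == pytest.approx(expect, abs=1e-12)

    def test_neutral_probe_ignores_charges(self, rng):
        receptor = random_receptor(rng, 15, charged=True)
        uncharged = Structure(atoms=[
            Atom(serial=a.serial, name=a.name, residue_name=a.residue_name,
                 residue_seq=a.residue_seq, chain_id=a.chain_id, element=a.element,
                 position=a.position, charge=0.0, radius=a.radius)
            for a in receptor.atoms
        ])
        grid = GridSpec(npoints=(6, 6, 6), spacing=1.0)
        probe = get_probe("CH3")
        m1 = compute_map(receptor, probe, grid)
        m2 = compute_map(uncharged, probe, grid)
        assert np.array_equal(m1.energies, m2.energies)

    def test_default_grid_has_125000_points(self, toy_pocket_structure):
        amap = compute_map(toy_pocket_structure, get_probe("CH3"), GridSpec())
        assert amap.energies.size == 125_000
        assert amap.energies.shape == (50, 50, 50)

    def test_charged_probe_needs_charges(self, tmp_path):
        pdb = tmp_path / "x.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n")
        from pocketprobe.structure import read_pdb

        with pytest.raises(ValueError, match="charges"):
            compute_map(read_pdb(pdb), get_probe("NH4"), GridSpec(npoints=(3, 3, 3)))

    def test_capping(self, rng):
        receptor = single_atom_receptor()
        amap = compute_map(receptor, get_probe("CH3"), GridSpec(npoints=(5, 5, 5), spacing=0.3))
        assert amap.energies.max() <= 5.0

    def test_translation_equivariance(self, rng):
        receptor = random_receptor(rng, 10, box=3.0)
        shift = np.array([3.0, -2.0, 1.5])
        shifted = Structure(atoms=[
            Atom(serial=a.serial, name=a.name, residue_name=a.residue_name,
                 residue_seq=a.residue_seq, chain_id=a.chain_id, element=a.element,
                 position=a.position + shift, charge=a.charge, radius=a.radius)
            for a in receptor.atoms
        ])
        probe = get_probe("OH")
        g0 = GridSpec(center=(0, 0, 0), npoints=(5, 5, 5), spacing=1.0)
        g1 = GridSpec(center=tuple(shift), npoints=(5, 5, 5), spacing=1.0)
        m0 = compute_map(receptor, probe, g0)
        m1 = compute_map(shifted, probe, g1)
        assert m0.energies == pytest.approx(m1.energies, abs=1e-9)

    def test_superposition_additivity(self, rng):
        a = random_receptor(rng, 6, box=3.0, charged=False)
        b_atoms = random_receptor(rng, 6, box=3.0, charged=False).atoms
        union = Structure(atoms=a.atoms + b_atoms)
        b = Structure(atoms=b_atoms)
        probe = get_probe("CH3")
        grid = GridSpec(npoints=(5, 5, 5), spacing=1.2)
        cap = 1e12  # effectively uncapped
        mu = compute_map(union, probe, grid, emax_cap=cap)
        ma = compute_map(a, probe, grid, emax_cap=cap)
        mb = compute_map(b, probe, grid, emax_cap=cap)
        # additivity holds wherever no component hit the cap (clash points)
        ok = (ma.energies < cap) & (mb.energies < cap) & (mu.energies < cap)
        assert ok.any()
        assert mu.energies[ok] == pytest.approx(
            (ma.energies + mb.energies)[ok], abs=1e-9, rel=1e-12
        )


class TestHbondGeometry:
    def test_nh4_minimum_along_carbonyl_axis(self):
        """For a C=O acceptor the donor-probe optimum sits anti to the C."""
        atoms = [
            Atom(serial=1, name="C", residue_name="FEA", residue_seq=1, chain_id="A",
                 element="C", position=np.array([-1.23, 0.0, 0.0]), charge=0.4, radius=1.7),
            Atom(serial=2, name="O", residue_name="FEA", residue_seq=1, chain_id="A",
                 element="O", position=np.zeros(3), charge=-0.5, radius=1.4),
        ]
        receptor = Structure(atoms=atoms)
        grid = GridSpec(center=(1.5, 0.0, 0.0), npoints=(13, 13, 13), spacing=0.5)
        amap = compute_map(receptor, get_probe("NH4"), grid)
        imin = np.unravel_index(np.argmin(amap.energies), amap.energies.shape)
        pos = amap.grid.point_position(imin)
        # off-axis displacement within one grid spacing
        assert abs(pos[1]) <= grid.spacing + 1e-9
        assert abs(pos[2]) <= grid.spacing + 1e-9
        assert pos[0] > 0  # on the far side of O from C


class TestFindRegions:
    def _flat_map(self, shape=(8, 8, 8), value=0.0):
        g = GridSpec(npoints=shape, spacing=0.5)
        return AffinityMap(grid=g, probe_name="CH3", energies=np.full(shape, value))

    def test_single_point_region(self):
        amap = self._flat_map()
        amap.energies[2, 3, 4] = -5.0
        regions = find_regions(amap, threshold=-2.5)
        assert len(regions) == 1
        assert regions[0].volume == pytest.approx(0.5**3)
        assert regions[0].min_energy == -5.0

    def test_two_separated_blobs(self):
        amap = self._flat_map()
        amap.energies[1, 1, 1] = -4.0
        amap.energies[6, 6, 6] = -3.0
        regions = find_regions(amap, threshold=-2.5)
        assert len(regions) == 2
        assert regions[0].min_energy <= regions[1].min_energy  # sorted deepest first

    def test_diagonal_points_are_26_connected(self):
        amap = self._flat_map()
        amap.energies[3, 3, 3] = -4.0
        amap.energies[4, 4, 4] = -4.0
        assert len(find_regions(amap, threshold=-2.5)) == 1

    def test_two_attractive_atoms_give_two_regions(self):
        """Two strong acceptor features 12 Å apart produce two hotspots
        centred near the feature atoms."""
        sep = 12.0
        atoms = [
            Atom(serial=i + 1, name="O", residue_name="FEA", residue_seq=i + 1,
                 chain_id="A", element="O", position=np.array(p), charge=-0.4, radius=1.4)
            for i, p in enumerate([(-sep / 2, 0, 0), (sep / 2, 0, 0)])
        ]
        receptor = Structure(atoms=atoms)
        grid = GridSpec(npoints=(41, 11, 11), spacing=0.5)
        amap = compute_map(receptor, get_probe("NH4"), grid)
        regions = find_regions(amap, threshold=amap.min_energy * 0.5)
        assert len(regions) == 2
        centers = sorted(r.min_point[0] for r in regions)
        assert abs(centers[0] - (-sep / 2)) < 3.0
        assert abs(centers[1] - sep / 2) < 3.0

    def test_empty_when_nothing_below_threshold(self):
        assert find_regions(self._flat_map(value=1.0), threshold=-2.5) == []


class TestResidueDecomposition:
    def test_conservation(self, rng):
        receptor = random_receptor(rng, 20, box=6.0)
        lig_atoms = random_receptor(rng, 5, box=2.0).atoms
        ligand = Structure(atoms=[
            Atom(serial=a.serial, name=a.name, residue_name="LIG", residue_seq=900,
                 chain_id="L", element=a.element, position=a.position + 12.0,
                 charge=a.charge, radius=a.radius) for a in lig_atoms
        ])
        rows = residue_decomposition(receptor, ligand)
        total = sum(r[3] for r in rows)
        # direct all-atom double sum
        from naive_oracle import COULOMB, ELEMENT_EPS

        direct = 0.0
        for a in receptor.atoms:
            for b in ligand.atoms:
                r = max(np.linalg.norm(a.position - b.position), 1e-6)
                eps = math.sqrt(ELEMENT_EPS.get(a.element, 0.1) * ELEMENT_EPS.get(b.element, 0.1))
                rm = a.radius + b.radius
                direct += eps * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
                direct += COULOMB * a.charge * b.charge / (4.0 * r * r)
        assert total == pytest.approx(direct, abs=1e-9)

    def test_distant_ligand_negligible(self, rng):
        receptor = random_receptor(rng, 10, box=4.0)
        far = Structure(atoms=[
            Atom(serial=1, name="C", residue_name="LIG", residue_seq=900, chain_id="L",
                 element="C", position=np.array([300.0, 0.0, 0.0]), charge=0.3, radius=1.7)
        ])
        rows = residue_decomposition(receptor, far)
        assert all(abs(r[3]) < 1e-3 for r in rows)

    def test_one_residue_receptor_equals_total(self, rng):
        receptor = random_receptor(rng, 4, box=2.0)
        for a in receptor.atoms:
            object.__setattr__(a, "residue_seq", 1)
        ligand = Structure(atoms=[
            Atom(serial=1, name="N", residue_name="LIG", residue_seq=2, chain_id="L",
                 element="N", position=np.array([5.0, 0.0, 0.0]), charge=-0.2, radius=1.6)
        ])
        rows = residue_decomposition(receptor, ligand)
        assert len(rows) == 1
        assert rows[0][3] == pytest.approx(rows[0][1] + rows[0][2], abs=1e-12)

    def test_requires_parameters(self, tmp_path):
        pdb = tmp_path / "x.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n")
        from pocketprobe.structure import read_pdb

        s = read_pdb(pdb)
        with pytest.raises(ValueError):
            residue_decomposition(s, s)


class TestDxIO:
    def test_roundtrip_random_map(self, rng, tmp_path):
        g = GridSpec(center=(1.0, -2.0, 0.5), npoints=(5, 5, 5), spacing=0.5)
        amap = AffinityMap(grid=g, probe_name="OH",
                           energies=rng.uniform(-5, 5, (5, 5, 5)))
        path = tmp_path / "m.dx"
        write_dx(amap, path)
        back = read_dx(path)
        assert back.grid.npoints == g.npoints
        assert back.grid.spacing == pytest.approx(g.spacing, abs=1e-9)
        assert np.asarray(back.grid.center) == pytest.approx(g.center, abs=1e-5)
        assert back.energies == pytest.approx(amap.energies, abs=1e-5)
        assert back.probe_name == "OH"

    def test_written_origin_convention(self, tmp_path):
        g = GridSpec(center=(0.0, 0.0, 0.0), npoints=(5, 5, 5), spacing=0.5)
        amap = AffinityMap(grid=g, probe_name="CH3", energies=np.zeros((5, 5, 5)))
        path = tmp_path / "m.dx"
        write_dx(amap, path)
        origin_line = [l for l in path.read_text().splitlines() if l.startswith("origin")][0]
        assert [float(v) for v in origin_line.split()[1:]] == pytest.approx([-1.0, -1.0, -1.0])

    def test_handwritten_dx_z_fastest(self, tmp_path):
        path = tmp_path / "tiny.dx"
        path.write_text(
            "object 1 class gridpositions counts 2 2 2\n"
            "origin 0 0 0\n"
            "delta 1 0 0\ndelta 0 1 0\ndelta 0 0 1\n"
            "object 2 class gridconnections counts 2 2 2\n"
            "object 3 class array type double rank 0 items 8 data follows\n"
            "0 1 2\n3 4 5\n6 7\n"
        )
        amap = read_dx(path)
        # z varies fastest: value at [ix, iy, iz] = 4*ix + 2*iy + iz
        assert amap.energies[1, 0, 1] == 5.0
        assert amap.energies[0, 1, 0] == 2.0

    def test_malformed_header_raises(self, tmp_path):
        path = tmp_path / "bad.dx"
        path.write_text("object 3 class array type double rank 0 items 1 data follows\n1.0\n")
        with pytest.raises(ValueError, match="malformed"):
            read_dx(path)
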