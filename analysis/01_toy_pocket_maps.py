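#!/usr/bin/env python
"""Build a toy binding pocket and map all five chemical probes over it.

Writes the receptor PQR and a hotspot table (favorable regions at the
default −2.5 kcal/mol contour, or a relative half-depth contour for
shallow probes) under results/maps/; the bulky OpenDX grids go to
scratch/maps/ for visual inspection.
"""

from pathlib import Path

from pocketprobe.maps import GridSpec, compute_map, find_regions, write_dx
from pocketprobe.probes import DEFAULT_PROBES
from pocketprobe.structure import write_pqr
from pocketprobe.synthetic import FeatureAtom, ToyPocketSpec, toy_pocket

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "maps"
DX_OUT = ROOT / "scratch" / "maps"
OUT.mkdir(parents=True, exist_ok=True)
DX_OUT.mkdir(parents=True, exist_ok=True)

# Cavity with one carbonyl-like acceptor and one ammonium-like donor feature,
# loosely emulating the polar rim of a colchicine-type pocket.
spec = ToyPocketSpec(
    n_shell_atoms=12,
    shell_radius=8.0,
    feature_atoms=(
        FeatureAtom("C", (-4.23, 0.0, 1.0), charge=0.45, radius=1.7, name="CF"),
        FeatureAtom("O", (-3.0, 0.0, 1.0), charge=-0.50, radius=1.4, name="OF"),
        FeatureAtom("N", (3.0, 0.5, -1.0), charge=0.60, radius=1.6, name="NF"),
        FeatureAtom("H", (3.6, 0.5, -0.2), charge=0.30, radius=1.0, name="HF"),
    ),
    seed=0,
)
receptor = toy_pocket(spec)
write_pqr(receptor, OUT / "toy_pocket.pqr")
print(f"receptor: {len(receptor)} atoms -> {OUT / 'toy_pocket.pqr'}")

grid = GridSpec(center=(0.0, 0.0, 0.0), npoints=(31, 31, 31), spacing=0.5)
rows = ["probe\tregion\tcx\tcy\tcz\tvolume_A3\tmin_energy_kcal"]
for name, probe in sorted(DEFAULT_PROBES.items()):
    amap = compute_map(receptor, probe, grid)
    write_dx(amap, DX_OUT / f"map_{name}.dx")
    thr = min(-2.5, amap.min_energy * 0.5)
    regions = find_regions(amap, thr)
    print(f"{name:12s} min {amap.min_energy:7.2f} kcal/mol, "
          f"{len(regions)} region(s) at {thr:.2f}")
    for i, r in enumerate(regions):
        rows.append(f"{name}\t{i}\t{r.centroid[0]:.2f}\t{r.centroid[1]:.2f}"
                    f"\t{r.centroid[2]:.2f}\t{r.volume:.2f}\t{r.min_energy:.3f}")
(OUT / "hotspots.tsv").write_text("\n".join(rows) + "\n")
print(f"hotspot table -> {OUT / 'hotspots.tsv'}")
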