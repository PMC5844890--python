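"""Pipeline configuration and stage runner behind ``pocketprobe run``.

A run is described by a TOML config (stages to execute plus per-stage
parameters); the runner executes the requested stages in order, writes
their artifacts under the output directory, and emits a machine-readable
JSON report with package version, seeds, parameters and input digests so
any run can be reproduced from its report alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__

log = logging.getLogger("pocketprobe")

_KNOWN_KEYS = {
    "stages", "output_dir", "seed", "probe_file", "dielectric", "dielectric_factor",
    "spacing", "npoints", "emax_cap", "region_threshold", "kb_ref", "noise_sigma",
    "replicates", "pqr", "probe", "center",
}


@dataclass
class RunConfig:
    """Parsed run configuration; unknown keys are rejected."""

    stages: list[str] = field(default_factory=lambda: ["simulate"])
    output_dir: Path = Path("pocketprobe_out")
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(
            stages=list(data.get("stages", ["simulate"])),
            output_dir=Path(data.get("output_dir", "pocketprobe_out")),
            seed=int(data.get("seed", 0)),
            params={k: v for k, v in data.items() if k not in ("stages", "output_dir", "seed")},
        )
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return {
            "stages": self.stages,
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            **self.params,
        }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; return (and write) the run report.

    Stage failures abort the run with the failing stage recorded; artifacts
    of completed stages are retained.
    """
    from . import equilibria, maps, probes, structure, synthetic

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": [],
        "inputs": {},
        "artifacts": [],
    }
    p = config.params

    try:
        for stage in config.stages:
            t0 = time.monotonic()
            log.info("stage %s: start", stage)
            if stage == "simulate":
                design = synthetic.SimulationDesign(
                    noise_sigma=float(p.get("noise_sigma", 0.10)),
                    replicates=int(p.get("replicates", 3)),
                    seed=config.seed,
                )
                exps = synthetic.simulate_centrifugation(design)
                path = out / "competition.csv"
                equilibria.write_competition_csv(exps, path)
                series = synthetic.simulate_displacement(design)
                spath = out / "displacement.csv"
                equilibria.write_titration_csv(series, spath)
                report["artifacts"] += [str(path), str(spath)]
            elif stage == "map":
                pqr = Path(p["pqr"]) if "pqr" in p else None
                if pqr is None:
                    spec = synthetic.ToyPocketSpec(seed=config.seed)
                    receptor = synthetic.toy_pocket(spec)
                else:
                    receptor = structure.read_pqr(pqr)
                    report["inputs"][str(pqr)] = _digest(pqr)
                probe = probes.get_probe(str(p.get("probe", "CH3")))
                center = tuple(p.get("center", (0.0, 0.0, 0.0)))
                npts = p.get("npoints", 50)
                npts = tuple(npts) if isinstance(npts, (list, tuple)) else (npts,) * 3
                grid = maps.GridSpec(center=center, npoints=npts,
                                     spacing=float(p.get("spacing", 0.5)))
                amap = maps.compute_map(receptor, probe, grid,
                                        emax_cap=float(p.get("emax_cap", 5.0)))
                path = out / f"map_{probe.name}.dx"
                maps.write_dx(amap, path)
                report["artifacts"].append(str(path))
            elif stage == "hotspots":
                dx_files = sorted(out.glob("map_*.dx"))
                if not dx_files:
                    raise FileNotFoundError("hotspots stage needs a map stage output (map_*.dx)")
                thr = float(p.get("region_threshold", -2.5))
                rows = ["probe\tregion\tcentroid_x\tcentroid_y\tcentroid_z\tvolume_A3\tmin_energy"]
                for dx in dx_files:
                    amap = maps.read_dx(dx)
                    for i, reg in enumerate(maps.find_regions(amap, thr)):
                        c = reg.centroid
                        rows.append(
                            f"{amap.probe_name}\t{i}\t{c[0]:.3f}\t{c[1]:.3f}\t{c[2]:.3f}"
                            f"\t{reg.volume:.3f}\t{reg.min_energy:.4f}"
                        )
                path = out / "hotspots.tsv"
                path.write_text("\n".join(rows) + "\n")
                report["artifacts"].append(str(path))
            elif stage == "kb":
                comp = out / "competition.csv"
                if not comp.exists():
                    raise FileNotFoundError("kb stage needs competition.csv (run simulate first)")
                exps = equilibria.read_competition_csv(comp)
                kb_ref = float(p.get("kb_ref", 9.1e7))
                est = equilibria.estimate_kb_centrifugation(exps, kb_ref)
                path = out / "kb.json"
                path.write_text(json.dumps(
                    {"kb": est.value, "sd": est.sd, "method": est.method, "n": est.n}, indent=2))
                report["artifacts"].append(str(path))
            else:
                raise ValueError(f"unknown stage {stage!r}")
            report["stages"].append({"name": stage, "seconds": round(time.monotonic() - t0, 3)})
            log.info("stage %s: done", stage)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
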