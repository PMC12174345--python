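"""End-to-end pipeline: synthesis -> detection -> statistics -> clustering
-> assembly -> occupancy, driven by a single config that round-trips
through YAML.  Every run writes its resolved config next to its outputs
and all writes are atomic."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import assembly as asm
from . import clustering, detection, spatial, synthetic
from .ioutils import atomic_write
from .particles import ParticleSet, Region
from .pdbio import model_to_pdb

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("poremap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # synthesis
    pattern: str = "glassy"
    n_particles: int = 300
    spacing: float = synthetic.DEFAULT_SPACING_NM
    jitter: float = 0.3
    region_width: float = 120.0
    region_height: float = 120.0
    seed: int = 0
    particles_csv: str | None = None  # load instead of simulating
    # rendering / detection
    detect: bool = False
    pixel_size: float = 0.5
    pore_depth: float = 1.4
    noise_sd: float = 0.1
    thresholds: tuple[float, float, float] = detection.DEFAULT_THRESHOLDS
    min_separation: float = 4.0
    # spatial statistics
    rdf: bool = True
    dr: float = 0.2
    r_max: float = 20.0
    hull_mode: str = "concave"
    dilation_radius: float = 5.0
    contexts: bool = True
    # clustering
    cluster: bool = True
    epsilon: float = clustering.DEFAULT_EPSILON_NM
    # assembly
    build_assembly: bool = False
    n_rotations: int = 64
    clash_cutoff: float = asm.DEFAULT_CLASH_CUTOFF_NM
    occupancy_resolution: float = 0.2

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        with atomic_write(path) as tmp:
            tmp.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _write_json(obj, path: Path) -> None:
    with atomic_write(path) as tmp:
        tmp.write_text(json.dumps(obj, indent=2, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the enabled stages and write reports into ``outdir``.

    Produces particles.csv, rdf.csv, contexts.json, clusters.json,
    model.pdb, occupancy_<species>.txt, config.yaml and a summary.json;
    stage failures raise :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log.info("resolved config: %s", asdict(config))
    summary: dict = {"seed": config.seed}
    region = Region(config.region_width, config.region_height)

    # --- particles -------------------------------------------------------
    try:
        if config.particles_csv:
            particles = ParticleSet.from_csv(config.particles_csv)
            particles.region = region
        else:
            particles = synthetic.generate_pattern(
                synthetic.GeneratorConfig(
                    kind=config.pattern, n_particles=config.n_particles,
                    spacing=config.spacing, jitter=config.jitter, seed=config.seed,
                ),
                region,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("particles", str(e)) from e

    if config.detect:
        try:
            image = synthetic.render_topography(
                particles, pixel_size=config.pixel_size,
                pore_depth=config.pore_depth, noise_sd=config.noise_sd,
                seed=config.seed + 1, region=region,
            )
            image.to_tiff(outdir / "topography.tif")
            particles = detection.detect_pores(
                image, thresholds=config.thresholds,
                min_separation=config.min_separation,
            )
            particles.region = region
        except Exception as e:  # noqa: BLE001
            raise PipelineError("detect", str(e)) from e
        summary["n_detected_by_tier"] = {
            t: int(np.count_nonzero(particles.tier <= t)) for t in (1, 2, 3)
        }
    particles.to_csv(outdir / "particles.csv")
    summary["n_particles"] = particles.n

    patch = None
    if config.rdf or config.contexts:
        try:
            patch = spatial.compute_patch_surface(
                particles, config.dilation_radius, config.hull_mode
            )
            summary["patch_area_nm2"] = patch.area
        except Exception as e:  # noqa: BLE001
            raise PipelineError("patch", str(e)) from e

    if config.rdf:
        try:
            rdf = spatial.compute_rdf(particles, patch, config.dr, config.r_max)
            with atomic_write(outdir / "rdf.csv") as tmp:
                rdf.to_frame().to_csv(tmp, index=False)
            summary["rdf_first_peak_nm"] = spatial.first_peak(rdf)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("rdf", str(e)) from e

    if config.contexts:
        try:
            prof = spatial.shell_occurrences(particles, patch)
            _write_json(
                {"occurrences": prof.as_dict(), "n": prof.n},
                outdir / "contexts.json",
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("contexts", str(e)) from e

    if config.cluster:
        try:
            report = clustering.cluster_particles(particles, config.epsilon)
            _write_json(report.as_dict(), outdir / "clusters.json")
            summary["f_mono"] = report.f_mono
            summary["f_clust"] = report.f_clust
            summary["n_clusters"] = report.n_clusters
            summary["mean_cluster_size"] = report.mean_cluster_size
        except Exception as e:  # noqa: BLE001
            raise PipelineError("cluster", str(e)) from e

    if config.build_assembly:
        try:
            tpl = synthetic.generate_template(seed=config.seed)
            model = asm.build_assembly(
                particles, [tpl], config.n_rotations, config.clash_cutoff,
                seed=config.seed,
            )
            asm.prune_overlapping_lipids(model)
            model_to_pdb(model, outdir / "model.pdb")
            pos, species, leaflet, _ = model.lipid_table()
            for leaf in ("cytosolic", "IMS"):
                sel = leaflet == leaf
                if not np.any(sel):
                    continue
                omap = asm.compute_occupancy_map(
                    pos[sel], species[sel], config.occupancy_resolution
                )
                for s in omap.species:
                    with atomic_write(outdir / f"occupancy_{leaf}_{s}.txt") as tmp:
                        np.savetxt(tmp, omap.enrichment(s))
            summary["n_lipids_retained"] = model.n_lipids_retained
            summary["n_lipids_pruned"] = model.n_lipids_pruned
        except Exception as e:  # noqa: BLE001
            raise PipelineError("assembly", str(e)) from e

    _write_json(summary, outdir / "summary.json")
    return summary
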