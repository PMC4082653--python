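"""End-to-end orchestration: synth -> correct -> eval.

``run_synth`` writes a complete synthetic phantom bundle (pre/post volumes,
beads, probe points, scanner clouds, ground-truth parameters).  ``run_correct``
executes the correction chain — mesh, crack from probe points, template/ICP/
CPD tracking, BC extraction, XFEM assembly and solve, crack-aware warping —
on the files of a bundle, never touching the ground truth.  ``run_eval``
scores the model-updated output against the synthetic post-retraction truth.
Every stage is deterministic under the configured seed, logs its timing and
writes a manifest with checksums; a stage whose resolved configuration and
inputs are unchanged is skipped on rerun.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic as synth
from .beads import BeadSet
from .cloud import PointCloud
from .cpd import CPDParams, cpd_nonrigid_register
from .crack import CrackGeometry, crack_from_probe
from .errors import ConfigurationError, RetractxError
from .evaluation import canny_edge_points, evaluate_beads, modified_hausdorff
from .mesh import build_hex_mesh, classify_enrichment
from .tracking import (RetractorModel, blade_contact_template, extract_contact_bcs,
                       track_blade_displacements)
from .vtkio import write_vtu
from .volume import ImageVolume, LabelVolume
from .warp import WarpConfig, warp_back_interpolate, warp_traditional
from .xfem import (MaterialParams, apply_boundary_conditions, assemble,
                   displacement_at, solve_system)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_synth", "run_correct", "run_eval", "run_all"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class BladeConfig:
    side: int = 1                 # +1 pushes the +normal hemisphere
    w_center_mm: float = 0.0
    insert_depth_mm: float = 22.0


@dataclass
class CrackConfig:
    normal: tuple = (1.0, 0.0, 0.0)
    depth_dir: tuple = (0.0, 0.0, -1.0)
    width_mm: float = 54.0
    depth_mm: float = 30.0
    mouth_origin: tuple | str = "auto"   # "auto": top of the tissue at grid center


@dataclass
class RetractionConfig:
    d_right_mm: float = 7.0
    d_left_mm: float = 6.3
    decay_radius_mm: float = 65.0
    front_taper_mm: float = 8.0
    edge_taper_mm: float = 20.0


@dataclass
class LRSConfig:
    keep_fraction: float = 0.8
    noise_sd_mm: float = 0.3
    occluded_patch_fraction: float = 0.3


@dataclass
class MeshConfig:
    element_size_mm: float = 5.0
    occupancy_threshold: float = 0.5


@dataclass
class MaterialConfig:
    E_pa: float = 3000.0
    nu: float = 0.45


@dataclass
class CPDConfig:
    beta: float = 2.0
    lam: float = 3.0
    w: float = 0.05
    max_iter: int = 120
    tol: float = 1e-6


@dataclass
class ICPConfig:
    trim_fraction: float = 0.7
    residual_threshold_mm: float = 2.0


@dataclass
class RetractorConfig:
    width_mm: float = 14.0
    length_mm: float = 60.0
    thickness_mm: float = 2.0
    pitch_mm: float = 1.5


@dataclass
class WarpSection:
    background_intensity: float = 0.0
    interpolation: str = "trilinear"
    traditional_variant: bool = False


@dataclass
class EvalConfig:
    slice_axis: int | str = "auto"
    n_slices: int = 19
    slice_range_mm: tuple | str = "auto"
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.2


@dataclass
class PhantomConfig:
    grid_shape: tuple = (128, 128, 128)
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    ellipsoid_semiaxes_mm: tuple = (55.0, 45.0, 38.0)
    n_beads: int = 23
    bead_diameter_mm: float = 1.5
    background_intensity: float = 0.0
    tissue_intensity: float = 80.0
    bead_intensity: float = 255.0
    smooth_sigma_mm: float = 1.5


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "retractx_out"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    crack: CrackConfig = field(default_factory=CrackConfig)
    retraction: RetractionConfig = field(default_factory=RetractionConfig)
    blades: list = field(default_factory=lambda: [
        BladeConfig(side=1), BladeConfig(side=-1)
    ])
    retractor: RetractorConfig = field(default_factory=RetractorConfig)
    lrs: LRSConfig = field(default_factory=LRSConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    cpd: CPDConfig = field(default_factory=CPDConfig)
    icp: ICPConfig = field(default_factory=ICPConfig)
    zero_region_height_mm: float = 8.0
    warp: WarpSection = field(default_factory=WarpSection)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    # -- (de)serialization with schema validation ---------------------------
    _SECTIONS = {
        "phantom": PhantomConfig, "crack": CrackConfig, "retraction": RetractionConfig,
        "retractor": RetractorConfig, "lrs": LRSConfig, "mesh": MeshConfig,
        "material": MaterialConfig, "cpd": CPDConfig, "icp": ICPConfig,
        "warp": WarpSection, "evaluation": EvalConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        for key, val in (d or {}).items():
            if key not in known:
                raise ConfigurationError(f"unknown config key: {key!r}")
            if key in cls._SECTIONS:
                sec_cls = cls._SECTIONS[key]
                sec_known = {f.name for f in dataclasses.fields(sec_cls)}
                extra = set(val) - sec_known
                if extra:
                    raise ConfigurationError(f"unknown keys in {key}: {sorted(extra)}")
                setattr(cfg, key, sec_cls(**val))
            elif key == "blades":
                cfg.blades = [BladeConfig(**b) for b in val]
            else:
                setattr(cfg, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, name: str, files: list, extra: dict | None = None):
    manifest = {
        "files": {f.name: _sha256(f) for f in files},
        **(extra or {}),
    }
    with open(outdir / name, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_fingerprint(section_dict: dict, input_files: list) -> str:
    payload = json.dumps(section_dict, sort_keys=True, default=str)
    payload += "".join(_sha256(Path(f)) for f in input_files)
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage_cached(outdir: Path, stage: str, fingerprint: str, outputs: list) -> bool:
    meta = outdir / f"{stage}.stage.json"
    if not meta.exists() or not all(Path(p).exists() for p in outputs):
        return False
    try:
        return json.loads(meta.read_text()).get("fingerprint") == fingerprint
    except (json.JSONDecodeError, OSError):
        return False


def _mark_stage(outdir: Path, stage: str, fingerprint: str):
    (outdir / f"{stage}.stage.json").write_text(
        json.dumps({"fingerprint": fingerprint, "time": time.time()})
    )


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0]
               % (2 ** 31))


def _resolve_crack(cfg: PipelineConfig) -> CrackGeometry:
    c = cfg.crack
    if isinstance(c.mouth_origin, str) and c.mouth_origin == "auto":
        spec_center = 0.5 * (np.asarray(cfg.phantom.grid_shape) - 1) \
            * np.asarray(cfg.phantom.voxel_size_mm)
        d = np.asarray(c.depth_dir, dtype=float)
        semi = np.asarray(cfg.phantom.ellipsoid_semiaxes_mm)
        # mouth where the depth axis leaves the ellipsoid (top of the tissue)
        t = 1.0 / np.sqrt((d ** 2 / semi ** 2).sum())
        origin = spec_center - t * d
    else:
        origin = np.asarray(c.mouth_origin, dtype=float)
    return CrackGeometry(tuple(origin), tuple(c.normal), tuple(c.depth_dir),
                         c.width_mm, c.depth_mm)


def _blade_pull(cfg: PipelineConfig, side: int) -> float:
    return cfg.retraction.d_right_mm if side > 0 else cfg.retraction.d_left_mm


def _blade_retractor(cfg: PipelineConfig, blade: BladeConfig) -> RetractorModel:
    r = cfg.retractor
    return RetractorModel(r.width_mm, blade.insert_depth_mm, r.thickness_mm, r.pitch_mm)


def _blade_tag(blade: BladeConfig) -> str:
    return "plus" if blade.side > 0 else "minus"


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_synth(cfg: PipelineConfig, outdir=None) -> dict:
    """Generate the phantom bundle; returns a dict of artifact paths."""
    outdir = Path(outdir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fp = _stage_fingerprint({"seed": cfg.seed, "phantom": dataclasses.asdict(cfg.phantom),
                             "crack": dataclasses.asdict(cfg.crack),
                             "retraction": dataclasses.asdict(cfg.retraction),
                             "blades": [dataclasses.asdict(b) for b in cfg.blades],
                             "retractor": dataclasses.asdict(cfg.retractor),
                             "lrs": dataclasses.asdict(cfg.lrs)}, [])
    paths = _synth_paths(outdir, cfg)
    if _stage_cached(outdir, "synth", fp, list(paths.values())):
        log.info("synth: cached bundle is up to date, skipping")
        return paths
    t0 = time.perf_counter()

    ph = cfg.phantom
    spec = synth.PhantomSpec(
        tuple(ph.grid_shape), tuple(ph.voxel_size_mm), tuple(ph.ellipsoid_semiaxes_mm),
        ph.n_beads, ph.bead_diameter_mm, ph.background_intensity, ph.tissue_intensity,
        ph.bead_intensity, cfg.seed, ph.smooth_sigma_mm,
    )
    pre, label, beads_pre = synth.generate_phantom_volume(spec)
    crack = _resolve_crack(cfg)
    r = cfg.retraction
    field_ = synth.analytic_retraction_field(
        crack, r.d_right_mm, r.d_left_mm, r.decay_radius_mm,
        r.front_taper_mm, r.edge_taper_mm,
    )
    post, beads_post = synth.apply_field_to_volume(
        pre, field_, crack, beads_pre, background_intensity=ph.background_intensity
    )

    pre.save(paths["pre"])
    label.save(paths["label"])
    post.save(paths["post"])
    if len(beads_pre):
        beads_pre.to_csv(paths["beads_pre"])
        beads_post.to_csv(paths["beads_post"])

    probe_rows = []
    for bi, blade in enumerate(cfg.blades):
        model = _blade_retractor(cfg, blade)
        corners = synth.simulate_probe_points(crack, model, blade.w_center_mm,
                                              blade.insert_depth_mm)
        for p in corners:
            probe_rows.append({"blade": _blade_tag(blade), "side": blade.side,
                               "x": p[0], "y": p[1], "z": p[2]})
        template = blade_contact_template(corners, model, blade.side,
                                          normal_hint=crack.n)
        pull = _blade_pull(cfg, blade.side)
        shift = blade.side * (pull - cfg.retractor.thickness_mm)
        displaced = PointCloud(template.points + shift * crack.n, template.normals,
                               labels=template.labels)
        lrs = synth.simulate_lrs_cloud(
            displaced, cfg.lrs.keep_fraction, cfg.lrs.noise_sd_mm,
            cfg.lrs.occluded_patch_fraction, seed=_child_seed(cfg.seed, 100 + bi),
        )
        lrs.to_ply(paths[f"lrs_{_blade_tag(blade)}_ply"])
        lrs.to_csv(paths[f"lrs_{_blade_tag(blade)}_csv"])
    import pandas as pd

    pd.DataFrame(probe_rows).to_csv(paths["probe"], index=False)
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump({"field": json.loads(json.dumps(field_.to_dict())),
                        "seed": cfg.seed}, fh)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    _write_manifest(outdir, "synth.manifest.json",
                    [p for p in paths.values() if Path(p).exists()])
    _mark_stage(outdir, "synth", fp)
    log.info("synth: bundle written to %s in %.1f s", outdir, time.perf_counter() - t0)
    return paths


def _synth_paths(outdir: Path, cfg: PipelineConfig) -> dict:
    paths = {
        "pre": outdir / "pre.nii.gz", "label": outdir / "label.nii.gz",
        "post": outdir / "post.nii.gz", "probe": outdir / "probe_points.csv",
        "truth": outdir / "truth.yaml",
    }
    if cfg.phantom.n_beads:
        paths["beads_pre"] = outdir / "beads_pre.csv"
        paths["beads_post"] = outdir / "beads_post.csv"
    for blade in cfg.blades:
        tag = _blade_tag(blade)
        paths[f"lrs_{tag}_ply"] = outdir / f"lrs_{tag}.ply"
        paths[f"lrs_{tag}_csv"] = outdir / f"lrs_{tag}.csv"
    return paths


def run_correct(cfg: PipelineConfig, outdir=None) -> dict:
    """Tracking -> BCs -> assemble/solve -> warp; returns artifact paths."""
    outdir = Path(outdir or cfg.output_dir)
    in_paths = _synth_paths(outdir, cfg)
    import pandas as pd

    for key in ("pre", "label", "probe"):
        if not Path(in_paths[key]).exists():
            raise RetractxError(f"correct stage: missing input file {in_paths[key]}")
    paths = {
        "updated": outdir / "updated.nii.gz",
        "solution_vtu": outdir / "solution.vtu",
        "bcs": outdir / "bcs.csv",
        "beads_model": outdir / "beads_model.csv",
        "dofs_npz": outdir / "dofs.npz",
        "dofs_csv": outdir / "dofs.csv",
        "diag": outdir / "correct_diagnostics.json",
    }
    if cfg.warp.traditional_variant:
        paths["updated_traditional"] = outdir / "updated_traditional.nii.gz"
    fp = _stage_fingerprint(
        {"mesh": dataclasses.asdict(cfg.mesh), "material": dataclasses.asdict(cfg.material),
         "cpd": dataclasses.asdict(cfg.cpd), "icp": dataclasses.asdict(cfg.icp),
         "zero": cfg.zero_region_height_mm, "warp": dataclasses.asdict(cfg.warp),
         "crack": dataclasses.asdict(cfg.crack),
         "retractor": dataclasses.asdict(cfg.retractor)},
        [in_paths["pre"], in_paths["label"], in_paths["probe"]],
    )
    if _stage_cached(outdir, "correct", fp, list(paths.values())):
        log.info("correct: cached results are up to date, skipping")
        return paths

    timings = {}

    def tic():
        return time.perf_counter()

    def stage(name, fn):
        t0 = tic()
        try:
            out = fn()
        except RetractxError as exc:
            raise RetractxError(f"correct stage [{name}]: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("correct [%s]: %.2f s", name, timings[name])
        return out

    pre = ImageVolume.load(in_paths["pre"])
    label = LabelVolume.load(in_paths["label"])
    probe = pd.read_csv(in_paths["probe"])

    mesh = stage("mesh", lambda: build_hex_mesh(label, cfg.mesh.element_size_mm,
                                                cfg.mesh.occupancy_threshold))
    crack = stage("crack", lambda: crack_from_probe(
        probe[["x", "y", "z"]].to_numpy(float), cfg.crack.width_mm, cfg.crack.depth_mm,
        depth_hint=cfg.crack.depth_dir, normal_hint=cfg.crack.normal,
    ))
    enr = stage("enrichment", lambda: classify_enrichment(mesh, crack))

    def track():
        clouds = []
        for blade in cfg.blades:
            tag = _blade_tag(blade)
            rows = probe[probe["blade"] == tag]
            if rows.empty:
                raise RetractxError(f"no probe points for blade {tag}")
            corners = rows[["x", "y", "z"]].to_numpy(float)
            model = _blade_retractor(cfg, blade)
            template = blade_contact_template(corners, model, blade.side,
                                              normal_hint=crack.n)
            lrs_path = in_paths.get(f"lrs_{tag}_csv")
            if lrs_path is None or not Path(lrs_path).exists():
                raise RetractxError(f"missing scanner cloud for blade {tag}")
            scan = PointCloud.from_csv(lrs_path)
            registered, rms = track_blade_displacements(
                template, scan,
                cpd_params=CPDParams(cfg.cpd.beta, cfg.cpd.lam, cfg.cpd.w,
                                     cfg.cpd.max_iter, cfg.cpd.tol),
                trim_fraction=cfg.icp.trim_fraction,
                fill_distance_mm=2.0 * cfg.retractor.pitch_mm,
                residual_threshold_mm=cfg.icp.residual_threshold_mm,
            )
            timings[f"icp_rms_{tag}"] = rms
            clouds.append(registered)
        return PointCloud.concatenate(clouds)

    registered = stage("tracking", track)

    zmin = label.index_to_world(np.argwhere(label.mask).min(axis=0))[2]
    depth_axis = int(np.argmax(np.abs(crack.d)))

    def zero_region(nodes):
        return nodes[:, depth_axis] <= zmin + cfg.zero_region_height_mm \
            if crack.d[depth_axis] < 0 else \
            nodes[:, depth_axis] >= zmin - cfg.zero_region_height_mm

    r_model = RetractorModel(cfg.retractor.width_mm, cfg.retractor.length_mm,
                             cfg.retractor.thickness_mm, cfg.retractor.pitch_mm)
    bcs = stage("bcs", lambda: extract_contact_bcs(
        registered, r_model, mesh, crack, zero_region, enrichment=enr))

    mat = MaterialParams(cfg.material.E_pa, cfg.material.nu)
    system = stage("assemble", lambda: assemble(mesh, enr, crack, mat))
    system = stage("constraints", lambda: apply_boundary_conditions(system, bcs))
    sol = stage("solve", lambda: solve_system(system))

    wcfg = WarpConfig(cfg.warp.background_intensity, cfg.warp.interpolation)
    updated = stage("warp", lambda: warp_back_interpolate(pre, mesh, sol, crack, wcfg))
    updated.save(paths["updated"])
    if cfg.warp.traditional_variant:
        stage("warp_traditional",
              lambda: warp_traditional(pre, mesh, sol, wcfg)).save(
                  paths["updated_traditional"])

    if "beads_pre" in in_paths and Path(in_paths["beads_pre"]).exists():
        beads_pre = BeadSet.from_csv(in_paths["beads_pre"])
        disp = displacement_at(sol, beads_pre.centers)
        beads_pre.with_centers(beads_pre.centers + disp, "model-updated").to_csv(
            paths["beads_model"])
    else:
        paths.pop("beads_model")

    bcs.to_csv(paths["bcs"])
    np.savez_compressed(paths["dofs_npz"], dofs=sol.dofs)
    pd.DataFrame({"dof": np.arange(len(sol.dofs)), "value": sol.dofs}).to_csv(
        paths["dofs_csv"], index=False)
    write_vtu(paths["solution_vtu"], mesh,
              point_data={"displacement": sol.u},
              cell_data={"cut_flag": enr.elem_type.astype(float)})
    with open(paths["diag"], "w") as fh:
        json.dump({"timings_s": timings, **sol.diagnostics,
                   "n_bc_entries": len(bcs), "n_zero_nodes": int(len(bcs.zero_nodes)),
                   "n_J": int(len(enr.set_J)), "n_M": int(len(enr.set_M)),
                   "n_nodes": mesh.n_nodes, "n_elements": mesh.n_elements}, fh, indent=2)
    _write_manifest(outdir, "correct.manifest.json",
                    [p for p in paths.values() if Path(p).exists()])
    _mark_stage(outdir, "correct", fp)
    return paths


def run_eval(cfg: PipelineConfig, outdir=None):
    """Score the model-updated bundle; returns a :class:`MetricsReport`."""
    outdir = Path(outdir or cfg.output_dir)
    in_paths = _synth_paths(outdir, cfg)
    beads_pre = BeadSet.from_csv(in_paths["beads_pre"])
    beads_post = BeadSet.from_csv(in_paths["beads_post"], space="post-retraction")
    beads_model = BeadSet.from_csv(outdir / "beads_model.csv", space="model-updated")
    report = evaluate_beads(beads_pre, beads_model, beads_post)

    pre = ImageVolume.load(in_paths["pre"])
    post = ImageVolume.load(in_paths["post"])
    updated = ImageVolume.load(outdir / "updated.nii.gz")

    ev = cfg.evaluation
    with open(in_paths["truth"]) as fh:
        truth = yaml.safe_load(fh)
    crack = CrackGeometry.from_dict(truth["field"]["crack"])
    axis = int(np.argmax(np.abs(crack.d))) if ev.slice_axis == "auto" else int(ev.slice_axis)
    if isinstance(ev.slice_range_mm, str) and ev.slice_range_mm == "auto":
        mouth = crack.o[axis]
        front = crack.front_point[axis]
        lo, hi = sorted((front, mouth))
        lo, hi = lo + 4.0, hi - 8.0
    else:
        lo, hi = ev.slice_range_mm
    positions = np.linspace(lo, hi, ev.n_slices)
    vx = pre.voxel_size[axis]
    origin = pre.affine[axis, 3]
    for pos in positions:
        idx = int(round((pos - origin) / vx))
        e_pre = canny_edge_points(pre, axis, idx, ev.canny_sigma, ev.canny_low, ev.canny_high)
        e_post = canny_edge_points(post, axis, idx, ev.canny_sigma, ev.canny_low, ev.canny_high)
        e_mod = canny_edge_points(updated, axis, idx, ev.canny_sigma, ev.canny_low,
                                  ev.canny_high)
        if min(len(e_pre), len(e_post), len(e_mod)) == 0:
            continue
        report.mhd_slices.append(
            (axis, idx, modified_hausdorff(e_pre, e_post),
             modified_hausdorff(e_mod, e_post))
        )
    report.parameters = {"slice_axis": axis, "n_slices": ev.n_slices,
                         "slice_range_mm": [float(lo), float(hi)]}
    report.to_json(outdir / "metrics.json")
    report.to_csv(outdir / "metrics.csv")
    return report


def run_all(cfg: PipelineConfig, outdir=None):
    outdir = Path(outdir or cfg.output_dir)
    run_synth(cfg, outdir)
    run_correct(cfg, outdir)
    return run_eval(cfg, outdir)
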