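"""End-to-end orchestration: phantom generation, all four reconstructions,
and the cross-modality comparison report.

The pipeline mirrors the bench protocol: one deforming ventricle drives
(a) dual-camera marker tracks reconstructed by stereo-photogrammetry
(SP), (b) a short-axis cine stack segmented slice-by-slice (CMR), and
(c) transvalvular flow curves at probe-like (dense) and PC-CMR-like
(20 phases/cycle) sampling integrated to volume.  Normalized volume
curves are then compared pairwise: CMR vs SP, SP vs flow probes, and
CMR vs PC-CMR.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as lvio
from .camera import default_rig, make_calibration_target, render_camera_images, PIN_ID
from .cine import CineSeries, reconstruct_series
from .flow import (
    ComparisonReport,
    compare_modalities,
    ejection_fraction,
    integrate_volume,
    normalize_volume,
    resample_flow_series,
)
from .geometry import default_geometry, volume_of
from .markers import place_markers
from .motion import make_phase_geometries
from .slices import SliceSpec, max_wall_speeds, render_slices
from .stereo import (
    cloud_to_volume,
    ensemble_average_cycles,
    ldlt_fit,
    mirror_cloud,
    triangulate,
)
from .waveform import (
    FlowSeries,
    VolumeSeries,
    WaveformTiming,
    derive_flows,
    make_volume_waveform,
)

__all__ = ["RunConfig", "RunResult", "run_all", "write_report", "validate_install"]

log = logging.getLogger("lvphantom")


@dataclass
class RunConfig:
    """Every knob of a phantom-to-comparison run; serializable to YAML."""

    seed: int = 0
    # physiology
    edv_ml: float = 65.0
    esv_ml: float = 31.0
    heart_rate_bpm: float = 70.0
    peak_aortic_lpm: float = 20.0
    peak_mitral_lpm: float = 17.5
    # stereo-photogrammetry
    n_sp_phases: int = 214
    n_cycles: int = 15
    marker_pitch_mm: float = 4.0
    marker_noise_px: float = 0.5
    distortion_amplitude_px: float = 2.0
    ldlt_cells: tuple[int, int, int] = (3, 3, 3)
    wall_offset_mm: float | None = None  # default: the wall thickness
    # cine
    n_cine_phases: int = 128
    n_slices: int = 15
    slice_thickness_mm: float = 6.0
    pixel_size_mm: float = 1.2
    cine_image_px: int = 64
    cine_noise_sigma: float = 0.03
    n_blurred_phases: int = 7
    # flows
    n_pc_phases: int = 20
    pc_regurgitant_fraction: float = 0.05
    # toggles
    run_sp: bool = True
    run_cine: bool = True
    motion_mode: str = "asymmetric"

    def timing(self) -> WaveformTiming:
        return WaveformTiming(
            peak_aortic_lpm=self.peak_aortic_lpm, peak_mitral_lpm=self.peak_mitral_lpm
        )

    # -- serialization ------------------------------------------------

    def save(self, path) -> Path:
        import yaml

        path = Path(path)
        d = asdict(self)
        d["ldlt_cells"] = list(self.ldlt_cells)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if "ldlt_cells" in d:
            d["ldlt_cells"] = tuple(d["ldlt_cells"])
        return cls(**d)


@dataclass
class RunResult:
    config: RunConfig
    truth_sp: VolumeSeries
    truth_cine: VolumeSeries
    sp_volumes: VolumeSeries | None
    cine: CineSeries | None
    fp_volumes: VolumeSeries
    pc_volumes: VolumeSeries
    flows_probe: FlowSeries
    flows_pc: FlowSeries
    comparisons: list[ComparisonReport]
    ef_percent: dict[str, float]
    usable_fraction: float | None
    timings_s: dict[str, float]


def _reconstruct_sp(cfg: RunConfig, geometry, v_sp: VolumeSeries) -> VolumeSeries:
    markers = place_markers(geometry, pitch=cfg.marker_pitch_mm)
    geoms = make_phase_geometries(geometry, v_sp, mode=cfg.motion_mode)
    positions = np.stack([markers.positions(g) for g in geoms])
    center = (0.0, 0.0, float(geometry.slice_z[-1]) / 2.0)
    rig = default_rig(
        target_center=center,
        distortion_amplitude_px=cfg.distortion_amplitude_px,
        seed=cfg.seed,
    )
    target = make_calibration_target(rig, seed=cfg.seed + 1)
    calib = ldlt_fit(target, cell_spec=cfg.ldlt_cells)
    tracks = render_camera_images(
        positions,
        markers.ids,
        rig,
        noise_px=cfg.marker_noise_px,
        n_cycles=cfg.n_cycles,
        pin_position=markers.pin_position,
        seed=cfg.seed + 2,
    )
    mean_tracks = ensemble_average_cycles(tracks)
    piv_tbl = mean_tracks.set_index(["marker_id", "cam", "frame"])
    cam1, cam2 = rig[0].name, rig[1].name
    # pin: averaged over cameras' triangulation across all frames
    wall_offset = cfg.wall_offset_mm if cfg.wall_offset_mm is not None else geometry.wall_thickness
    volumes = np.empty(cfg.n_sp_phases)
    pin_est = None
    for k in range(cfg.n_sp_phases):
        pts, kept_ids = [], []
        for mid in markers.ids:
            try:
                o1 = piv_tbl.loc[(mid, cam1, k)]
                o2 = piv_tbl.loc[(mid, cam2, k)]
            except KeyError:
                continue
            p, _ = triangulate((o1.x_px, o1.y_px), (o2.x_px, o2.y_px), calib, cams=(cam1, cam2))
            pts.append(p)
            kept_ids.append(mid)
        pts = np.array(pts)
        if pin_est is None:
            o1 = piv_tbl.loc[(PIN_ID, cam1, k)]
            o2 = piv_tbl.loc[(PIN_ID, cam2, k)]
            pin_est, _ = triangulate((o1.x_px, o1.y_px), (o2.x_px, o2.y_px), calib, cams=(cam1, cam2))
        cloud = mirror_cloud(pts, kept_ids, pin_est)
        volumes[k] = cloud_to_volume(
            cloud, method="slicewise", band_height=cfg.marker_pitch_mm, wall_offset=wall_offset
        )
    return VolumeSeries(times=v_sp.times.copy(), volumes=volumes, period=v_sp.period)


def run_all(config: RunConfig, out_dir=None) -> RunResult:
    """Run phantom generation and every reconstruction; fully seeded.

    Any stage failure raises with the stage name; artifacts produced up to
    that point remain in ``out_dir`` when given.
    """
    cfg = config
    timings: dict[str, float] = {}
    stage = "phantom"
    try:
        t0 = time.time()
        geometry = default_geometry(cfg.edv_ml)
        v_sp = make_volume_waveform(
            cfg.edv_ml, cfg.esv_ml, cfg.heart_rate_bpm, cfg.timing(), cfg.n_sp_phases
        )
        v_cine = make_volume_waveform(
            cfg.edv_ml, cfg.esv_ml, cfg.heart_rate_bpm, cfg.timing(), cfg.n_cine_phases
        )
        timings[stage] = time.time() - t0
        log.info("phantom ready: EDV %.1f mL (%.2f s)", volume_of(geometry), timings[stage])

        sp_vols = None
        if cfg.run_sp:
            stage = "stereo"
            t0 = time.time()
            sp_vols = _reconstruct_sp(cfg, geometry, v_sp)
            timings[stage] = time.time() - t0
            log.info("SP reconstruction done (%.2f s)", timings[stage])

        cine = None
        usable_fraction = None
        if cfg.run_cine:
            stage = "cine"
            t0 = time.time()
            geoms = make_phase_geometries(geometry, v_cine, mode=cfg.motion_mode)
            speeds = max_wall_speeds(geoms, v_cine.times)
            spec = SliceSpec(
                n_slices=cfg.n_slices,
                slice_thickness=cfg.slice_thickness_mm,
                pixel_size=cfg.pixel_size_mm,
                image_px=cfg.cine_image_px,
            )
            stack = render_slices(
                geoms,
                v_cine.times,
                spec=spec,
                wall_speeds=speeds,
                n_blurred=cfg.n_blurred_phases,
                noise_sigma=cfg.cine_noise_sigma,
                period=v_cine.period,
                seed=cfg.seed + 3,
            )
            cine = reconstruct_series(stack)
            usable_fraction = cine.usable_indices.size / stack.n_phases
            timings[stage] = time.time() - t0
            log.info(
                "cine done: %d/%d usable phases, EF %.1f%% (%.2f s)",
                cine.usable_indices.size, stack.n_phases, cine.ef_percent, timings[stage],
            )

        stage = "flows"
        t0 = time.time()
        flows_probe = derive_flows(v_sp)
        pc_times = np.linspace(0.0, v_sp.period, cfg.n_pc_phases, endpoint=False)
        flows_pc_sparse = derive_flows(
            VolumeSeries(
                times=pc_times,
                volumes=np.interp(pc_times, v_sp.times, v_sp.volumes),
                period=v_sp.period,
            ),
            regurgitant_fraction=cfg.pc_regurgitant_fraction,
        )
        # spline the 20-phase PC-CMR flows up to the probe discretization
        flows_pc = resample_flow_series(flows_pc_sparse, v_sp.times)
        esv_sp = float(np.min(sp_vols.volumes)) if sp_vols is not None else cfg.esv_ml
        esv_cine = float(np.min(cine.volumes)) if cine is not None else cfg.esv_ml
        fp_volumes = integrate_volume(flows_probe, esv_constant=esv_sp)
        pc_volumes = integrate_volume(flows_pc, esv_constant=esv_cine)
        timings[stage] = time.time() - t0

        stage = "comparison"
        t0 = time.time()
        curves = {}
        ef = {}
        if cine is not None:
            vc = VolumeSeries(times=cine.times, volumes=cine.volumes, period=cine.period)
            curves["CMR"] = normalize_volume(vc, "CMR")
            ef["CMR"] = ejection_fraction(vc)
        if sp_vols is not None:
            curves["SP"] = normalize_volume(sp_vols, "SP")
            ef["SP"] = ejection_fraction(sp_vols)
        curves["FP"] = normalize_volume(fp_volumes, "FP")
        ef["FP"] = ejection_fraction(fp_volumes)
        curves["PC-CMR"] = normalize_volume(pc_volumes, "PC-CMR")
        ef["PC-CMR"] = ejection_fraction(pc_volumes)
        pairs = [("CMR", "SP"), ("SP", "FP"), ("CMR", "PC-CMR")]
        comparisons = []
        for a, b in pairs:
            if a in curves and b in curves:
                rep = compare_modalities(curves[a], curves[b])
                rep.ef_a_percent = ef[a]
                rep.ef_b_percent = ef[b]
                comparisons.append(rep)
        timings[stage] = time.time() - t0
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    result = RunResult(
        config=cfg,
        truth_sp=v_sp,
        truth_cine=v_cine,
        sp_volumes=sp_vols,
        cine=cine,
        fp_volumes=fp_volumes,
        pc_volumes=pc_volumes,
        flows_probe=flows_probe,
        flows_pc=flows_pc,
        comparisons=comparisons,
        ef_percent=ef,
        usable_fraction=usable_fraction,
        timings_s=timings,
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def write_report(result: RunResult, out_dir, plots: bool = True) -> Path:
    """Write the JSON summary, per-curve CSVs and comparison figures."""
    if not result.comparisons:
        raise ValueError("empty comparison list; nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "ef_percent": result.ef_percent,
        "usable_phase_fraction": result.usable_fraction,
        "comparisons": [c.summary() for c in result.comparisons],
        "timings_s": result.timings_s,
        "seed": result.config.seed,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    result.config.save(out / "config.yaml")
    lvio.write_flows_csv(result.flows_probe, out / "flows_probe.csv")
    lvio.write_flows_csv(result.flows_pc, out / "flows_pccmr.csv")
    lvio.write_volumes_csv(result.fp_volumes, out / "volumes_fp.csv")
    lvio.write_volumes_csv(result.pc_volumes, out / "volumes_pccmr.csv")
    lvio.write_volumes_csv(result.truth_sp, out / "volumes_truth.csv")
    if result.sp_volumes is not None:
        lvio.write_volumes_csv(result.sp_volumes, out / "volumes_sp.csv")
    if result.cine is not None:
        lvio.write_volumes_csv(
            VolumeSeries(result.cine.times, result.cine.volumes, result.cine.period),
            out / "volumes_cine.csv",
        )
    for c in result.comparisons:
        tag = f"{c.label_a}_vs_{c.label_b}".replace(" ", "").replace("-", "").lower()
        import pandas as pd

        pd.DataFrame(
            {
                "cycle_fraction": c.fractions,
                f"vbar_{c.label_a}": c.values_a,
                f"vbar_{c.label_b}": c.values_b,
                "abs_diff_percent": c.abs_diff_percent,
            }
        ).to_csv(out / f"compare_{tag}.csv", index=False, float_format="%.17g")
    if plots:
        _plot_comparisons(result, out)
    return out


def _plot_comparisons(result: RunResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for c in result.comparisons:
        fig, (ax1, ax2) = plt.subplots(
            2, 1, figsize=(6, 5), sharex=True, height_ratios=[2, 1]
        )
        order = np.argsort(c.fractions)
        ax1.plot(c.fractions[order], c.values_a[order], "o-", ms=2, label=c.label_a)
        ax1.plot(c.fractions[order], c.values_b[order], "s-", ms=2, label=c.label_b)
        ax1.set_ylabel("normalized volume")
        ax1.legend()
        ax2.plot(c.fractions[order], c.abs_diff_percent[order], "k.-", ms=2)
        ax2.set_xlabel("cycle fraction")
        ax2.set_ylabel("|difference| (%)")
        ax2.axhline(c.mean_percent, color="r", ls="--", lw=0.8)
        fig.suptitle(
            f"{c.label_a} vs {c.label_b}: {c.mean_percent:.1f} ± {c.sd_percent:.1f} %"
        )
        fig.tight_layout()
        tag = f"{c.label_a}_vs_{c.label_b}".replace(" ", "").replace("-", "").lower()
        fig.savefig(out / f"compare_{tag}.png", dpi=120)
        plt.close(fig)


def validate_install(verbose: bool = False) -> dict[str, bool]:
    """Fast self-checks of the four measurement chains (< 2 min)."""
    from scipy import ndimage as ndi

    from .geometry import LVGeometry
    from .piv import multipass
    from .stereo import dlt_fit
    from .camera import make_camera

    checks: dict[str, bool] = {}
    # sphere volume by slice summation
    z = np.linspace(0, 40 * (1 - 1e-9), 200)
    prof = np.sqrt(np.clip(1 - ((z - 20) / 20) ** 2, 0, None))
    g = LVGeometry(z, 20 * prof, 20 * prof, np.zeros((len(z), 2)), None, 1.59)
    checks["sphere_volume"] = abs(volume_of(g) - 4 / 3 * np.pi * 8) < 0.005 * 4 / 3 * np.pi * 8
    # DLT on noiseless pinhole projections
    cam = make_camera("c", (600, 0, 35), (0, 0, 35))
    rng = np.random.default_rng(0)
    world = rng.uniform([-30, -30, 0], [30, 30, 80], (20, 3))
    uv, _ = cam.project(world)
    checks["dlt_noiseless"] = dlt_fit(world, uv).rms_px < 1e-6
    # PIV integer shift
    big = ndi.gaussian_filter(rng.uniform(0, 1, (160, 200)), 1.5)
    a, b = big[:, :160], big[:, 6:166]
    f = multipass(a, b)
    interior = (slice(1, -1), slice(1, -1))  # frame-edge windows cannot
    # gather the predictor shift and carry the usual wrap bias
    checks["piv_integer_shift"] = bool(
        np.abs(f.u[interior] + 6).max() < 0.05 and np.abs(f.v[interior]).max() < 0.05
    )
    # flow round trip
    v = make_volume_waveform()
    rec = integrate_volume(derive_flows(v), esv_constant=v.esv)
    checks["flow_round_trip"] = bool(
        np.max(np.abs(rec.volumes - v.volumes)) < 0.005 * v.edv
    )
    if verbose:
        for k, ok in checks.items():
            print(f"{'PASS' if ok else 'FAIL'}  {k}")
    return checks
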