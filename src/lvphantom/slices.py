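"""Synthetic short-axis cine slice stacks.

Renders the deforming cavity as a stack of grayscale short-axis images the
way a balanced-SSFP acquisition presents it: bright lumen, darker wall,
dark background, additive Gaussian noise.  Fifteen contiguous 6 mm slices
at 1.2 x 1.2 mm in-plane resolution cover the long axis by default.

Phases in which the wall moves fast relative to the effective temporal
window are rendered with a linear motion-blur kernel whose length grows
with wall speed, and carry a blur flag — emulating the handful of early
diastolic / peak-systolic frames in which the wall cannot be segmented.
The blur threshold is calibrated so a chosen number of phases (7 of 128
by default) is affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import LVGeometry
from .markers import outer_surface_params

__all__ = [
    "SliceSpec",
    "SliceStack",
    "render_slices",
    "max_wall_speeds",
    "calibrate_blur_threshold",
]


@dataclass(frozen=True)
class SliceSpec:
    """Acquisition geometry of the short-axis stack."""

    n_slices: int = 15
    slice_thickness: float = 6.0  # mm, no gap
    pixel_size: float = 1.2  # mm
    image_px: int = 64
    z0: float = 0.0  # mm, lower edge of the first slice
    lumen_level: float = 0.85
    wall_level: float = 0.35
    background_level: float = 0.15
    exposure_s: float = 0.1  # effective temporal window driving motion blur


@dataclass
class SliceStack:
    """Grayscale short-axis images per (slice, phase) plus acquisition meta."""

    images: np.ndarray  # (n_slices, n_phases, H, W) in [0, 1]
    slice_z: np.ndarray  # (n_slices,) mm, slice centres
    slice_thickness: float  # mm
    pixel_size: float  # mm
    phase_times: np.ndarray  # (n_phases,) s
    period: float  # s
    blur_flags: np.ndarray  # (n_phases,) bool
    wall_speed: np.ndarray  # (n_phases,) mm/s

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]

    @property
    def n_phases(self) -> int:
        return self.images.shape[1]

    def __post_init__(self) -> None:
        if self.images.min() < -1e-6 or self.images.max() > 1 + 1e-6:
            raise ValueError("pixel values must lie in [0, 1]")


def max_wall_speeds(
    geometries: list[LVGeometry],
    times: np.ndarray,
    n_theta: int = 36,
    n_z: int = 30,
) -> np.ndarray:
    """Peak outer-wall speed (mm/s) per phase.

    Tracks a fixed parametric grid of surface points through the phase
    sequence and takes the max over points of |dp/dt| by periodic central
    differences — a material-point proxy for how fast the wall sweeps
    through an imaging voxel.
    """
    times = np.asarray(times, dtype=float)
    n_ph = len(geometries)
    if n_ph != times.size:
        raise ValueError("one geometry per time sample required")
    g0 = geometries[0]
    zs = np.linspace(g0.slice_z[0], g0.slice_z[-1] * 0.98, n_z)
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    pos = np.empty((n_ph, n_z * n_theta, 2))
    for k, g in enumerate(geometries):
        a, b, cx, cy = outer_surface_params(g, zs)
        x = cx[:, None] + a[:, None] * np.cos(th)
        y = cy[:, None] + b[:, None] * np.sin(th)
        pos[k] = np.column_stack([x.ravel(), y.ravel()])
    dt = np.gradient(times)
    vel = (np.roll(pos, -1, axis=0) - np.roll(pos, 1, axis=0)) / (2 * dt[:, None, None])
    return np.linalg.norm(vel, axis=2).max(axis=1)


def calibrate_blur_threshold(wall_speeds: np.ndarray, n_blurred: int = 7) -> float:
    """Threshold flagging exactly the ``n_blurred`` fastest phases."""
    s = np.sort(np.asarray(wall_speeds, dtype=float))[::-1]
    if n_blurred <= 0:
        return float(s[0] + 1.0)
    if n_blurred >= s.size:
        return 0.0
    if s[n_blurred - 1] - s[n_blurred] < 1e-12:
        raise ValueError("speed tie at the requested flag count; cannot calibrate")
    return float((s[n_blurred - 1] + s[n_blurred]) / 2.0)


def _coverage(a, b, cx, cy, cut_line, xg, yg, supersample: int = 3):
    """Anti-aliased indicator of an (optionally cut) ellipse on the grid."""
    n = supersample
    px = xg[0, 1] - xg[0, 0]
    offs = (np.arange(n) - (n - 1) / 2) / n * px
    cov = np.zeros_like(xg)
    for ox in offs:
        for oy in offs:
            x = xg + ox
            y = yg + oy
            inside = ((x - cx) / max(a, 1e-9)) ** 2 + ((y - cy) / max(b, 1e-9)) ** 2 <= 1.0
            if cut_line is not None:
                nx, ny, c = cut_line
                inside &= nx * x + ny * y <= c
            cov += inside
    return cov / n**2


def render_slices(
    geometries: list[LVGeometry],
    times: np.ndarray,
    spec: SliceSpec | None = None,
    wall_speeds: np.ndarray | None = None,
    blur_threshold: float | None = None,
    n_blurred: int = 7,
    noise_sigma: float = 0.03,
    period: float | None = None,
    seed: int = 0,
) -> SliceStack:
    """Render the short-axis stack across all phases.

    ``blur_threshold`` defaults to the calibration that flags the
    ``n_blurred`` fastest phases.  Blurred phases are convolved with a
    45-degree line kernel of length proportional to wall speed times the
    exposure window.
    """
    spec = spec or SliceSpec()
    times = np.asarray(times, dtype=float)
    n_ph = len(geometries)
    g0 = geometries[0]
    span = spec.z0 + spec.n_slices * spec.slice_thickness
    if g0.slice_z[-1] > span + 1e-6 or g0.slice_z[0] < spec.z0 - 1e-6:
        raise ValueError(
            f"slice stack [{spec.z0}, {span}] mm does not cover the geometry "
            f"[{g0.slice_z[0]:.1f}, {g0.slice_z[-1]:.1f}] mm"
        )
    if wall_speeds is None:
        wall_speeds = max_wall_speeds(geometries, times)
    wall_speeds = np.asarray(wall_speeds, dtype=float)
    if blur_threshold is None:
        blur_threshold = calibrate_blur_threshold(wall_speeds, n_blurred)
    flags = wall_speeds > blur_threshold

    H = W = spec.image_px
    half = (W - 1) / 2.0
    xs = (np.arange(W) - half) * spec.pixel_size
    xg, yg = np.meshgrid(xs, xs)
    slice_z = spec.z0 + (np.arange(spec.n_slices) + 0.5) * spec.slice_thickness
    rng = np.random.default_rng(seed)
    images = np.empty((spec.n_slices, n_ph, H, W), dtype=np.float32)
    for k, g in enumerate(geometries):
        for s, zc in enumerate(slice_z):
            if zc <= g.slice_z[-1]:
                a, b, cx, cy = (float(v) for v in g.params_at(zc))
                ao, bo, _, _ = (float(v) for v in outer_surface_params(g, zc))
                line = g.cut_line_at(zc)
                outer = _coverage(ao, bo, cx, cy, line, xg, yg)
                lumen = _coverage(a, b, cx, cy, line, xg, yg)
            else:
                outer = lumen = np.zeros_like(xg)
            img = (
                spec.background_level
                + (spec.wall_level - spec.background_level) * outer
                + (spec.lumen_level - spec.wall_level) * lumen
            )
            if flags[k]:
                blur_px = wall_speeds[k] * spec.exposure_s / spec.pixel_size
                L = max(3, int(np.round(blur_px)))
                kern = np.eye(L) / L  # 45-degree linear motion kernel
                img = ndimage.convolve(img, kern, mode="nearest")
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma, img.shape)
            images[s, k] = np.clip(img, 0.0, 1.0)
    return SliceStack(
        images=images,
        slice_z=slice_z,
        slice_thickness=spec.slice_thickness,
        pixel_size=spec.pixel_size,
        phase_times=times,
        period=period if period is not None else float(times[-1] + (times[1] - times[0])),
        blur_flags=flags,
        wall_speed=wall_speeds,
    )
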