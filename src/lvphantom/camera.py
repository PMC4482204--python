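"""Synthetic dual-camera rig, refraction-like distortion, and marker tracks.

The true imaging model is an ideal pinhole (3x4 projection) optionally
followed by a smooth image-space displacement that depends on the world
position of the point.  The displacement stands in for the net effect of
imaging through air / acrylic / water-glycerin: it is low-order-polynomial
smooth, a few pixels at most, and exactly the kind of spatially varying
bias that localized (per-cell) DLT calibration can absorb while a single
global DLT cannot.  Ray-level refraction is deliberately not traced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerGrid

__all__ = [
    "WorldDistortion",
    "TrueCamera",
    "make_camera",
    "default_rig",
    "CalibrationTarget",
    "make_calibration_target",
    "render_camera_images",
]

PIN_ID = "pin"


@dataclass(frozen=True)
class WorldDistortion:
    """Pixel displacement as a quadratic polynomial of world position.

    Coefficients act on monomials [X^2, Y^2, Z^2, XY, XZ, YZ] of the world
    coordinates normalized to the calibration volume; the output is scaled
    so the maximum displacement over that volume is ``amplitude_px``.
    """

    coeffs: np.ndarray  # (2, 6)
    center: np.ndarray  # (3,)
    scale: np.ndarray  # (3,)
    amplitude_px: float

    @classmethod
    def random(cls, amplitude_px: float, bounds: np.ndarray, seed: int) -> "WorldDistortion":
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(size=(2, 6))
        center = bounds.mean(axis=0)
        scale = (bounds[1] - bounds[0]) / 2.0
        self = cls(coeffs=coeffs, center=center, scale=scale, amplitude_px=amplitude_px)
        # normalize to the requested max displacement over the volume
        g = np.stack(np.meshgrid(*[np.linspace(-1, 1, 9)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
        pts = self.center + g * self.scale
        mag = np.linalg.norm(self._raw(pts), axis=1).max()
        coeffs = coeffs * (amplitude_px / max(mag, 1e-12))
        return cls(coeffs=coeffs, center=center, scale=scale, amplitude_px=amplitude_px)

    def _monomials(self, pts: np.ndarray) -> np.ndarray:
        q = (np.atleast_2d(pts) - self.center) / self.scale
        x, y, z = q[:, 0], q[:, 1], q[:, 2]
        return np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z])

    def _raw(self, pts: np.ndarray) -> np.ndarray:
        return self._monomials(pts) @ self.coeffs.T

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """(n, 2) pixel displacement for world points (n, 3)."""
        return self._raw(pts)


@dataclass
class TrueCamera:
    """Ground-truth camera: pinhole projection + optional world distortion."""

    name: str
    P: np.ndarray  # (3, 4)
    image_size: tuple[int, int] = (1280, 1024)
    distortion: WorldDistortion | None = None

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points (n, 3) -> pixel coords (n, 2) and depths."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.column_stack([pts, np.ones(len(pts))]) @ self.P.T
        depth = h[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            uv = h[:, :2] / depth[:, None]
        if self.distortion is not None:
            uv = uv + self.distortion(pts)
        return uv, depth

    def in_frame(self, uv: np.ndarray, depth: np.ndarray) -> np.ndarray:
        w, hgt = self.image_size
        return (
            (depth > 0)
            & (uv[:, 0] >= 0) & (uv[:, 0] <= w - 1)
            & (uv[:, 1] >= 0) & (uv[:, 1] <= hgt - 1)
        )


def make_camera(
    name: str,
    position,
    look_at,
    up=(0.0, 0.0, 1.0),
    focal_px: float = 5000.0,
    image_size: tuple[int, int] = (1280, 1024),
    distortion: WorldDistortion | None = None,
) -> TrueCamera:
    position = np.asarray(position, dtype=float)
    fwd = np.asarray(look_at, dtype=float) - position
    fwd = fwd / np.linalg.norm(fwd)
    right = np.cross(fwd, np.asarray(up, dtype=float))
    right = right / np.linalg.norm(right)
    down = np.cross(fwd, right)
    R = np.stack([right, down, fwd])
    K = np.array(
        [
            [focal_px, 0.0, image_size[0] / 2.0],
            [0.0, focal_px, image_size[1] / 2.0],
            [0.0, 0.0, 1.0],
        ]
    )
    P = K @ np.column_stack([R, -R @ position])
    return TrueCamera(name=name, P=P, image_size=image_size, distortion=distortion)


def default_rig(
    target_center=(0.0, 0.0, 35.0),
    distance: float = 600.0,
    half_angle_deg: float = 14.0,
    focal_px: float = 5000.0,
    distortion_amplitude_px: float = 0.0,
    distortion_bounds: np.ndarray | None = None,
    seed: int = 0,
) -> list[TrueCamera]:
    """Two cameras on the +x side, converging on the marker volume."""
    center = np.asarray(target_center, dtype=float)
    cams = []
    for i, az in enumerate((-half_angle_deg, half_angle_deg)):
        azr = np.deg2rad(az)
        pos = center + distance * np.array([np.cos(azr), np.sin(azr), 0.0])
        dist = None
        if distortion_amplitude_px > 0:
            if distortion_bounds is None:
                distortion_bounds = np.array([center - 45.0, center + 45.0])
            dist = WorldDistortion.random(
                distortion_amplitude_px, np.asarray(distortion_bounds, float), seed=seed * 97 + i
            )
        cams.append(make_camera(f"cam{i + 1}", pos, center, focal_px=focal_px, distortion=dist))
    return cams


@dataclass
class CalibrationTarget:
    """Multi-plane grid target: world control points + detected pixels.

    Emulates a 1 cm grid sheet traversed along x through the chamber; the
    detected image coordinates already include the rig's distortion (that
    is the point: calibration must absorb it).
    """

    world: np.ndarray  # (n, 3) mm
    image: dict[str, np.ndarray]  # cam name -> (n, 2) px
    visible: dict[str, np.ndarray]  # cam name -> (n,) bool
    grid_pitch: float
    plane_x: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cam, uv in self.image.items():
            vis = self.visible[cam]
            for k in range(len(self.world)):
                if vis[k]:
                    rows.append(
                        dict(
                            plane_x_mm=self.world[k, 0],
                            x_mm=self.world[k, 0],
                            y_mm=self.world[k, 1],
                            z_mm=self.world[k, 2],
                            cam=cam,
                            x_px=uv[k, 0],
                            y_px=uv[k, 1],
                        )
                    )
        return pd.DataFrame(rows)


def make_calibration_target(
    cameras: list[TrueCamera],
    plane_x=np.arange(-30.0, 31.0, 10.0),
    y_range=(-35.0, 35.0),
    z_range=(-5.0, 80.0),
    grid_pitch: float = 10.0,
    noise_px: float = 0.0,
    seed: int = 0,
) -> CalibrationTarget:
    plane_x = np.asarray(plane_x, dtype=float)
    ys = np.arange(y_range[0], y_range[1] + 1e-9, grid_pitch)
    zs = np.arange(z_range[0], z_range[1] + 1e-9, grid_pitch)
    world = np.array([[x, y, z] for x in plane_x for y in ys for z in zs])
    rng = np.random.default_rng(seed)
    image, visible = {}, {}
    for cam in cameras:
        uv, depth = cam.project(world)
        if noise_px > 0:
            uv = uv + rng.normal(0.0, noise_px, uv.shape)
        image[cam.name] = uv
        visible[cam.name] = cam.in_frame(uv, depth)
    return CalibrationTarget(world=world, image=image, visible=visible, grid_pitch=grid_pitch, plane_x=plane_x)


def render_camera_images(
    marker_positions: np.ndarray,
    marker_ids: list[str],
    cameras: list[TrueCamera],
    noise_px: float = 0.5,
    n_cycles: int = 15,
    pin_position: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Project per-phase marker positions into both cameras over many cycles.

    Parameters
    ----------
    marker_positions : (n_phases, n_markers, 3) array, mm.
    noise_px : std of i.i.d. zero-mean Gaussian pixel noise, independent per
        cycle (so across-cycle averaging reduces it by 1/sqrt(n_cycles)).

    Returns
    -------
    DataFrame with columns cycle, frame, marker_id, cam, x_px, y_px.
    Markers behind a camera or outside its frame are absent for that frame.
    """
    pos = np.asarray(marker_positions, dtype=float)
    n_phases, n_mk, _ = pos.shape
    ids = list(marker_ids)
    if pin_position is not None:
        pos = np.concatenate([pos, np.broadcast_to(pin_position, (n_phases, 1, 3))], axis=1)
        ids = ids + [PIN_ID]
        n_mk += 1
    rng = np.random.default_rng(seed)
    flat = pos.reshape(-1, 3)
    frames = np.repeat(np.arange(n_phases), n_mk)
    mk_idx = np.tile(np.arange(n_mk), n_phases)
    chunks = []
    for cam in cameras:
        uv, depth = cam.project(flat)
        ok = cam.in_frame(uv, depth)
        for cyc in range(n_cycles):
            noisy = uv[ok]
            if noise_px > 0:
                noisy = noisy + rng.normal(0.0, noise_px, noisy.shape)
            chunks.append(
                pd.DataFrame(
                    {
                        "cycle": cyc,
                        "frame": frames[ok],
                        "marker_id": [ids[i] for i in mk_idx[ok]],
                        "cam": cam.name,
                        "x_px": noisy[:, 0],
                        "y_px": noisy[:, 1],
                    }
                )
            )
    return pd.concat(chunks, ignore_index=True)
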