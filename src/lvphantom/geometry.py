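"""Ground-truth left-ventricular geometry as a stack of elliptical sections.

The cavity is modeled the way the physical mold was designed: a series of
concentric ellipses stacked along the long axis (z, apex at z = 0), with a
single oblique planar cut at the base whose dihedral angle with the long
axis is 125 degrees on the outflow side.  The silicone wall is represented
as a constant in-plane offset of the cavity ellipses (default 1.59 mm).

Cross-section areas, including sections clipped by the basal cut plane, are
evaluated in closed form (elliptical-segment formula), so cavity volumes
from :func:`volume_of` are exact up to the axial trapezoidal rule.

Deformation scales the short-axis semi-axes; because the cut plane is a
material surface it is transformed consistently, which makes the cavity
volume scale exactly with the in-plane area factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BasalCut",
    "GeometryConfig",
    "LVGeometry",
    "build_geometry",
    "default_geometry",
    "volume_of",
    "deform_to_volume",
]


@dataclass(frozen=True)
class BasalCut:
    """Oriented cut plane; the cavity lies on the side n . (p - p0) <= 0."""

    point: np.ndarray  # (3,) mm
    normal: np.ndarray  # (3,) unit

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if not np.isfinite(nn) or nn < 1e-12:
            raise ValueError("cut-plane normal must be non-zero")
        object.__setattr__(self, "normal", n / nn)


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the reference (end-diastolic) cavity.

    The apex-to-base profile is a prolate ellipsoid of revolutionized
    semi-axes (a_max, b_max, long_axis/2) truncated by the basal cut; the
    dihedral convention for ``basal_cut_angle_deg`` puts the plane 35 deg
    off the transverse plane for the default 125 deg.
    """

    a_max: float = 21.0  # mm, x semi-axis at the equator
    b_max: float = 21.0  # mm, y semi-axis at the equator
    long_axis_length: float = 80.0  # mm, full ellipsoid span (<= 90)
    n_slices: int = 200
    wall_thickness: float = 1.59  # mm
    basal_cut_z: float = 64.0  # mm, where the cut plane crosses the long axis
    basal_cut_angle_deg: float = 125.0
    center_offset_amplitude: float = 0.0  # mm, lateral bowing of centers


@dataclass
class LVGeometry:
    """Stack of elliptical cross-sections truncated by a basal cut plane."""

    slice_z: np.ndarray  # (n,) mm, strictly increasing, apex first
    semi_a: np.ndarray  # (n,) mm, x semi-axis of the cavity
    semi_b: np.ndarray  # (n,) mm, y semi-axis
    centers: np.ndarray  # (n, 2) mm, in-plane centre offsets
    basal_cut: BasalCut | None = None
    wall_thickness: float = 1.59  # mm

    def __post_init__(self) -> None:
        self.slice_z = np.asarray(self.slice_z, dtype=float)
        self.semi_a = np.asarray(self.semi_a, dtype=float)
        self.semi_b = np.asarray(self.semi_b, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        n = self.slice_z.size
        if n < 2:
            raise ValueError("geometry needs at least two slices")
        if self.semi_a.shape != (n,) or self.semi_b.shape != (n,) or self.centers.shape != (n, 2):
            raise ValueError("inconsistent per-slice array shapes")
        if np.any(np.diff(self.slice_z) <= 0):
            raise ValueError("slice positions must be strictly increasing")
        if np.any(self.semi_a < 0) or np.any(self.semi_b < 0):
            raise ValueError("semi-axes must be non-negative")

    @property
    def long_axis_length(self) -> float:
        return float(self.slice_z[-1] - self.slice_z[0])

    # -- interpolated per-height cavity parameters (used by markers/slices)

    def params_at(self, z) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(a, b, cx, cy) of the cavity ellipse at height(s) z, mm."""
        z = np.asarray(z, dtype=float)
        a = np.interp(z, self.slice_z, self.semi_a)
        b = np.interp(z, self.slice_z, self.semi_b)
        cx = np.interp(z, self.slice_z, self.centers[:, 0])
        cy = np.interp(z, self.slice_z, self.centers[:, 1])
        return a, b, cx, cy

    def cut_line_at(self, z: float) -> tuple[float, float, float] | None:
        """In-plane half-space nx*x + ny*y <= c kept by the cut at height z."""
        if self.basal_cut is None:
            return None
        n = self.basal_cut.normal
        c = float(n @ self.basal_cut.point) - n[2] * float(z)
        return float(n[0]), float(n[1]), c

    def section_area(self, z) -> np.ndarray:
        """Cavity cross-section area (mm^2) at height(s) z, cut-aware."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        a, b, cx, cy = self.params_at(z)
        area = np.pi * a * b
        if self.basal_cut is not None:
            n = self.basal_cut.normal
            c = float(n @ self.basal_cut.point) - n[2] * z
            area = _ellipse_halfplane_area(a, b, cx, cy, n[0], n[1], c)
        return area


def _ellipse_halfplane_area(a, b, cx, cy, nx, ny, c) -> np.ndarray:
    """Area of {x^2/a^2 + y^2/b^2 <= 1 (centred at c)} ∩ {nx x + ny y <= c}.

    Closed form via the affine map to the unit disk: the kept region maps to
    a circular region {m . u <= d} whose area is pi - acos(d) + d sqrt(1-d^2).
    """
    a = np.atleast_1d(np.asarray(a, float))
    b = np.atleast_1d(np.asarray(b, float))
    full = np.pi * a * b
    rim = np.hypot(nx * a, ny * b)
    margin = np.asarray(c) - (nx * np.asarray(cx) + ny * np.asarray(cy))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(rim > 1e-12, margin / np.maximum(rim, 1e-300), np.where(margin >= 0, 1.0, -1.0))
    d = np.clip(d, -1.0, 1.0)
    frac = (np.pi - np.arccos(d) + d * np.sqrt(1.0 - d * d)) / np.pi
    return full * frac


def build_geometry(config: GeometryConfig | None = None) -> LVGeometry:
    """Construct the reference ellipse-stack geometry from a config.

    The stack samples the ellipsoidal profile on ``n_slices`` heights from
    the apex to the top of the ellipsoid; sections above the basal cut have
    zero area and do not contribute to the volume.
    """
    cfg = config or GeometryConfig()
    if cfg.a_max <= 0 or cfg.b_max <= 0 or cfg.long_axis_length <= 0:
        raise ValueError("semi-axes and long-axis length must be positive")
    if not 0 < cfg.basal_cut_z < cfg.long_axis_length:
        raise ValueError("basal cut plane misses the geometry")
    half = cfg.long_axis_length / 2.0
    z = np.linspace(0.0, cfg.long_axis_length * (1 - 1e-9), cfg.n_slices)
    profile = np.sqrt(np.clip(1.0 - ((z - half) / half) ** 2, 0.0, None))
    cx = cfg.center_offset_amplitude * np.sin(np.pi * z / cfg.long_axis_length)
    centers = np.column_stack([cx, np.zeros_like(z)])
    # plane tilted (angle - 90) deg from the transverse plane, within the
    # x = 0 symmetry plane so the cut respects the mirror assumption
    tilt = np.deg2rad(cfg.basal_cut_angle_deg - 90.0)
    cut = BasalCut(
        point=np.array([0.0, 0.0, cfg.basal_cut_z]),
        normal=np.array([0.0, np.sin(tilt), np.cos(tilt)]),
    )
    return LVGeometry(
        slice_z=z,
        semi_a=cfg.a_max * profile,
        semi_b=cfg.b_max * profile,
        centers=centers,
        basal_cut=cut,
        wall_thickness=cfg.wall_thickness,
    )


def volume_of(geometry: LVGeometry) -> float:
    """Cavity volume in mL: per-slice ellipse area x spacing (trapezoidal).

    Sections clipped by the basal cut use the exact elliptical-segment area.
    """
    areas = geometry.section_area(geometry.slice_z)
    if geometry.long_axis_length <= 0 or not np.any(areas > 0):
        raise ValueError("degenerate geometry: no positive cross-section")
    return float(np.trapezoid(areas, geometry.slice_z)) / 1000.0


def scale_inplane(geometry: LVGeometry, sx: float, sy: float) -> LVGeometry:
    """Material scaling (x, y, z) -> (sx x, sy y, z), cut plane included."""
    if sx <= 0 or sy <= 0:
        raise ValueError("scale factors must be positive")
    cut = geometry.basal_cut
    if cut is not None:
        n = cut.normal
        cut = BasalCut(
            point=np.array([sx * cut.point[0], sy * cut.point[1], cut.point[2]]),
            normal=np.array([n[0] / sx, n[1] / sy, n[2]]),
        )
    return LVGeometry(
        slice_z=geometry.slice_z.copy(),
        semi_a=geometry.semi_a * sx,
        semi_b=geometry.semi_b * sy,
        centers=geometry.centers * np.array([sx, sy]),
        basal_cut=cut,
        wall_thickness=geometry.wall_thickness,
    )


def deform_to_volume(
    geometry: LVGeometry,
    target_volume: float,
    mode: str = "uniform",
    asymmetry: float = 1.08,
) -> LVGeometry:
    """Scale the short-axis semi-axes so the cavity volume hits a target.

    ``uniform`` applies one factor s to both semi-axes; ``asymmetric``
    applies s*asymmetry to x and s/asymmetry to y, which leaves the area
    factor (and hence the volume) identical while the wall excursion
    differs by direction — emulating the uneven anterior/inferior versus
    lateral/septal contraction of the physical model.

    Because the cut plane is transformed as a material surface, volume
    scales exactly as s^2 and the direct solution suffices; a bisection
    polish guards the non-exact case (tolerance 0.1 %).
    """
    if target_volume <= 0:
        raise ValueError("target volume must be positive")
    if mode not in ("uniform", "asymmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    v0 = volume_of(geometry)
    s = float(np.sqrt(target_volume / v0))
    k = float(asymmetry) if mode == "asymmetric" else 1.0

    def make(scale: float) -> LVGeometry:
        return scale_inplane(geometry, scale * k, scale / k)

    out = make(s)
    v = volume_of(out)
    if abs(v - target_volume) > 1e-3 * target_volume:
        from scipy.optimize import brentq

        lo, hi = 0.2 * s, 5.0 * s
        f = lambda m: volume_of(make(m)) - target_volume
        if f(lo) * f(hi) > 0:
            raise RuntimeError(
                f"volume solve failed: target {target_volume} mL not bracketed "
                f"by scales [{lo:.3f}, {hi:.3f}] (got {v:.3f} mL at s={s:.3f})"
            )
        s = brentq(f, lo, hi, xtol=1e-8)
        out = make(s)
        v = volume_of(out)
        if abs(v - target_volume) > 1e-3 * target_volume:
            raise RuntimeError(f"volume solve did not converge: {v:.4f} vs {target_volume}")
    return out


def default_geometry(edv: float = 65.0, config: GeometryConfig | None = None) -> LVGeometry:
    """Reference geometry scaled so the cavity volume equals the EDV."""
    return deform_to_volume(build_geometry(config), edv, mode="uniform")
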