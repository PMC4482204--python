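"""Stereo-photogrammetric reconstruction: DLT/LDLT calibration,
triangulation, cycle ensemble averaging, mirroring, and volumetry.

The camera model is the standard 11-parameter direct linear transformation
(DLT).  The localized variant (LDLT) tiles the calibration volume into
rectangular cells and fits an independent 11-parameter set per cell per
camera; at query time the cell containing the reconstructed point supplies
the coefficients, which lets piecewise-linear models absorb the smooth
refraction-like distortion that a single global DLT cannot.

Volumes come from the mirrored point cloud either by slicewise ellipse
fitting (default, consistent with how the mold was designed) or by convex
hull.  Slicewise fitting is cut-aware: a ring whose points span only part
of the circumference (because the basal cut removed the rest) is clipped
by the chord between the arc end points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel

__all__ = [
    "DLTCoefficients",
    "CameraCalibration",
    "ReconstructedCloud",
    "dlt_fit",
    "dlt_project",
    "ldlt_fit",
    "triangulate",
    "triangulate_many",
    "ensemble_average_cycles",
    "mirror_cloud",
    "cloud_to_volume",
]


# ---------------------------------------------------------------- DLT core


@dataclass
class DLTCoefficients:
    L: np.ndarray  # (11,)
    rms_px: float
    n_points: int


def _dlt_design(world: np.ndarray, image: np.ndarray):
    X, Y, Z = world[:, 0], world[:, 1], world[:, 2]
    u, v = image[:, 0], image[:, 1]
    n = len(world)
    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    A[0::2, 0:3] = world
    A[0::2, 3] = 1.0
    A[0::2, 8:11] = -u[:, None] * world
    A[1::2, 4:7] = world
    A[1::2, 7] = 1.0
    A[1::2, 8:11] = -v[:, None] * world
    b[0::2] = u
    b[1::2] = v
    return A, b


def _check_noncoplanar(world: np.ndarray) -> None:
    c = world - world.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[-1] < 1e-6 * max(s[0], 1.0):
        raise ValueError(
            "calibration points are (nearly) coplanar: the 11-parameter DLT "
            "system is rank deficient; supply points spanning a volume"
        )


def dlt_fit(world_points: np.ndarray, image_points: np.ndarray) -> DLTCoefficients:
    """Least-squares fit of the 11 DLT coefficients.

    u = (L1 X + L2 Y + L3 Z + L4) / (L9 X + L10 Y + L11 Z + 1), likewise v
    with L5..L8.  Requires >= 6 points that are not all coplanar.
    """
    world = np.asarray(world_points, dtype=float)
    image = np.asarray(image_points, dtype=float)
    if world.ndim != 2 or world.shape[1] != 3 or image.shape != (len(world), 2):
        raise ValueError("expected world (n,3) and image (n,2) arrays")
    if len(world) < 6:
        raise ValueError(f"DLT needs at least 6 control points, got {len(world)}")
    _check_noncoplanar(world)
    # normalize world coordinates for conditioning, then de-normalize
    c = world.mean(axis=0)
    s = world.std(axis=0)
    s[s < 1e-9] = 1.0
    wn = (world - c) / s
    A, b = _dlt_design(wn, image)
    Ln, *_ = np.linalg.lstsq(A, b, rcond=None)
    # map back: the DLT is projective-linear in world coords
    M = np.vstack([Ln[0:4], Ln[4:8], np.append(Ln[8:11], 1.0)])  # (3,4) on normalized
    T = np.eye(4)
    T[:3, :3] = np.diag(1.0 / s)
    T[:3, 3] = -c / s
    Mw = M @ T
    Mw = Mw / Mw[2, 3]
    L = np.concatenate([Mw[0], Mw[1], Mw[2, :3]])
    resid = dlt_project(L, world) - image
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return DLTCoefficients(L=L, rms_px=rms, n_points=len(world))


def dlt_project(L: np.ndarray, world: np.ndarray) -> np.ndarray:
    """Reproject world points (n,3) through 11 DLT coefficients -> (n,2)."""
    w = np.atleast_2d(np.asarray(world, dtype=float))
    den = w @ L[8:11] + 1.0
    u = (w @ L[0:3] + L[3]) / den
    v = (w @ L[4:7] + L[7]) / den
    return np.column_stack([u, v])


# ------------------------------------------------------------- calibration


@dataclass
class CameraCalibration:
    """Global or localized DLT calibration for a set of cameras."""

    mode: str  # 'global' | 'localized'
    image_size: tuple[int, int]
    global_coeffs: dict[str, DLTCoefficients]
    cell_origin: np.ndarray | None = None  # (3,)
    cell_size: np.ndarray | None = None  # (3,)
    cell_shape: tuple[int, int, int] | None = None
    local_coeffs: dict[str, list[DLTCoefficients]] | None = None

    @property
    def camera_names(self) -> list[str]:
        return list(self.global_coeffs)

    def n_cells(self) -> int:
        return int(np.prod(self.cell_shape)) if self.cell_shape else 1

    def cell_index(self, point: np.ndarray) -> int:
        """Cell containing a world point; points outside clamp to the edge.

        On an exact cell boundary the floor rule assigns the higher cell,
        which coincides with the nearest-centre rule there; ties cannot
        occur off the lattice, so the assignment is deterministic.
        """
        idx = np.floor((np.asarray(point) - self.cell_origin) / self.cell_size).astype(int)
        idx = np.clip(idx, 0, np.array(self.cell_shape) - 1)
        return int(np.ravel_multi_index(tuple(idx), self.cell_shape))

    def coeffs_for(self, cam: str, point: np.ndarray | None = None) -> DLTCoefficients:
        if self.mode == "global" or point is None:
            return self.global_coeffs[cam]
        return self.local_coeffs[cam][self.cell_index(point)]


def calibrate_global(target) -> CameraCalibration:
    """Single 11-parameter DLT per camera over the whole target."""
    coeffs = {}
    for cam, uv in target.image.items():
        vis = target.visible[cam]
        coeffs[cam] = dlt_fit(target.world[vis], uv[vis])
    return CameraCalibration(mode="global", image_size=(0, 0), global_coeffs=coeffs)


def ldlt_fit(
    target,
    cell_spec: tuple[int, int, int] = (3, 3, 3),
    margin: float = 0.35,
) -> CameraCalibration:
    """Localized DLT: per-cell 11-parameter fits over a cell decomposition.

    Each cell is fit from the control points inside the cell expanded by
    ``margin`` x cell size on every face (points near boundaries are shared
    between neighbouring cells, which keeps every cell over-determined and
    the piecewise model continuous in practice).  A cell with fewer than 6
    usable points, or with all points coplanar, is an error naming the cell.
    """
    cal = calibrate_global(target)
    vis_any = np.zeros(len(target.world), dtype=bool)
    for cam in target.image:
        vis_any |= target.visible[cam]
    world = target.world
    lo = world[vis_any].min(axis=0)
    hi = world[vis_any].max(axis=0)
    shape = tuple(int(n) for n in cell_spec)
    size = (hi - lo) / np.array(shape)
    size[size <= 0] = 1.0
    local: dict[str, list[DLTCoefficients]] = {cam: [] for cam in target.image}
    for cell in range(int(np.prod(shape))):
        idx = np.array(np.unravel_index(cell, shape))
        c_lo = lo + idx * size - margin * size
        c_hi = lo + (idx + 1) * size + margin * size
        inside = np.all((world >= c_lo) & (world <= c_hi), axis=1)
        for cam, uv in target.image.items():
            sel = inside & target.visible[cam]
            if sel.sum() < 6:
                raise ValueError(
                    f"LDLT cell {tuple(idx)} has only {int(sel.sum())} usable "
                    f"points for {cam}; coarsen the cells or widen the margin"
                )
            try:
                local[cam].append(dlt_fit(world[sel], uv[sel]))
            except ValueError as e:
                raise ValueError(f"LDLT cell {tuple(idx)} ({cam}): {e}") from e
    return CameraCalibration(
        mode="localized",
        image_size=(0, 0),
        global_coeffs=cal.global_coeffs,
        cell_origin=lo,
        cell_size=size,
        cell_shape=shape,
        local_coeffs=local,
    )


# ----------------------------------------------------------- triangulation


def _triangulate_linear(obs: list[np.ndarray], Ls: list[np.ndarray]):
    A = np.empty((2 * len(obs), 3))
    b = np.empty(2 * len(obs))
    for k, (uv, L) in enumerate(zip(obs, Ls)):
        u, v = uv
        A[2 * k] = L[0:3] - u * L[8:11]
        b[2 * k] = u - L[3]
        A[2 * k + 1] = L[4:7] - v * L[8:11]
        b[2 * k + 1] = v - L[7]
    X, *_ = np.linalg.lstsq(A, b, rcond=None)
    return X


def triangulate(
    obs_cam1,
    obs_cam2,
    calib: CameraCalibration,
    cams: tuple[str, str] | None = None,
    max_cell_iter: int = 5,
) -> tuple[np.ndarray, float]:
    """Two-view linear triangulation -> (world point mm, reprojection RMS px).

    In localized mode the cell is selected by the current solution and the
    triangulation repeated until the chosen cell contains it (at most
    ``max_cell_iter`` rounds); non-convergence falls back to the global fit
    with a warning.
    """
    if obs_cam1 is None or obs_cam2 is None:
        raise ValueError("both camera observations are required")
    cams = cams or tuple(calib.camera_names[:2])
    obs = [np.asarray(obs_cam1, dtype=float), np.asarray(obs_cam2, dtype=float)]
    Ls = [calib.global_coeffs[c].L for c in cams]
    X = _triangulate_linear(obs, Ls)
    if calib.mode == "localized":
        cell = calib.cell_index(X)
        converged = False
        seen = {cell}
        for _ in range(max_cell_iter):
            Ls = [calib.local_coeffs[c][cell].L for c in cams]
            X = _triangulate_linear(obs, Ls)
            new_cell = calib.cell_index(X)
            if new_cell == cell:
                converged = True
                break
            if new_cell in seen:
                # oscillation across a cell boundary: the neighbouring fits
                # overlap there; settle on the cell whose centre is nearest
                idx = np.array(np.unravel_index(new_cell, calib.cell_shape))
                ctr_new = calib.cell_origin + (idx + 0.5) * calib.cell_size
                idx_old = np.array(np.unravel_index(cell, calib.cell_shape))
                ctr_old = calib.cell_origin + (idx_old + 0.5) * calib.cell_size
                cell = (
                    new_cell
                    if np.linalg.norm(X - ctr_new) <= np.linalg.norm(X - ctr_old)
                    else cell
                )
                Ls = [calib.local_coeffs[c][cell].L for c in cams]
                X = _triangulate_linear(obs, Ls)
                converged = True
                break
            seen.add(new_cell)
            cell = new_cell
        if not converged:
            warnings.warn("LDLT cell selection did not settle; using global DLT", stacklevel=2)
            Ls = [calib.global_coeffs[c].L for c in cams]
            X = _triangulate_linear(obs, Ls)
    resid = [dlt_project(L, X[None])[0] - uv for L, uv in zip(Ls, obs)]
    rms = float(np.sqrt(np.mean(np.concatenate(resid) ** 2)))
    return X, rms


def triangulate_many(uv1: np.ndarray, uv2: np.ndarray, calib: CameraCalibration, cams=None):
    """Triangulate n correspondences; returns (n,3) points and (n,) RMS."""
    uv1 = np.atleast_2d(uv1)
    uv2 = np.atleast_2d(uv2)
    pts = np.empty((len(uv1), 3))
    rms = np.empty(len(uv1))
    for i in range(len(uv1)):
        pts[i], rms[i] = triangulate(uv1[i], uv2[i], calib, cams=cams)
    return pts, rms


# ------------------------------------------------- cycles, mirror, volume


def ensemble_average_cycles(tracks: pd.DataFrame) -> pd.DataFrame:
    """Average per-marker pixel trajectories over cycles into one cycle.

    Input columns: cycle, frame, marker_id, cam, x_px, y_px.  Missing
    samples are simply absent rows and are excluded from the mean; the
    output carries the contributing-cycle count per sample in ``n_cycles``.
    A marker absent in *all* cycles at a frame yields no output row (a gap).
    """
    required = {"cycle", "frame", "marker_id", "cam", "x_px", "y_px"}
    if not required.issubset(tracks.columns):
        raise ValueError(f"tracks must have columns {sorted(required)}")
    g = tracks.groupby(["marker_id", "cam", "frame"], sort=True)
    out = g.agg(x_px=("x_px", "mean"), y_px=("y_px", "mean"), n_cycles=("cycle", "size"))
    return out.reset_index()


@dataclass
class ReconstructedCloud:
    """Per-phase 3D points with marker identities and mirror bookkeeping."""

    points: np.ndarray  # (n, 3) mm
    ids: list[str]
    pin: np.ndarray  # (3,) mm
    mirrored: np.ndarray  # (n,) bool
    plane_normal: np.ndarray  # (3,) unit


def mirror_cloud(points: np.ndarray, ids: list[str], pin, plane_normal=(1.0, 0.0, 0.0)) -> ReconstructedCloud:
    """Union of the points and their reflections across the symmetry plane.

    The plane passes through the stationary pin with the given unit normal;
    the pin (and any point on the plane) maps to itself.
    """
    n = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(n)
    if not np.isclose(nn, 1.0, atol=1e-6):
        raise ValueError("plane normal must be a unit vector")
    n = n / nn
    pin = np.asarray(pin, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = (pts - pin) @ n
    refl = pts - 2.0 * d[:, None] * n
    return ReconstructedCloud(
        points=np.vstack([pts, refl]),
        ids=list(ids) + [f"{i}_m" for i in ids],
        pin=pin,
        mirrored=np.concatenate([np.zeros(len(pts), bool), np.ones(len(pts), bool)]),
        plane_normal=n,
    )


def _fit_band_ellipse(xy: np.ndarray):
    if len(xy) < 5:
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        m = EllipseModel.from_estimate(xy)  # circle limit divides by (a - c)
    if not m:
        return None
    (xc, yc), (a, b), theta = m.center, m.axis_lengths, m.theta
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return None
    return float(xc), float(yc), float(a), float(b), float(theta)


def _ring_gap(xy: np.ndarray, center) -> tuple[float, np.ndarray, np.ndarray]:
    """Largest angular gap of the ring about ``center``.

    Returns (gap_rad, p_lo, p_hi) with the two points flanking the gap —
    for a ring truncated by the basal cut these flank the cut chord.
    """
    ang = np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0])
    order = np.argsort(ang)
    gaps = np.diff(np.concatenate([ang[order], [ang[order[0]] + 2 * np.pi]]))
    imax = int(np.argmax(gaps))
    return float(gaps[imax]), xy[order[imax]], xy[order[(imax + 1) % len(order)]]


def _extend_arc_endpoints(fit, p1, p2, extension: float):
    """Push the arc end points outward along the fitted ellipse.

    Markers stop short of the basal cut edge by roughly the printing margin
    plus half the grid pitch; extending each end of the observed arc by the
    expected shortfall (``extension`` mm of circumferential arc) before
    forming the clipping chord removes the systematic area deficit.
    """
    if extension <= 0:
        return p1, p2
    xc, yc, a, b, theta = fit
    ct, st = np.cos(theta), np.sin(theta)
    R = np.array([[ct, st], [-st, ct]])  # world -> ellipse frame

    def param_angle(p):
        q = R @ (np.asarray(p) - [xc, yc])
        return np.arctan2(q[1] / b, q[0] / a)

    def on_ellipse(t):
        q = np.array([a * np.cos(t), b * np.sin(t)])
        return R.T @ q + [xc, yc]

    t1, t2 = param_angle(p1), param_angle(p2)
    # the gap runs from t1 to t2 counter-clockwise; extend into the gap
    span = (t2 - t1) % (2 * np.pi)
    out = []
    for t, sgn in ((t1, +1.0), (t2, -1.0)):
        r_loc = np.hypot(a * np.sin(t), b * np.cos(t))
        dt = min(extension / max(r_loc, 1e-9), span / 2.0 * 0.99)
        out.append(on_ellipse(t + sgn * dt))
    return out[0], out[1]


def _clipped_ellipse_area(fit, p1, p2, points_side):
    """Area of the fitted ellipse clipped by the chord through p1, p2,
    keeping the side containing ``points_side`` (the observed arc)."""
    xc, yc, a, b, theta = fit
    e = np.asarray(p2) - np.asarray(p1)
    if np.linalg.norm(e) < 1e-9:
        return np.pi * a * b
    n2 = np.array([e[1], -e[0]])
    n2 /= np.linalg.norm(n2)
    if (np.asarray(points_side) - np.asarray(p1)) @ n2 > 0:
        n2 = -n2
    c = n2 @ np.asarray(p1)
    # rotate into the ellipse frame for the closed-form segment area
    ct, st = np.cos(-theta), np.sin(-theta)
    R = np.array([[ct, -st], [st, ct]])
    nr = R @ n2
    cr = c - n2 @ np.array([xc, yc])
    from .geometry import _ellipse_halfplane_area

    return float(_ellipse_halfplane_area(a, b, 0.0, 0.0, nr[0], nr[1], cr)[0])


def cloud_to_volume(
    cloud,
    method: str = "slicewise",
    band_height: float = 4.0,
    wall_offset: float = 0.0,
    edge_extension: float = 3.0,
    return_mesh: bool = False,
):
    """Enclosed volume (mL) of a reconstructed point cloud.

    slicewise (default): bin points into axial bands of ``band_height`` mm,
    least-squares fit an ellipse per band, clip partially covered rings at
    the chord of the missing arc, shrink semi-axes by ``wall_offset`` (to
    convert an outer-wall cloud to a cavity volume), and integrate area
    over z with linear area extrapolation to close the apex and base.

    hull: convex hull volume of the (optionally radially shrunk) points.

    Returns volume or (volume, mesh) with a trimesh.Trimesh when
    ``return_mesh`` — slicewise meshes are lofted from the fitted rings.
    """
    points = cloud.points if hasattr(cloud, "points") else np.asarray(cloud, dtype=float)
    if method == "hull":
        from scipy.spatial import ConvexHull

        pts = points.copy()
        if wall_offset > 0.0:
            xy = pts[:, :2]
            ctr = xy.mean(axis=0)
            r = np.linalg.norm(xy - ctr, axis=1)
            shrink = np.clip((r - wall_offset) / np.maximum(r, 1e-9), 0.0, None)
            pts[:, :2] = ctr + (xy - ctr) * shrink[:, None]
        if len(pts) < 4:
            raise ValueError("hull volume needs at least 4 non-coplanar points")
        hull = ConvexHull(pts)
        vol = hull.volume / 1000.0
        if return_mesh:
            import trimesh

            mesh = trimesh.Trimesh(vertices=pts[hull.vertices], faces=None, process=True)
            mesh = trimesh.convex.convex_hull(pts)
            return vol, mesh
        return vol
    if method != "slicewise":
        raise ValueError(f"unknown method {method!r}")

    z = points[:, 2]
    if z.max() - z.min() < band_height:
        raise ValueError("cloud spans less than one axial band")
    # cluster points into rings: markers sit on common-z rows, so 1-D
    # clustering with a gap threshold of half the band height finds them
    # (and degrades gracefully to bands for unstructured clouds)
    order = np.argsort(z)
    zs_sorted = z[order]
    breaks = np.where(np.diff(zs_sorted) > band_height / 2.0)[0]
    groups = np.split(order, breaks + 1)
    groups = [g for g in groups if len(g) >= 3]
    if len(groups) < 3:
        # unstructured cloud (no ring organisation): fall back to uniform bands
        edges = np.arange(z.min() - 1e-9, z.max() + band_height, band_height)
        groups = [
            np.where((z >= lo) & (z < hi))[0] for lo, hi in zip(edges[:-1], edges[1:])
        ]
        groups = [g for g in groups if len(g) >= 3]
    if len(groups) < 2:
        raise ValueError("fewer than two usable axial rings in the cloud")
    for g in groups:
        xy = points[g, :2]
        if np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
            raise ValueError("ring points are collinear; cannot fit a section")

    centers_z, fits, coverage = [], [], []
    for g in groups:
        xy = points[g, :2]
        centers_z.append(float(z[g].mean()))
        fit = _fit_band_ellipse(xy)
        if fit is None:
            coverage.append(0.0)
        else:
            gap, _, _ = _ring_gap(xy, fit[:2])
            coverage.append(2 * np.pi - gap)
        fits.append(fit)
    centers_z = np.array(centers_z)
    # free fits are only trusted where the arc covers at least half the
    # ring; sparser rings inherit shape parameters extrapolated in z from
    # the trusted ones (their area is then clipped at the observed chord)
    trusted = [
        i for i, (f, cov) in enumerate(zip(fits, coverage)) if f is not None and cov >= np.pi
    ]
    if not trusted:
        raise ValueError("no axial ring had enough angular coverage for an ellipse fit")

    def _interp_extrap(zq: float, k: int) -> float:
        zt = centers_z[trusted]
        yt = np.array([fits[t][k] for t in trusted])
        if len(zt) == 1:
            return float(yt[0])
        if zq <= zt[0]:
            z0, z1, y0, y1 = zt[0], zt[1], yt[0], yt[1]
        elif zq >= zt[-1]:
            z0, z1, y0, y1 = zt[-2], zt[-1], yt[-2], yt[-1]
        else:
            return float(np.interp(zq, zt, yt))
        return float(y0 + (y1 - y0) * (zq - z0) / (z1 - z0))

    drop = []
    for i in range(len(groups)):
        if i in trusted:
            continue
        ref = tuple(_interp_extrap(centers_z[i], k) for k in range(5))
        f = fits[i]
        # a short-arc free fit is kept only when it is consistent with the
        # shape trend of the well-covered rings; a ring with neither a
        # usable fit nor a trustworthy reference is dropped and the end-cap
        # extrapolation closes the shape past it
        if f is not None and (
            0.75 * ref[2] <= f[2] <= 1.25 * ref[2] and 0.75 * ref[3] <= f[3] <= 1.25 * ref[3]
        ):
            continue
        # arc extent of the ring about the reference centre decides whether
        # the reference ellipse is usable at all for this ring
        xy = points[groups[i], :2]
        gap_ref, _, _ = _ring_gap(xy, ref[:2])
        if ref[2] > 0 and ref[3] > 0 and (2 * np.pi - gap_ref) >= np.deg2rad(120.0):
            fits[i] = ref
        else:
            drop.append(i)
    if drop:
        keep = [i for i in range(len(groups)) if i not in drop]
        centers_z = centers_z[keep]
        fits = [fits[i] for i in keep]
        groups = [groups[i] for i in keep]
    # chords (the trace of the basal cut) about the final ellipse centres
    chords, arc_ctr = [], []
    for i, g in enumerate(groups):
        xy = points[g, :2]
        gap, p1, p2 = _ring_gap(xy, fits[i][:2])
        chords.append((p1, p2) if gap > np.deg2rad(40.0) else None)
        arc_ctr.append(xy.mean(axis=0))
    areas = np.empty(len(groups))
    for i, f in enumerate(fits):
        xc, yc, a, b, th = f
        eff = (xc, yc, max(a - wall_offset, 1e-6), max(b - wall_offset, 1e-6), th)
        if chords[i] is not None:
            p1, p2 = _extend_arc_endpoints(f, *chords[i], edge_extension)
            areas[i] = _clipped_ellipse_area(eff, p1, p2, arc_ctr[i])
        else:
            areas[i] = np.pi * eff[2] * eff[3]
    # integrate; close apex and base by linear extrapolation of area to zero
    zs = list(centers_z)
    As = list(areas)
    for sign, i0, i1 in ((-1, 0, 1), (+1, len(groups) - 1, len(groups) - 2)):
        a0, a1 = areas[i0], areas[i1]
        if a1 > a0 > 0:
            dz = abs(centers_z[i1] - centers_z[i0])
            ext = min(a0 / (a1 - a0) * dz, 1.5 * band_height)
        else:
            ext = 0.5 * band_height
        if sign < 0:
            zs.insert(0, centers_z[0] - ext)
            As.insert(0, 0.0)
        else:
            zs.append(centers_z[-1] + ext)
            As.append(0.0)
    volume = float(np.trapezoid(As, zs)) / 1000.0
    if not return_mesh:
        return volume
    mesh = _loft_mesh(centers_z, [f[:5] for f in fits], wall_offset)
    return volume, mesh


def _loft_mesh(centers_z, fits, wall_offset, n_seg: int = 48):
    import trimesh

    rings = []
    for zc, (xc, yc, a, b, th) in zip(centers_z, fits):
        t = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
        ct, st = np.cos(th), np.sin(th)
        ae = max(a - wall_offset, 1e-6)
        be = max(b - wall_offset, 1e-6)
        x = xc + ae * np.cos(t) * ct - be * np.sin(t) * st
        y = yc + ae * np.cos(t) * st + be * np.sin(t) * ct
        rings.append(np.column_stack([x, y, np.full(n_seg, zc)]))
    verts = np.vstack(rings)
    faces = []
    for k in range(len(rings) - 1):
        o0, o1 = k * n_seg, (k + 1) * n_seg
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            faces.append([o0 + j, o1 + j, o1 + jn])
            faces.append([o0 + j, o1 + jn, o0 + jn])
    # apex and base fans
    apex = len(verts)
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    base = apex + 1
    for j in range(n_seg):
        jn = (j + 1) % n_seg
        faces.append([apex, jn, j])
        o = (len(rings) - 1) * n_seg
        faces.append([base, o + j, o + jn])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=True)
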