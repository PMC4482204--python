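"""Surface marker grid for stereo-photogrammetry.

Markers are printed on one lateral half of the *outer* wall surface on an
approximately 4 mm x 4 mm grid: rows equally spaced in meridional arc
length from apex to base, columns equally spaced in circumferential arc
length within each row.  Each marker is identified by its (row, column)
parameter pair, which is material — the same marker is re-evaluated on any
deformed geometry, so identity is stable across phases.

A fiducial pin at the apex on the long axis serves as the stationary
reference about which reconstructed half-clouds are mirrored; in-plane
scaling of the geometry leaves it fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LVGeometry

__all__ = ["MarkerGrid", "place_markers", "outer_surface_params"]


def outer_surface_params(geometry: LVGeometry, z):
    """(a, b, cx, cy) of the outer-wall ellipse at height(s) z.

    The wall is a constant in-plane offset of the cavity ellipse by the
    wall thickness.
    """
    a, b, cx, cy = geometry.params_at(z)
    t = geometry.wall_thickness
    return a + t, b + t, cx, cy


@dataclass
class MarkerGrid:
    """Material marker parameters plus the stationary pin."""

    row_z: np.ndarray  # (m,) mm, height of each marker (material, fixed)
    theta: np.ndarray  # (m,) rad, parametric angle on the ellipse
    ids: list[str]
    pin_position: np.ndarray  # (3,) mm
    grid_pitch: float = 4.0  # mm
    marker_diameter: float = 2.0  # mm
    half: str = "+x"

    def __len__(self) -> int:
        return self.row_z.size

    def positions(self, geometry: LVGeometry) -> np.ndarray:
        """3D marker positions (m, 3) on the given geometry's outer wall."""
        a, b, cx, cy = outer_surface_params(geometry, self.row_z)
        x = cx + a * np.cos(self.theta)
        y = cy + b * np.sin(self.theta)
        return np.column_stack([x, y, self.row_z])

    def mirrored(self) -> "MarkerGrid":
        """The same grid reflected across the x = 0 symmetry plane."""
        return MarkerGrid(
            row_z=self.row_z.copy(),
            theta=np.pi - self.theta,
            ids=[f"{i}_m" for i in self.ids],
            pin_position=self.pin_position.copy(),
            grid_pitch=self.grid_pitch,
            marker_diameter=self.marker_diameter,
            half="-x" if self.half == "+x" else "+x",
        )


def _half_ellipse_arc(a: float, b: float, n: int = 181):
    """Cumulative arc length over theta in [-pi/2, pi/2] (the +x half)."""
    th = np.linspace(-np.pi / 2, np.pi / 2, n)
    ds = np.hypot(a * np.sin(th), b * np.cos(th))
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(th))])
    return th, s


def place_markers(
    geometry: LVGeometry,
    pitch: float = 4.0,
    half: str = "+x",
    marker_diameter: float = 2.0,
    cut_margin: float = 1.0,
) -> MarkerGrid:
    """Lay out the marker grid on one half of the outer surface.

    Rows sit at equal meridional arc spacing (``pitch``) starting half a
    pitch above the apex; within a row, markers sit at equal circumferential
    arc spacing centred on the +x meridian.  Markers closer than
    ``cut_margin`` mm to the basal cut plane are dropped (nothing is printed
    across the cut edge).
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if half not in ("+x", "-x"):
        raise ValueError("half must be '+x' or '-x'")
    zs = np.linspace(geometry.slice_z[0], geometry.slice_z[-1], 400)
    a, b, _, _ = outer_surface_params(geometry, zs)
    r = (a + b) / 2.0
    drdz = np.gradient(r, zs)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(1.0, (drdz[1:] + drdz[:-1]) / 2) * np.diff(zs))])
    total_arc = arc[-1]
    row_arcs = np.arange(pitch / 2.0, total_arc, pitch)
    if row_arcs.size == 0:
        raise ValueError(f"pitch {pitch} mm exceeds the surface extent ({total_arc:.1f} mm)")

    row_z_list, theta_list, ids = [], [], []
    for j, s_row in enumerate(row_arcs):
        z = float(np.interp(s_row, arc, zs))
        az, bz, cx, cy = (float(v) for v in outer_surface_params(geometry, z))
        if az < pitch / (2 * np.pi):  # ring too small to carry a marker
            continue
        th_grid, s_half = _half_ellipse_arc(az, bz)
        n_col = max(1, int(np.floor(s_half[-1] / pitch)) + 1)
        offsets = (np.arange(n_col) - (n_col - 1) / 2.0) * pitch
        s_positions = s_half[-1] / 2.0 + offsets
        keep = (s_positions >= 0) & (s_positions <= s_half[-1])
        th = np.interp(s_positions[keep], s_half, th_grid)
        for i, t in enumerate(th):
            row_z_list.append(z)
            theta_list.append(float(t))
            ids.append(f"r{j:02d}c{i:02d}")

    grid = MarkerGrid(
        row_z=np.array(row_z_list),
        theta=np.array(theta_list),
        ids=ids,
        pin_position=np.array([0.0, 0.0, geometry.slice_z[0]]),
        grid_pitch=pitch,
        marker_diameter=marker_diameter,
        half="+x",
    )
    if geometry.basal_cut is not None:
        p = grid.positions(geometry)
        signed = (p - geometry.basal_cut.point) @ geometry.basal_cut.normal
        keep = signed <= -cut_margin
        grid = MarkerGrid(
            row_z=grid.row_z[keep],
            theta=grid.theta[keep],
            ids=[i for i, k in zip(grid.ids, keep) if k],
            pin_position=grid.pin_position,
            grid_pitch=pitch,
            marker_diameter=marker_diameter,
            half="+x",
        )
    if len(grid) == 0:
        raise ValueError("no markers fit on the surface with this pitch")
    return grid if half == "+x" else grid.mirrored()
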