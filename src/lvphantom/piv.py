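"""Ensemble 2-D particle image velocimetry.

Dual-pass FFT cross-correlation with decreasing interrogation windows
(64 -> 32 px, 50 % overlap): the first pass supplies an integer predictor
that shifts the second tile in the second pass, keeping the correlation
peak near the window centre.  Displacement is the primary correlation
peak with a 3-point Gaussian sub-pixel fit; vector quality is the
primary-to-secondary peak ratio Q (secondary searched outside a 3 px
exclusion zone).  Vectors with Q below 1.2 are deleted and holes filled
by interpolation from valid neighbours; phase-locked ensembles are
averaged node-wise over cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator, griddata

__all__ = [
    "VectorField2D",
    "background_subtract",
    "correlate_pass",
    "multipass",
    "validate_vectors",
    "fill_holes",
    "ensemble_average",
    "displacements_to_velocity",
]


@dataclass
class VectorField2D:
    """PIV vectors on a regular window-centre grid.

    Displacements are in pixels; ``to_velocity`` (via
    :func:`displacements_to_velocity`) converts to m/s.
    """

    x: np.ndarray  # (nx,) window-centre columns, px
    y: np.ndarray  # (ny,) window-centre rows, px
    u: np.ndarray  # (ny, nx) displacement, px
    v: np.ndarray  # (ny, nx)
    q: np.ndarray  # (ny, nx) peak ratio
    valid: np.ndarray  # (ny, nx) bool
    window: int
    overlap: float
    u_ms: np.ndarray | None = None  # (ny, nx) m/s, set by displacements_to_velocity
    v_ms: np.ndarray | None = None


def background_subtract(image: np.ndarray, scale: int = 5) -> np.ndarray:
    """Sliding background removal: subtract the local minimum over a
    ``scale`` x ``scale`` box and clip at zero."""
    if scale < 1:
        raise ValueError("background scale must be >= 1 pixel")
    img = np.asarray(image, dtype=float)
    bg = ndimage.minimum_filter(img, size=int(scale), mode="nearest")
    return np.clip(img - bg, 0.0, None)


def _gauss_subpixel(cm1: float, c0: float, cp1: float) -> float:
    """3-point Gaussian peak interpolation; parabolic fallback."""
    eps = 1e-12
    if cm1 > eps and c0 > eps and cp1 > eps:
        lm1, l0, lp1 = np.log(cm1), np.log(c0), np.log(cp1)
        den = 2 * (lm1 - 2 * l0 + lp1)
        if abs(den) > eps:
            return float((lm1 - lp1) / den)
    den = 2 * (cm1 - 2 * c0 + cp1)
    return float((cm1 - cp1) / den) if abs(den) > 1e-12 else 0.0


def correlate_pass(
    image_a: np.ndarray,
    image_b: np.ndarray,
    window: int = 64,
    overlap: float = 0.5,
    predictor: VectorField2D | None = None,
    exclusion_px: int = 3,
) -> VectorField2D:
    """One interrogation pass of FFT cross-correlation.

    Tiles are mean-subtracted; with a ``predictor`` field the second tile
    is gathered at the (rounded) predicted displacement so the residual
    peak stays near zero lag.  Windows without signal (zero variance) are
    marked invalid.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("image pair must share a shape")
    h, w = a.shape
    if window > min(h, w):
        raise ValueError("interrogation window larger than the image")
    if not 0.0 <= overlap <= 0.75:
        raise ValueError("overlap must be in [0, 0.75]")
    step = max(1, int(round(window * (1.0 - overlap))))
    xs = np.arange(0, w - window + 1, step)
    ys = np.arange(0, h - window + 1, step)
    cx = xs + window / 2.0 - 0.5
    cy = ys + window / 2.0 - 0.5

    pred_u = np.zeros((len(ys), len(xs)))
    pred_v = np.zeros((len(ys), len(xs)))
    if predictor is not None:
        pu = np.where(predictor.valid, predictor.u, 0.0)
        pv = np.where(predictor.valid, predictor.v, 0.0)
        fu = RegularGridInterpolator(
            (predictor.y, predictor.x), pu, bounds_error=False, fill_value=None
        )
        fv = RegularGridInterpolator(
            (predictor.y, predictor.x), pv, bounds_error=False, fill_value=None
        )
        gy, gx = np.meshgrid(cy, cx, indexing="ij")
        pts = np.column_stack([gy.ravel(), gx.ravel()])
        pred_u = np.round(fu(pts)).reshape(len(ys), len(xs))
        pred_v = np.round(fv(pts)).reshape(len(ys), len(xs))

    u = np.zeros((len(ys), len(xs)))
    v = np.zeros((len(ys), len(xs)))
    q = np.zeros((len(ys), len(xs)))
    valid = np.zeros((len(ys), len(xs)), dtype=bool)
    half = window // 2
    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            du0, dv0 = int(pred_u[j, i]), int(pred_v[j, i])
            ta = a[y0 : y0 + window, x0 : x0 + window]
            yb0, xb0 = y0 + dv0, x0 + du0
            if yb0 < 0 or xb0 < 0 or yb0 + window > h or xb0 + window > w:
                # clamp the shifted gather to the frame
                yb0 = min(max(yb0, 0), h - window)
                xb0 = min(max(xb0, 0), w - window)
                du0, dv0 = xb0 - x0, yb0 - y0
            tb = b[yb0 : yb0 + window, xb0 : xb0 + window]
            if ta.std() < 1e-9 or tb.std() < 1e-9:
                continue
            fa = np.fft.rfft2(ta - ta.mean())
            fb = np.fft.rfft2(tb - tb.mean())
            corr = np.fft.irfft2(np.conj(fa) * fb, s=(window, window))
            corr = np.fft.fftshift(corr)
            jj, ii = np.unravel_index(np.argmax(corr), corr.shape)
            c0 = corr[jj, ii]
            if c0 <= 0:
                continue
            # sub-pixel on each axis (skip at the window border)
            dx = dy = 0.0
            if 0 < ii < window - 1:
                dx = _gauss_subpixel(corr[jj, ii - 1], c0, corr[jj, ii + 1])
            if 0 < jj < window - 1:
                dy = _gauss_subpixel(corr[jj - 1, ii], c0, corr[jj + 1, ii])
            # peak ratio: secondary peak outside the exclusion zone
            masked = corr.copy()
            y_lo, y_hi = max(jj - exclusion_px, 0), min(jj + exclusion_px + 1, window)
            x_lo, x_hi = max(ii - exclusion_px, 0), min(ii + exclusion_px + 1, window)
            masked[y_lo:y_hi, x_lo:x_hi] = -np.inf
            second = float(masked.max())
            q[j, i] = c0 / second if second > 0 else np.inf
            u[j, i] = du0 + (ii - half) + dx
            v[j, i] = dv0 + (jj - half) + dy
            valid[j, i] = True
    return VectorField2D(x=cx, y=cy, u=u, v=v, q=q, valid=valid, window=window, overlap=overlap)


def multipass(
    image_a: np.ndarray,
    image_b: np.ndarray,
    windows: tuple[int, ...] = (64, 32),
    overlap: float = 0.5,
    q_min: float = 1.2,
) -> VectorField2D:
    """Dual-pass (decreasing window) interrogation with validation between
    passes; the final field is Q-validated and hole-filled."""
    field = None
    for k, win in enumerate(windows):
        if field is not None:
            field = fill_holes(validate_vectors(field, q_min))
        field = correlate_pass(image_a, image_b, window=win, overlap=overlap, predictor=field)
    return fill_holes(validate_vectors(field, q_min))


def validate_vectors(field: VectorField2D, q_min: float = 1.2) -> VectorField2D:
    """Delete vectors whose peak ratio Q falls below ``q_min``."""
    valid = field.valid & (field.q >= q_min)
    return replace(field, valid=valid)


def fill_holes(field: VectorField2D) -> VectorField2D:
    """Fill invalid nodes by interpolation from valid neighbours.

    Linear (grid-bilinear via triangulation) inside the convex hull of
    valid nodes, nearest-neighbour extrapolation at the edges.
    """
    if field.valid.all():
        return field
    if not field.valid.any():
        raise ValueError("cannot fill a field with no valid vectors")
    gy, gx = np.meshgrid(field.y, field.x, indexing="ij")
    pts = np.column_stack([gy[field.valid], gx[field.valid]])
    holes = ~field.valid
    targets = np.column_stack([gy[holes], gx[holes]])
    u = field.u.copy()
    v = field.v.copy()
    for comp, arr in (("u", u), ("v", v)):
        vals = arr[field.valid]
        filled = griddata(pts, vals, targets, method="linear")
        nn = griddata(pts, vals, targets, method="nearest")
        filled = np.where(np.isnan(filled), nn, filled)
        arr[holes] = filled
    return replace(field, u=u, v=v, valid=np.ones_like(field.valid))


def ensemble_average(fields: list[VectorField2D]) -> tuple[VectorField2D, np.ndarray]:
    """Node-wise mean over a phase-locked ensemble.

    Only valid samples contribute; returns the mean field (node valid if
    any cycle contributed) and the per-node contribution count.
    """
    if not fields:
        raise ValueError("empty ensemble")
    f0 = fields[0]
    for f in fields[1:]:
        if not (np.array_equal(f.x, f0.x) and np.array_equal(f.y, f0.y)):
            raise ValueError("ensemble fields must share the interrogation grid")
    count = np.sum([f.valid for f in fields], axis=0)
    su = np.sum([np.where(f.valid, f.u, 0.0) for f in fields], axis=0)
    sv = np.sum([np.where(f.valid, f.v, 0.0) for f in fields], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(count > 0, su / np.maximum(count, 1), np.nan)
        v = np.where(count > 0, sv / np.maximum(count, 1), np.nan)
    qm = np.mean([f.q for f in fields], axis=0)
    return (
        replace(f0, u=u, v=v, q=qm, valid=count > 0),
        count,
    )


def displacements_to_velocity(
    field: VectorField2D, dt: float, magnification: float
) -> VectorField2D:
    """Convert pixel displacements to m/s (``magnification`` in mm/px).

    Warns when the median displacement magnitude leaves the 5-8 px range
    the acquisition aims for.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mag = np.hypot(field.u, field.v)[field.valid]
    if mag.size:
        med = float(np.median(mag))
        if not 5.0 <= med <= 8.0:
            warnings.warn(
                f"median displacement {med:.1f} px outside the 5-8 px design range",
                stacklevel=2,
            )
    factor = magnification * 1e-3 / dt  # px -> m/s
    return replace(field, u_ms=field.u * factor, v_ms=field.v * factor)
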