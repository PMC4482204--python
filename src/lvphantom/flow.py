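"""Flow-to-volume integration, normalization, EF, and cross-modality
comparison of normalized volume curves.

The flow modalities (inline probes, PC-CMR) measure mitral inflow and
aortic outflow; the cavity volume follows by integrating their difference
from end systole,

    V(t) = ESV + \\int_{t_es}^{t} (q_mv - q_av) dt,

with the end-systolic volume supplied by an imaging modality.  Curves from
different modalities are compared after normalizing each by its own cycle
maximum and mapping time to cycle fraction; the comparison statistic is
the pointwise absolute difference of normalized volumes, in percent,
summarized as mean +/- population sd and the maximum with its phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .waveform import LPM_TO_MLPS, FlowSeries, VolumeSeries

__all__ = [
    "NormalizedVolumeSeries",
    "ComparisonReport",
    "integrate_volume",
    "resample_spline",
    "resample_flow_series",
    "normalize_volume",
    "ejection_fraction",
    "compare_modalities",
]


@dataclass
class NormalizedVolumeSeries:
    """Volume curve divided by its cycle maximum, on cycle-fraction time."""

    fractions: np.ndarray  # in [0, 1)
    values: np.ndarray  # dimensionless, max exactly 1
    label: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.fractions.shape != self.values.shape:
            raise ValueError("fractions and values must share a shape")
        if np.any((self.fractions < 0) | (self.fractions >= 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1)")
        if not np.isclose(self.values.max(), 1.0, atol=1e-9):
            raise ValueError("normalized series must have max exactly 1")
        if np.any(self.values <= 0):
            raise ValueError("normalized volumes must be positive")


@dataclass
class ComparisonReport:
    """Pointwise comparison of two normalized volume curves."""

    label_a: str
    label_b: str
    fractions: np.ndarray  # common grid (the finer modality's samples)
    values_a: np.ndarray
    values_b: np.ndarray
    abs_diff_percent: np.ndarray
    mean_percent: float
    sd_percent: float
    max_percent: float
    argmax_fraction: float
    ef_a_percent: float | None = None
    ef_b_percent: float | None = None

    def summary(self) -> dict:
        return {
            "pair": f"{self.label_a} vs {self.label_b}",
            "mean_percent": self.mean_percent,
            "sd_percent": self.sd_percent,
            "max_percent": self.max_percent,
            "argmax_fraction": self.argmax_fraction,
            "ef_a_percent": self.ef_a_percent,
            "ef_b_percent": self.ef_b_percent,
        }


def integrate_volume(
    flows: FlowSeries,
    esv_constant: float,
    t_reference: float | None = None,
) -> VolumeSeries:
    """Integrate q_mv - q_av from end systole with the ESV as the constant.

    ``t_reference`` defaults to the detected end-systolic instant: the
    upcrossing of mitral inflow (filling onset) following ejection.  The
    integration runs cyclically from there with the trapezoidal rule; any
    negative volume along the way is an error naming the offending time.
    """
    if esv_constant <= 0:
        raise ValueError("end-systolic constant must be positive")
    t = flows.times
    net = flows.net_mlps()  # mL/s
    n = t.size
    if t_reference is None:
        pos = flows.q_mv > 1e-9
        starts = np.where(pos & ~np.roll(pos, 1))[0]
        i_ref = int(starts[0]) if starts.size else 0
    else:
        i_ref = int(np.argmin(np.abs(t - t_reference)))
    # roll so integration starts at the reference, append the wrap interval
    order = np.roll(np.arange(n), -i_ref)
    tt = np.concatenate([t[order[: n - i_ref]], t[order[n - i_ref:]] + flows.period])
    vv = net[order]
    dv = np.concatenate([[0.0], np.cumsum((vv[1:] + vv[:-1]) / 2 * np.diff(tt))])
    vol_rolled = esv_constant + dv
    volumes = np.empty(n)
    volumes[order] = vol_rolled
    if np.any(volumes <= 0):
        bad = t[np.argmin(volumes)]
        raise ValueError(f"integrated volume non-positive at t = {bad:.3f} s; check the ESV constant")
    return VolumeSeries(times=t.copy(), volumes=volumes, period=flows.period)


def resample_spline(times, values, target_times, period: float) -> np.ndarray:
    """Periodic cubic-spline resampling of one cycle onto a target grid.

    Used to bring the 20-phase PC-CMR sampling onto the dense probe
    discretization.  Requires >= 4 strictly increasing samples.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("periodic spline needs at least 4 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    t_ext = np.append(t, t[0] + period)
    y_ext = np.append(y, y[0])
    cs = CubicSpline(t_ext, y_ext, bc_type="periodic")
    return cs(np.mod(np.asarray(target_times, dtype=float) - t[0], period) + t[0])


def resample_flow_series(flows: FlowSeries, target_times) -> FlowSeries:
    """Spline-resample both flow channels onto a new time grid."""
    tt = np.asarray(target_times, dtype=float)
    return FlowSeries(
        times=tt,
        q_mv=resample_spline(flows.times, flows.q_mv, tt, flows.period),
        q_av=resample_spline(flows.times, flows.q_av, tt, flows.period),
        period=flows.period,
    )


def normalize_volume(v: VolumeSeries, label: str = "") -> NormalizedVolumeSeries:
    """Divide by the cycle maximum; map times to cycle fraction.

    Exactly one sample equals 1 (the first maximum under ties).
    """
    vmax = float(np.max(v.volumes))
    if vmax <= 0:
        raise ValueError("cannot normalize a non-positive series")
    vals = v.volumes / vmax
    i = int(np.argmax(vals))
    vals[i] = 1.0  # guard against round-off on the defining sample
    return NormalizedVolumeSeries(
        fractions=np.mod(v.times - v.times[0], v.period) / v.period,
        values=vals,
        label=label,
    )


def ejection_fraction(v) -> float:
    """EF in percent: 100 (Vmax - Vmin) / Vmax.

    Accepts a VolumeSeries or any array of volumes.
    """
    vol = v.volumes if hasattr(v, "volumes") else np.asarray(v, dtype=float)
    vmax, vmin = float(np.max(vol)), float(np.min(vol))
    if not vmax >= vmin > 0:
        raise ValueError("volumes must be positive")
    return 100.0 * (vmax - vmin) / vmax


def _resample_normalized(src: NormalizedVolumeSeries, frac_target: np.ndarray) -> np.ndarray:
    return resample_spline(src.fractions, src.values, frac_target, period=1.0)


def compare_modalities(a: NormalizedVolumeSeries, b: NormalizedVolumeSeries) -> ComparisonReport:
    """Pointwise absolute difference of two normalized volume curves.

    The coarser modality is spline-resampled (periodically) onto the finer
    modality's cycle-fraction samples, so the comparison grid excludes any
    phases missing from the finer series (e.g. blur-rejected cine frames).
    The result is symmetric in its arguments.
    """
    if a.fractions.size == 0 or b.fractions.size == 0:
        raise ValueError("empty series cannot be compared")
    fine, coarse = (a, b) if a.fractions.size >= b.fractions.size else (b, a)
    grid = fine.fractions
    v_fine = fine.values
    v_coarse = _resample_normalized(coarse, grid)
    d = 100.0 * np.abs(v_fine - v_coarse)
    va, vb = (v_fine, v_coarse) if fine is a else (v_coarse, v_fine)
    return ComparisonReport(
        label_a=a.label,
        label_b=b.label,
        fractions=grid,
        values_a=va,
        values_b=vb,
        abs_diff_percent=d,
        mean_percent=float(np.mean(d)),
        sd_percent=float(np.std(d)),
        max_percent=float(np.max(d)),
        argmax_fraction=float(grid[np.argmax(d)]),
    )
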