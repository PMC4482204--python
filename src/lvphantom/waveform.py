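"""Ventricular volume waveforms and transvalvular flow curves.

The phantom is driven by a prescribed cavity-volume waveform V(t) over one
cardiac cycle.  The waveform is piecewise smooth: a raised-cosine ejection
lobe, an isovolumic pause, a raised-cosine filling lobe, and diastasis.
Filling is monophasic (a single E-wave; no A-wave).  Lobe durations are
solved from the requested peak aortic/mitral flow rates so that each lobe's
integral equals the stroke volume, which ties the printed peak flows and the
end-diastolic/end-systolic volumes together in a single parameterization.

Units: time s, volume mL, flow L/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeSeries",
    "FlowSeries",
    "WaveformTiming",
    "make_volume_waveform",
    "derive_flows",
]

#: mL/s per L/min
LPM_TO_MLPS = 1000.0 / 60.0


@dataclass
class VolumeSeries:
    """Cavity volume V(t) sampled on an explicit time grid.

    For a periodic phantom the grid is uniform and open (t = 0 ... T - dt),
    so periodic extension is implicit.
    """

    times: np.ndarray  # s
    volumes: np.ndarray  # mL
    period: float  # s
    #: optional phase landmarks (ejection/filling onsets etc.), seconds
    segments: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must have the same shape")
        if self.times.size < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.min(self.volumes) <= 0:
            raise ValueError("volumes must be positive")

    @property
    def edv(self) -> float:
        return float(np.max(self.volumes))

    @property
    def esv(self) -> float:
        return float(np.min(self.volumes))


@dataclass
class FlowSeries:
    """Mitral inflow and aortic outflow on a shared time grid (L/min).

    Both flows are positive in their forward direction; regurgitation shows
    up as negative excursions.
    """

    times: np.ndarray  # s
    q_mv: np.ndarray  # L/min, mitral inflow
    q_av: np.ndarray  # L/min, aortic outflow
    period: float  # s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q_mv = np.asarray(self.q_mv, dtype=float)
        self.q_av = np.asarray(self.q_av, dtype=float)
        if not (self.times.shape == self.q_mv.shape == self.q_av.shape):
            raise ValueError("times, q_mv and q_av must share a shape")

    def net_mlps(self) -> np.ndarray:
        """dV/dt in mL/s implied by the two flows."""
        return (self.q_mv - self.q_av) * LPM_TO_MLPS


@dataclass(frozen=True)
class WaveformTiming:
    """Timing/peak parameters of the volume waveform.

    Peak flows default to the PC-CMR measurements at the aortic and mitral
    planes (20 and 17.5 L/min); the isovolumic pauses are short flat
    segments bracketing ejection.
    """

    peak_aortic_lpm: float = 20.0
    peak_mitral_lpm: float = 17.5
    iso_contraction_s: float = 0.04
    iso_relaxation_s: float = 0.04


def volume_waveform_function(
    edv: float,
    esv: float,
    hr: float = 70.0,
    timing: WaveformTiming | None = None,
):
    """Return (V(t) callable, period).  V is T-periodic and vectorized."""
    if not edv > esv > 0:
        raise ValueError(f"require edv > esv > 0, got edv={edv}, esv={esv}")
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    timing = timing or WaveformTiming()
    period = 60.0 / hr
    sv = edv - esv
    q_av_pk = timing.peak_aortic_lpm * LPM_TO_MLPS  # mL/s
    q_mv_pk = timing.peak_mitral_lpm * LPM_TO_MLPS
    # raised-cosine lobe: integral = peak * duration / 2
    dur_ej = np.pi * sv / (2.0 * q_av_pk) if sv > 0 else 0.0
    dur_fill = np.pi * sv / (2.0 * q_mv_pk) if sv > 0 else 0.0
    t_active = timing.iso_contraction_s + dur_ej + timing.iso_relaxation_s + dur_fill
    if t_active > period:
        raise ValueError(
            f"waveform does not fit the cycle: active time {t_active:.3f} s "
            f"> period {period:.3f} s; raise peak flows or lower stroke volume"
        )
    t0 = timing.iso_contraction_s
    t1 = t0 + dur_ej
    t2 = t1 + timing.iso_relaxation_s
    t3 = t2 + dur_fill
    segments = {
        "ejection_onset": t0,
        "ejection_end": t1,
        "filling_onset": t2,
        "filling_end": t3,
    }

    def v_of_t(t):
        tau = np.mod(np.asarray(t, dtype=float), period)
        v = np.full_like(tau, edv)
        if sv > 0:
            ej = (tau >= t0) & (tau < t1)
            v[ej] = edv - sv * 0.5 * (1.0 - np.cos(np.pi * (tau[ej] - t0) / dur_ej))
            iso = (tau >= t1) & (tau < t2)
            v[iso] = esv
            fi = (tau >= t2) & (tau < t3)
            v[fi] = esv + sv * 0.5 * (1.0 - np.cos(np.pi * (tau[fi] - t2) / dur_fill))
        return v

    return v_of_t, period, segments


def make_volume_waveform(
    edv: float = 65.0,
    esv: float = 31.0,
    hr: float = 70.0,
    timing: WaveformTiming | None = None,
    n_samples: int = 214,
) -> VolumeSeries:
    """Sample the periodic volume waveform on a uniform open grid.

    Defaults reproduce the cine-derived extremes (EDV 65 mL, ESV 31 mL) at
    70 bpm; ``n_samples=214`` matches the stereo-photogrammetry frame count.
    """
    v_of_t, period, segments = volume_waveform_function(edv, esv, hr, timing)
    times = np.linspace(0.0, period, int(n_samples), endpoint=False)
    return VolumeSeries(times=times, volumes=v_of_t(times), period=period, segments=segments)


def derive_flows(v: VolumeSeries, regurgitant_fraction: float = 0.0) -> FlowSeries:
    """Differentiate V(t) into mitral and aortic flow curves.

    q_mv carries the positive part of dV/dt (filling), q_av the negative
    part (ejection), both converted to L/min.  A nonzero
    ``regurgitant_fraction`` superimposes leakage lobes (reverse mitral flow
    during ejection, reverse aortic flow during filling) while preserving
    q_mv - q_av = dV/dt at every sample, so the per-cycle balance holds.
    """
    t, vol = v.times, v.volumes
    dt = np.diff(t)
    uniform = np.allclose(dt, dt[0], rtol=1e-8)
    if uniform and abs((t[-1] - t[0]) + dt[0] - v.period) < 1e-9 * v.period:
        # open periodic grid: wrap-around central differences
        dvdt = (np.roll(vol, -1) - np.roll(vol, 1)) / (2.0 * dt[0])
    else:
        dvdt = np.gradient(vol, t)
        imbalance = np.trapezoid(dvdt, t)
        if abs(imbalance) > 0.005 * np.max(vol):
            warnings.warn(
                "volume series is not periodic; flows renormalized to "
                f"zero net per-cycle volume (imbalance {imbalance:.2f} mL)",
                stacklevel=2,
            )
            dvdt = dvdt - imbalance / (t[-1] - t[0])
    q_mv = np.maximum(dvdt, 0.0) / LPM_TO_MLPS
    q_av = np.maximum(-dvdt, 0.0) / LPM_TO_MLPS
    rf = float(regurgitant_fraction)
    if rf > 0.0:
        # subtract the same leak from both flows: the difference (and hence
        # the implied dV/dt and per-cycle balance) is unchanged
        leak_mv = rf * q_av   # reverse mitral flow during ejection
        leak_av = rf * q_mv   # reverse aortic flow during filling
        q_mv = q_mv - leak_mv - leak_av
        q_av = q_av - leak_mv - leak_av
    return FlowSeries(times=t.copy(), q_mv=q_mv, q_av=q_av, period=v.period)
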