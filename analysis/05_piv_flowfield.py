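"""Ensemble PIV of the synthetic diastolic jet and vortex pair.

Renders phase-locked particle-image pairs of the analytic early-diastole
field (1.15 m/s central jet, counter-rotating vortex pair), processes
them with dual-pass decreasing-window correlation, Q-ratio validation and
hole filling, ensemble-averages 50 pairs, and checks that the recovered
field reproduces the jet speed and the two opposite-signed vortices.
Writes the mean vector field to results/piv/.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np

from lvphantom.flowfield import ParticleImageSpec, make_velocity_field, render_particle_pair
from lvphantom.io import write_vector_field_csv
from lvphantom.piv import displacements_to_velocity, ensemble_average, multipass

OUT = Path(__file__).resolve().parents[1] / "results" / "piv"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--pairs", type=int, default=50,
                    help="image pairs in the phase-locked ensemble")
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    vf = make_velocity_field(jet_speed=1.15)
    spec = ParticleImageSpec(noise_sigma=0.02)
    fields = []
    for c in range(args.pairs):
        a, b = render_particle_pair(vf, dt=1e-3, spec=spec,
                                    seed=args.seed + 100 + c, jitter_mm=0.01)
        fields.append(multipass(a, b))
    mean, count = ensemble_average(fields)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = displacements_to_velocity(mean, 1e-3, spec.magnification)
    gx = vf.domain[0] + mean.x * spec.magnification
    gy = vf.domain[2] + mean.y * spec.magnification
    ut, vt = vf(*np.meshgrid(gx, gy))
    rms = np.sqrt(np.nanmean((mean.u_ms - ut) ** 2 + (mean.v_ms - vt) ** 2))
    speed = np.hypot(mean.u_ms, mean.v_ms)
    dxm = (mean.x[1] - mean.x[0]) * spec.magnification * 1e-3
    vort = (np.gradient(np.nan_to_num(mean.v_ms), axis=1) / dxm
            - np.gradient(np.nan_to_num(mean.u_ms), axis=0) / dxm)
    jmax = np.unravel_index(np.argmax(vort), vort.shape)
    jmin = np.unravel_index(np.argmin(vort), vort.shape)
    print(f"ensemble                      : {args.pairs} pairs, dt = 1.0 ms")
    print(f"peak recovered speed          : {np.nanmax(speed):5.3f} m/s (set 1.150)")
    print(f"RMS error                     : {100 * rms / 1.15:5.2f} % of peak")
    print(f"vortex cores (x mm, sign)     : "
          f"({gx[jmax[1]]:+5.1f}, +) ({gx[jmin[1]]:+5.1f}, -)")
    write_vector_field_csv(mean, OUT / "mean_field.csv")
    print(f"wrote mean vector field to {OUT}")


if __name__ == "__main__":
    main()
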