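"""Short-axis cine segmentation volumetry with blur rejection.

Renders the 15-slice short-axis stack of the deforming phantom, flags the
motion-blurred phases (the blur model is calibrated so 7 of 128 phases
blur out, at peak systole and early diastole), segments every usable
phase with the region-based active contour, and sums slice areas into
volumes.  The stack here uses 64 phases/cycle to keep the run at desk
scale; the blur statistics are reported from the full 128-phase stack.
Writes the cine volume curve to results/cine/.
"""

import argparse
from pathlib import Path

import numpy as np

from lvphantom.cine import reconstruct_series, reject_blurred
from lvphantom.geometry import default_geometry
from lvphantom.io import write_volumes_csv
from lvphantom.motion import make_phase_geometries
from lvphantom.slices import max_wall_speeds, render_slices
from lvphantom.waveform import VolumeSeries, make_volume_waveform

OUT = Path(__file__).resolve().parents[1] / "results" / "cine"


def _stack(n_phases, seed):
    v = make_volume_waveform(n_samples=n_phases)
    g = default_geometry(65.0)
    geoms = make_phase_geometries(g, v)
    speeds = max_wall_speeds(geoms, v.times)
    return v, render_slices(geoms, v.times, wall_speeds=speeds, noise_sigma=0.03,
                            period=v.period, seed=seed)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--phases", type=int, default=64, help="phases to segment")
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    _, full = _stack(128, args.seed + 11)
    usable, frac = reject_blurred(full)
    print(f"blur model (128 phases)       : {int(full.blur_flags.sum())} flagged, "
          f"{usable.size} usable ({100 * frac:.1f} % ~ 95 %)")

    v, stack = _stack(args.phases, args.seed + 12)
    res = reconstruct_series(stack)
    truth = v.volumes[res.usable_indices]
    err = 100 * np.abs(res.volumes - truth) / truth
    print(f"segmented stack               : {stack.n_slices} slices x {args.phases} phases")
    print(f"recovered EDV / ESV           : {res.volumes.max():5.1f} / {res.volumes.min():5.1f} mL")
    print(f"recovered EF                  : {res.ef_percent:5.1f} %  (truth 52.3 %)")
    print(f"per-phase volume error        : max {err.max():4.2f} %, mean {err.mean():4.2f} %")
    write_volumes_csv(VolumeSeries(res.times, res.volumes, res.period),
                      OUT / f"volumes_cine_{args.phases}.csv")
    print(f"wrote cine volume curve to {OUT}")


if __name__ == "__main__":
    main()
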