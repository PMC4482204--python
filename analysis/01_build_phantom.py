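"""Build the ground-truth deforming-LV phantom and its driving curves.

Constructs the ellipse-stack cavity scaled to a 65 mL end-diastolic
volume, the 70 bpm volume waveform with a 31 mL end-systolic volume, and
the mitral/aortic flow curves it implies.  Writes the truth curves to
results/phantom/ and prints the scalars every later reconstruction is
judged against.
"""

import argparse
from pathlib import Path

import numpy as np

from lvphantom.flow import ejection_fraction
from lvphantom.geometry import default_geometry, volume_of
from lvphantom.io import write_flows_csv, write_volumes_csv
from lvphantom.waveform import derive_flows, make_volume_waveform

OUT = Path(__file__).resolve().parents[1] / "results" / "phantom"


def main():
    argparse.ArgumentParser(description=__doc__).parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    g = default_geometry(65.0)
    print(f"cavity volume at end diastole : {volume_of(g):7.2f} mL")
    print(f"long-axis extent              : {g.long_axis_length:7.1f} mm")
    print(f"wall thickness                : {g.wall_thickness:7.2f} mm")
    v = make_volume_waveform(edv=65, esv=31, hr=70, n_samples=214)
    f = derive_flows(v)
    print(f"period                        : {v.period:7.3f} s  (70 bpm)")
    print(f"EF of the truth waveform      : {ejection_fraction(v):7.1f} %")
    print(f"peak aortic / mitral flow     : {f.q_av.max():5.1f} / {f.q_mv.max():5.1f} L/min")
    sv = np.trapezoid(np.append(f.q_mv, f.q_mv[0]),
                      np.append(f.times, v.period)) * 1000 / 60
    print(f"stroke volume (mitral integral): {sv:6.1f} mL")
    write_volumes_csv(v, OUT / "volumes_truth_214.csv")
    write_flows_csv(f, OUT / "flows_truth_214.csv")
    print(f"wrote truth curves to {OUT}")


if __name__ == "__main__":
    main()
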