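import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from lvphantom.geometry import default_geometry
from lvphantom.markers import place_markers
from lvphantom.motion import make_phase_geometries
from lvphantom.slices import max_wall_speeds, render_slices
from lvphantom.waveform import make_volume_waveform

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def geometry65():
    """Reference cavity scaled to the end-diastolic 65 mL."""
    return default_geometry(65.0)


@pytest.fixture(scope="session")
def markers65(geometry65):
    return place_markers(geometry65)


@pytest.fixture(scope="session")
def waveform128():
    return make_volume_waveform(n_samples=128)


@pytest.fixture(scope="session")
def cine_stack_full(geometry65, waveform128):
    """Noisy 128-phase, 15-slice stack with the calibrated blur model."""
    v = waveform128
    geoms = make_phase_geometries(geometry65, v)
    speeds = max_wall_speeds(geoms, v.times)
    return render_slices(
        geoms, v.times, wall_speeds=speeds, noise_sigma=0.03, period=v.period, seed=1
    )


@pytest.fixture(scope="session")
def cine_reduced():
    """64-phase stacks (noisy and noiseless) plus ground-truth volumes."""
    v = make_volume_waveform(n_samples=64)
    g0 = default_geometry(65.0)
    geoms = make_phase_geometries(g0, v)
    speeds = max_wall_speeds(geoms, v.times)
    stacks = {
        sigma: render_slices(
            geoms, v.times, wall_speeds=speeds, noise_sigma=sigma, period=v.period, seed=1
        )
        for sigma in (0.0, 0.03)
    }
    return {"waveform": v, "stacks": stacks}


@pytest.fixture(scope="session")
def piv_ensemble():
    """50-pair ensemble PIV of the diastolic jet + vortex-pair field."""
    from lvphantom.flowfield import ParticleImageSpec, make_velocity_field, render_particle_pair
    from lvphantom.piv import displacements_to_velocity, ensemble_average, multipass

    vf = make_velocity_field()
    spec = ParticleImageSpec(noise_sigma=0.02)
    fields = []
    for c in range(50):
        a, b = render_particle_pair(vf, dt=1e-3, spec=spec, seed=100 + c, jitter_mm=0.01)
        fields.append(multipass(a, b))
    mean, count = ensemble_average(fields)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = displacements_to_velocity(mean, 1e-3, spec.magnification)
    return {"field": vf, "mean": mean, "count": count, "spec": spec, "dt": 1e-3}
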