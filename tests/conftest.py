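import numpy as np
import pytest

from cortexcam import synthdata as sd
from cortexcam import volumize as vz


@pytest.fixture(scope="session")
def small_surface():
    return sd.make_sphere_surface(n_vertices=400, n_regions=6, seed=7)


@pytest.fixture(scope="session")
def small_map(small_surface):
    return vz.make_mollweide_map(small_surface, grid_size=24)


@pytest.fixture(scope="session")
def small_effect(small_surface):
    return sd.default_effect_spec(small_surface, seed=3)


@pytest.fixture(scope="session")
def tiny_cohort(small_surface, small_effect):
    """4 + 4 subjects x 8 trials, materialized."""
    table, sets = sd.simulate_cohort(small_surface, small_effect, 4, 8)
    return table, sets


def roi_window_means(surface, spec, trial_sets):
    """Per-subject mean amplitude over ROI vertices and the effect window."""
    mask = surface.region_mask(spec.roi_region_id)
    out = []
    for ts in trial_sets:
        t = ts.times_ms
        sel = (t >= spec.window_ms[0]) & (t < spec.window_ms[1])
        out.append(float(ts.data[:, mask][:, :, sel].mean()))
    return np.array(out)
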