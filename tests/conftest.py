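"""Shared fixtures: synthetic pellets reused across test modules."""

import numpy as np
import pytest

import pelletox as px

#: generating yield used for all recovery-style fixtures
TRUE_Y = 1.95


@pytest.fixture(scope="session")
def params():
    return px.TABLE_DEFAULTS


@pytest.fixture(scope="session")
def truth_params():
    return px.TABLE_DEFAULTS.replace(y_xo2=TRUE_Y)


@pytest.fixture(scope="session")
def regular_shells():
    spec, _ = px.preset("regular", seed=0)
    return px.gen_radial_hyphal_fraction(spec)


@pytest.fixture(scope="session")
def noiseless_aligned(truth_params):
    """Ground-truth-aligned noiseless pellet from the regular preset."""
    spec, _ = px.preset("regular", seed=3, noise_sd=0.0)
    shells = px.gen_radial_hyphal_fraction(spec)
    aligned, profile = px.gen_aligned_pellet(shells, truth_params, spec)
    return aligned, profile, shells


def small_supplied_pellet(seed: int, noise_sd: float = 0.1,
                          truth=None):
    """A pellet with oxygen everywhere positive (well-posed estimation)."""
    truth = truth or px.TABLE_DEFAULTS.replace(y_xo2=TRUE_Y)
    spec = px.SynthSpec(pellet_radius=245.0, core_fraction=0.15,
                        rim_fraction=0.15, rim_width=80.0,
                        noise_sd=noise_sd, seed=seed)
    shells = px.gen_radial_hyphal_fraction(spec)
    aligned, _ = px.gen_aligned_pellet(shells, truth, spec)
    return aligned, shells


def varied_pellet(seed: int, noise_sd: float = 0.1, truth=None):
    """Recovery-study pellet with seed-varied geometry and ch profile."""
    truth = truth or px.TABLE_DEFAULTS.replace(y_xo2=TRUE_Y)
    rng = np.random.default_rng(seed)
    radius = 50.0 + 15.0 * int(rng.integers(13, 31))     # 245..500 um
    core = float(rng.uniform(0.10, 0.30))
    rim = float(rng.uniform(0.15, 0.40))
    spec = px.SynthSpec(pellet_radius=radius, core_fraction=core,
                        rim_fraction=rim,
                        rim_width=float(rng.uniform(80.0, 160.0)),
                        noise_sd=noise_sd, seed=seed)
    shells = px.gen_radial_hyphal_fraction(spec)
    aligned, _ = px.gen_aligned_pellet(shells, truth, spec)
    return aligned, shells
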