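"""Shared fixtures: simulated carpets at several scales.

The full-scale carpets (2·10^5 lines, 64 pixels, 0.125 ms/line — the
acquisition geometry the analysis targets) are session-scoped because
they take a few minutes each; every test that needs realistic statistics
shares them.  The small carpets are cheap and regenerated per session as
well.
"""

from dataclasses import replace

import numpy as np
import pytest

from stedpcf.simulate import (
    PSFModel,
    SimulationConfig,
    Species,
    particles_for_focal_number,
    simulate_carpet,
)

CONFOCAL_PSF = PSFModel(w_xy=275.0, S=5.0)
STED_PSF = PSFModel(w_xy=110.0, S=10.0)


def _dilute_config(psf, D, n_focus, n_lines, n_pixels=64, seed=0, **kw):
    cfg = SimulationConfig(
        species=(Species(D=D, brightness=2.0),), psf=psf,
        n_pixels=n_pixels, n_lines=n_lines, n_particles=1,
        background=0.02, seed=seed, **kw,
    )
    return replace(cfg, n_particles=particles_for_focal_number(
        cfg.box_volume_um3, psf, n_focus))


@pytest.fixture(scope="session")
def confocal_config():
    """Confocal free-diffusion run: w_xy = 275 nm, S = 5, D = 8.5 µm²/s."""
    return _dilute_config(CONFOCAL_PSF, D=8.5, n_focus=1.5,
                          n_lines=200_000, seed=11)


@pytest.fixture(scope="session")
def confocal_carpet(confocal_config):
    return simulate_carpet(confocal_config)


@pytest.fixture(scope="session")
def sted_config():
    """STED free-diffusion run: w_xy = 110 nm, S = 10, D = 20 µm²/s
    (monomeric GFP in the nucleoplasm)."""
    return _dilute_config(STED_PSF, D=20.0, n_focus=1.2,
                          n_lines=200_000, seed=12)


@pytest.fixture(scope="session")
def sted_carpet(sted_config):
    return simulate_carpet(sted_config)


@pytest.fixture(scope="session")
def sted_slow_config():
    """STED run with D = 8.5 µm²/s (capsid-like particle regime), where a
    3–4 pixel displacement sits well inside the bell-shaped region."""
    return _dilute_config(STED_PSF, D=8.5, n_focus=1.2,
                          n_lines=150_000, seed=13)


@pytest.fixture(scope="session")
def sted_slow_carpet(sted_slow_config):
    return simulate_carpet(sted_slow_config)


@pytest.fixture(scope="session")
def small_config():
    """Cheap 12-pixel, 10^4-line STED-like run for estimator tests."""
    return _dilute_config(STED_PSF, D=8.5, n_focus=1.2,
                          n_lines=10_000, n_pixels=12, seed=5)


@pytest.fixture(scope="session")
def small_carpet(small_config):
    return simulate_carpet(small_config)


NE_PIXEL = 24.25          # envelope plane between pixels 24 and 25
NE_SCENE = dict(
    n_pixels=48, n_lines=100_000, background=0.05,
    barrier_kwargs=dict(position_x=NE_PIXEL * 50.0, permeability=0.05,
                        slow_zone_halfwidth=600.0, slow_zone_D=4.3),
    D=17.0, brightness=8.0,
)


def _ne_scene_config(psf, n_focus, n_lines, seed):
    """Nuclear-envelope scene: free pool at D = 17 µm²/s, a semi-permeable
    envelope plane, and a 600 nm trapping zone around it where diffusion
    slows to 4.3 µm²/s (transport-complex binding).  The slow zone also
    accumulates particles (trap-like enrichment), producing the intensity
    contrast around the envelope."""
    from stedpcf.simulate import BarrierSpec
    cfg = SimulationConfig(
        species=(Species(D=NE_SCENE["D"], brightness=NE_SCENE["brightness"]),),
        psf=psf, n_pixels=NE_SCENE["n_pixels"], n_lines=n_lines,
        n_particles=1, background=NE_SCENE["background"],
        barrier=BarrierSpec(**NE_SCENE["barrier_kwargs"]), seed=seed,
    )
    return replace(cfg, n_particles=particles_for_focal_number(
        cfg.box_volume_um3, psf, n_focus))


@pytest.fixture(scope="session")
def ne_sted_carpet():
    return simulate_carpet(_ne_scene_config(STED_PSF, 1.0, 100_000, seed=31))


@pytest.fixture(scope="session")
def ne_confocal_carpet():
    return simulate_carpet(_ne_scene_config(CONFOCAL_PSF, 2.0, 80_000, seed=32))


@pytest.fixture(scope="session")
def interface_profiles():
    """Synthetic two-compartment intensity profiles: a 4x intensity step at
    pixel 30 blurred by the PSF (error-function edge), 64 pixels of 50 nm."""

    from scipy.special import erf

    def make(psf: PSFModel, x0_px=30.0, lo=100.0, hi=400.0, n_pixels=64):
        x = np.arange(n_pixels, dtype=float)
        # a step convolved with the Gaussian PSF (1/e² radius w) has an
        # erf edge of width sigma = w/2 (in pixels: /50 nm)
        sigma_px = psf.w_xy / 2.0 / 50.0
        return lo + (hi - lo) * 0.5 * (1.0 + erf((x - x0_px) / (sigma_px * np.sqrt(2))))

    return make
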