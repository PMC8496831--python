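"""Shared fixtures: small seeded synthetic pipelines."""

from __future__ import annotations

import numpy as np
import pytest

from deti import encoders, mapping, synthdata
from deti import veps as veps_mod
from deti.stimuli import StimulusSet, WindowSpec, build_window_mask, rms_calibrate


@pytest.fixture(scope="session")
def tiny_stimuli() -> StimulusSet:
    """Eight 32-px calibrated noise images (fast, for shape/contract tests)."""
    rng = np.random.default_rng(0)
    window = WindowSpec(image_size=32, diameter=32.0)
    mask, _ = build_window_mask(window)
    images = [rms_calibrate(rng.standard_normal((32, 32)), mask) for _ in range(8)]
    return StimulusSet(images, [f"im{i}" for i in range(8)], window, mask=mask)


@pytest.fixture(scope="session")
def tiny_space(tiny_stimuli) -> encoders.EncoderSpace:
    return encoders.encode_images(tiny_stimuli)


@pytest.fixture(scope="session")
def recovery_cfg() -> synthdata.SynthConfig:
    """Config with recoverable ground truth (uniform per-electrode
    preference, spaced bands, per-band gain jitter)."""
    return synthdata.SynthConfig(
        seed=11,
        n_images=40,
        image_size=96,
        n_electrodes=6,
        post_ms=80,
        preference_bands=(1, 7),
        eccentricity_rings=0,
        band_gain_sigma=2.5,
    )


@pytest.fixture(scope="session")
def recovery_run(recovery_cfg) -> dict:
    """Full noiseless synthetic run: stimuli -> encoder space -> VEPs ->
    PC series, shared by the recovery-flavored tests."""
    cfg = recovery_cfg
    stimuli = synthdata.synth_images(cfg)
    space = encoders.encode_images(stimuli)
    truth = synthdata.synth_ground_truth(cfg, space.n_visible, space.pixel_index)
    epochs, veps = synthdata.synth_veps(space, truth, cfg)
    series = veps_mod.timeresolved_pc1(veps)
    return {
        "cfg": cfg,
        "stimuli": stimuli,
        "space": space,
        "truth": truth,
        "veps": veps,
        "series": series,
    }


@pytest.fixture(scope="session")
def recovery_tags(recovery_run) -> np.ndarray:
    """Image-general tags for every (electrode, step) of the recovery run."""
    space = recovery_run["space"]
    series = recovery_run["series"]
    n_e, n_s, _ = series.loadings.shape
    tags = np.zeros((n_e, n_s, space.n_visible), dtype=np.int16)
    for e in range(n_e):
        for s in range(n_s):
            maps = mapping.pixelwise_regression(space, series.loadings[e, s])
            sig = mapping.significance_mask(maps, 0.05)
            tags[e, s] = mapping.tag_image_general(maps, sig, e, s).tags
    return tags
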