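"""Shared fixtures: phantom scans and their deconvolved maps.

Phantoms are generated at the package's default study conditions
(50×50 grid, 0.2 mm pitch, 40-dB peak SNR) or at the fine 0.05 mm pitch
used for depth profiling; all are session-scoped because the deconvolution
of a full scan is the expensive step every integration test shares.
"""

import numpy as np
import pytest

import flimcart as fc


def _run(preset_name, seed, pitch=0.2, snr=40.0):
    cfg = fc.AcquisitionConfig(pixel_pitch=pitch, peak_snr_db=snr, seed=seed)
    scan, truth = fc.make_phantom(cfg, fc.preset(preset_name))
    maps = fc.build_maps(scan)
    return scan, truth, maps


@pytest.fixture(scope="session")
def control_run():
    return _run("control", seed=1)


@pytest.fixture(scope="session")
def high_run():
    return _run("high", seed=2)


@pytest.fixture(scope="session")
def high_run_seg():
    return _run("high", seed=4)


@pytest.fixture(scope="session")
def low_run_seg():
    return _run("low", seed=5)


@pytest.fixture(scope="session")
def fine_control_run():
    """Fine-pitch (0.05 mm) control scan with surface, distances, profile."""
    scan, truth, maps = _run("control", seed=3, pitch=0.05)
    surface = fc.detect_surface(maps)
    dist = fc.distance_map(surface, maps)
    profile = fc.depth_profile(maps, dist)
    return scan, truth, maps, surface, dist, profile


@pytest.fixture(scope="session")
def noiseless_control_run():
    return _run("control", seed=0, snr=None)


@pytest.fixture(scope="session")
def noiseless_low_run():
    return _run("low", seed=0, snr=None)


@pytest.fixture(scope="session")
def noiseless_high_run():
    return _run("high", seed=0, snr=None)


@pytest.fixture(scope="session")
def default_irf():
    cfg = fc.AcquisitionConfig()
    return fc.make_irf(cfg), cfg


def roi_depth_mask(truth, min_depth=0.5):
    """Tissue ROI excluding the superficial ramp region."""
    return truth.tissue_mask & (truth.depth > min_depth)


def pooled_ratio_values(runs):
    """Stack (ch1 ratio, depleted label) over the valid tissue pixels of
    several (scan, truth, maps) runs."""
    vals, labels = [], []
    for _, truth, maps in runs:
        sel = maps.valid & truth.tissue_mask
        vals.append(maps.ratio[sel][:, 0])
        labels.append(truth.depleted_mask[sel])
    return np.concatenate(vals), np.concatenate(labels)
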