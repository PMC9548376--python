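"""Shared fixtures: small rendered movies with ground truth."""
import logging

import pytest

from fuccitrack.models import CellCycleModel, ImagingConfig
from fuccitrack.pipeline import analyze_movie, simulate_cohort_movie

logging.getLogger("fuccitrack").setLevel(logging.ERROR)

# a compact dividing-cohort model resolvable at a 15-min frame interval
CLEAN_MODEL = CellCycleModel(
    g1_median_min=300.0, g1_logsd=0.25,
    sg2m_median_min=450.0, sg2m_logsd=0.25,
    overlap_min=60.0, dark_gap_frames=3, genotype_label="clean")

CLEAN_IMAGING = ImagingConfig(
    n_frames=130, frame_interval_min=15.0, height=256, width=256,
    poisson_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_renders():
    """Two noiseless rendered movies with truth, oracle clicks and the full
    analysis — the shared oracle for segmentation/tracking/timing tests."""
    out = []
    for seed in (1, 2):
        result, clicks = simulate_cohort_movie(
            CLEAN_MODEL, CLEAN_IMAGING, n_founders=10, seed=seed)
        analysis = analyze_movie(result.movie, clicks, genotype="clean")
        out.append((result, clicks, analysis))
    return out


@pytest.fixture(scope="session")
def noisy_render():
    """One movie rendered with the default Poisson + read-noise model."""
    imaging = ImagingConfig(n_frames=90, frame_interval_min=15.0,
                            height=224, width=224)
    result, clicks = simulate_cohort_movie(CLEAN_MODEL, imaging,
                                           n_founders=8, seed=5)
    return result, clicks
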