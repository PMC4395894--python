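import numpy as np
import pytest

from corvispy.contours import ContourSet
from corvispy.pipeline import analyze_sequence
from corvispy.synthetic import (
    SyntheticConfig,
    GroundTruth,
    compute_ground_truth,
    make_paper_like_config,
    render_sequence,
)


def contours_from_truth(truth: GroundTruth, height: int = 200) -> ContourSet:
    """Wrap analytic ground-truth contours as a fully-valid ContourSet."""
    t, w = truth.outer_true.shape
    ones = np.ones((t, w), dtype=bool)
    return ContourSet(
        outer=truth.outer_true.copy(),
        inner=truth.inner_true.copy(),
        valid_outer=ones.copy(),
        valid_inner=ones.copy(),
        height=height,
        width=w,
        n_frames=t,
    )


def small_scene(**overrides) -> SyntheticConfig:
    """A reduced-geometry scene for fast rendering tests."""
    defaults = dict(
        n_frames=40,
        height=80,
        width=200,
        arc_radius_px=400.0,
        apex_row=15.0,
        corneal_thickness_px=10.0,
        bump_amplitude_px=20.0,
        bump_sigma_px=30.0,
        bump_onset_frame=8.0,
        bump_peak_frame=20.0,
        bump_offset_frame=34.0,
        eyeball_left_px=4.0,
        eyeball_right_px=4.0,
        eyeball_onset_frame=6.0,
        eyeball_peak_frame=25.0,
        eyeball_offset_frame=39.0,
        vibration_amplitude_px=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def paper_like_run():
    """Render and fully analyze the clinical-ballpark scene once per session."""
    cfg = make_paper_like_config(seed=1)
    seq, truth = render_sequence(cfg)
    result = analyze_sequence(seq)
    return cfg, seq, truth, result


@pytest.fixture(scope="session")
def paper_like_truth():
    return compute_ground_truth(make_paper_like_config(seed=1))
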