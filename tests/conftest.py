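import numpy as np
import pytest

from ecgseg import BeatParams, PageSpec, RunConfig, render_synthetic_page, segment_image

#: Compact page for unit tests: same 4x4 grid, quarter-scale geometry.
SMALL_BEAT = BeatParams(
    p_amp=4.0, q_amp=-6.0, r_amp=20.0, s_amp=-6.0, t_amp=8.0,
    p_width=4.0, qrs_width=2.0, t_width=6.0, period=90, jitter=2.0,
)


def small_spec(**kwargs) -> PageSpec:
    defaults = dict(
        shape=(310, 500),
        baseline_rows=(40, 115, 190, 265),
        separator_cols=(125, 250, 375),
        beat=SMALL_BEAT,
        seed=0,
    )
    defaults.update(kwargs)
    return PageSpec(**defaults)


#: Tracking windows scaled to the quarter-size grid (75 px lead spacing).
SMALL_CONFIG = RunConfig(apply_crop=False, alpha=36, beta=24, gamma=10)


@pytest.fixture(scope="session")
def no_crop_config() -> RunConfig:
    return RunConfig(apply_crop=False)


@pytest.fixture(scope="session")
def clean_truth():
    """One clean full-size page (thickness 1, no gaps/noise/clutter)."""
    return render_synthetic_page(PageSpec(seed=123))


@pytest.fixture(scope="session")
def clean_result(clean_truth, no_crop_config):
    return segment_image(clean_truth.page, no_crop_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
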