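"""Shared fixtures: synthetic movies and pipeline bundles.

Session-scoped so that the (seconds-long) renders and pipeline runs are
paid once and reused across the module and acceptance tests.
"""

import pytest
from hypothesis import settings

from thrombofret import pipeline as pl
from thrombofret import segment as seg
from thrombofret import synth

settings.register_profile("fixed", derandomize=True, max_examples=50,
                          database=None)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def clean_flow_movie():
    """Default flow on/off scenario with background but all noise off."""
    noise = synth.NoiseModel(shot_noise=False, read_noise_sd=0.0, seed=0)
    stack, gt, schedule = synth.default_flow_movie(seed=0, noise=noise)
    return stack, gt, schedule


@pytest.fixture(scope="session")
def pipeline_bundle():
    """Full default pipeline run (noisy default movie, seed 1)."""
    return pl.run_pipeline(pl.RunConfig(seed=1))


@pytest.fixture(scope="session")
def ca_bundle():
    """Default pipeline run with simultaneous Fura-2 Ca2+ channels."""
    return pl.run_pipeline(pl.RunConfig(simulate={"include_ca": True}, seed=2))


@pytest.fixture(scope="session")
def growth_run():
    """Growth/dissolution movie segmented at the generator-matched threshold."""
    stack, gt, area = synth.default_growth_movie(seed=3)
    thr = synth.consistent_threshold()
    masks = seg.segment_stack(stack, seg.SegmentationParams(threshold=thr))
    table = seg.area_table(masks, stack.dt, stack.pixel_size_um)
    return stack, gt, area, masks, table


def jaccard(a, b) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
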