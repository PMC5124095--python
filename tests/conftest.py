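"""Shared fixtures: calibration, small simulated scan pairs, and the
session-scoped batch of simulated deployments used by the heavier
recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

import barct
from barct.synthetic_data import (
    AccretionPatch,
    BarSimSpec,
    Borehole,
    GrazedRegion,
    make_bar_pair,
    make_batch_specs,
)
from barct.volume_io import CalibrationCurve

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def cal() -> CalibrationCurve:
    """The generator's session calibration: density = 0.01·attn + 0.5."""
    return CalibrationCurve(slope=0.01, intercept=0.5, r_squared=1.0, n_phantoms=4)


def small_modified_spec(seed: int = 3) -> BarSimSpec:
    """A compact block with one of each imposed modification."""
    return BarSimSpec(
        block_dims_cm=(0.8, 0.4, 0.3),
        accretion_patches=[
            AccretionPatch(face="z+", center=(0.3, 0.5), size=(0.3, 0.4), thickness_voxels=4)
        ],
        boreholes=[Borehole(face="x+", entry=(0.5, 0.5), radius_um=220.0, length_um=3000.0)],
        grazed_regions=[GrazedRegion(face="z+", depth_voxels=3, footprint=(0.55, 0.9, 0.15, 0.85))],
        microboring_density_drop_frac=0.08,
        rigid_offset=((2.0, -1.5, 1.0), (0.8, -0.5, 0.4)),
        noise_sd=3.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_pair(cal):
    """(spec, pre, post, truth, analysis) for one compact modified block."""
    spec = small_modified_spec()
    pre, post, truth = make_bar_pair(spec)
    analysis = barct.analyze_bar_pair(pre, post, cal)
    return spec, pre, post, truth, analysis


@pytest.fixture(scope="session")
def batch_results(cal):
    """Ten varied simulated deployments run through the full pipeline.

    Returns (results, elapsed_seconds) where each result is
    (spec, truth, analysis).
    """
    import time

    t0 = time.perf_counter()
    out = []
    for spec in make_batch_specs(n=10, seed=11):
        pre, post, truth = make_bar_pair(spec)
        analysis = barct.analyze_bar_pair(pre, post, cal)
        out.append((spec, truth, analysis))
    return out, time.perf_counter() - t0
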