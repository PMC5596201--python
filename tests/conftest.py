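"""Shared fixtures: one default phantom built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from radpathcorr import phantom as ph
from radpathcorr import pipeline


@pytest.fixture(scope="session")
def spec0() -> ph.PhantomSpec:
    return pipeline.make_spec(0)


@pytest.fixture(scope="session")
def gt0(spec0) -> ph.GroundTruth:
    return ph.build_phantom(spec0)


@pytest.fixture(scope="session")
def table0() -> ph.GradientTable:
    return ph.default_gradient_table()


@pytest.fixture(scope="session")
def weighted0(gt0) -> dict:
    return ph.render_weighted_images(gt0)


@pytest.fixture(scope="session")
def frames0(gt0, table0) -> list:
    return ph.simulate_dwi(gt0, table0)


@pytest.fixture(scope="session")
def noiseless_frames0(gt0, table0) -> list:
    return ph.simulate_dwi(gt0, table0, sigma=0.0)


@pytest.fixture(scope="session")
def hist_labels0(gt0) -> np.ndarray:
    return ph.hist_label_image(gt0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
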