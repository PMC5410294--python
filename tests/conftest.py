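import numpy as np
import pytest

from endosirna import fixtures as fx

STUDY_SEED = 5


@pytest.fixture(scope="session")
def study_result(tmp_path_factory):
    """Full noise-free three-library study fixture, run once per session."""
    td = tmp_path_factory.mktemp("study")
    return fx.run_fixture(fx.default_study_spec(STUDY_SEED), td, seed=STUDY_SEED,
                          outdir=td / "out")


@pytest.fixture(scope="session")
def fig1c_result(tmp_path_factory):
    td = tmp_path_factory.mktemp("fig1c")
    return fx.run_fixture(fx.fig1c_hairpin_spec(1), td, seed=1)


@pytest.fixture(scope="session")
def fig2c_result(tmp_path_factory):
    td = tmp_path_factory.mktemp("fig2c")
    return fx.run_fixture(fx.fig2c_l1_spec(1), td, seed=1)


@pytest.fixture(scope="session")
def plce1_result(tmp_path_factory):
    td = tmp_path_factory.mktemp("plce1")
    return fx.run_fixture(fx.plce1_ic_spec(1), td, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
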