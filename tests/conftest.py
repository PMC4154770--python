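import numpy as np
import pytest

from grasslandsem.fit import SampleMoments
from grasslandsem.io import AnalysisConfig
from grasslandsem.models import default_ra_model, default_rh_model
from grasslandsem.synth import default_truth, simulate_plot_table, write_fixture_dir


@pytest.fixture(scope="session")
def rh_spec():
    return default_rh_model()


@pytest.fixture(scope="session")
def ra_spec():
    return default_ra_model()


@pytest.fixture(scope="session")
def rh_truth():
    return default_truth("rh")


@pytest.fixture(scope="session")
def ra_truth():
    return default_truth("ra")


@pytest.fixture(scope="session")
def rh_moments(rh_truth):
    """Moments of 500 plots simulated from the RH truth (fixed seed)."""
    table = simulate_plot_table(rh_truth, 500, seed=11)
    S = np.cov(table.to_numpy(), rowvar=False, ddof=1)
    return SampleMoments(rh_truth.spec.observed, S, 500)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small synthetic study on disk: 2 regions x 2 years x 20 plots."""
    outdir = tmp_path_factory.mktemp("study")
    config = AnalysisConfig(regions=["ALB", "HAI"], seed=7)
    truth = default_truth("ra", plots_per_region=20, regions=("ALB", "HAI"), seed=7)
    realized = write_fixture_dir(outdir, truth=truth, config=config, seed=7)
    return outdir, config, realized
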