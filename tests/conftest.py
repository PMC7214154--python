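import numpy as np
import pandas as pd
import pytest

from mirpoc.simulate import SimulationConfig, write_study


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, default_config):
    """A complete synthetic study written to disk once per session."""
    outdir = tmp_path_factory.mktemp("study")
    write_study(default_config, outdir)
    return outdir


def nb_counts(mean, alpha, size, rng) -> np.ndarray:
    """Independent NB sampler for building oracle datasets in tests."""
    mean = np.asarray(mean, float)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(np.broadcast_to(r, np.shape(p)) if np.ndim(p) else r, p, size=size)


@pytest.fixture
def two_group_counts():
    """Null NB counts (no group difference), 300 features x 2x20 samples."""
    rng = np.random.default_rng(42)
    base = np.exp(rng.uniform(np.log(20), np.log(800), 300))
    mat = nb_counts(np.tile(base[:, None], (1, 40)), 0.1, None, rng)
    counts = pd.DataFrame(mat, index=[f"f{i}" for i in range(300)], columns=[f"s{i}" for i in range(40)])
    groups = pd.Series(["A"] * 20 + ["B"] * 20, index=counts.columns)
    return counts, groups
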