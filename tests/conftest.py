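import numpy as np
import pandas as pd
import pytest

from dielarray import synth
from dielarray.design import make_design


@pytest.fixture(scope="session")
def design10():
    """The open-ocean style design: 10 time points, 3 h apart, duplicates."""
    return make_design(10, 3, 2, 6.0, 12.0)


@pytest.fixture(scope="session")
def small_dataset(design10):
    """300-gene fixture with faint, diel and flat genes plus ERCC spikes."""
    truths = synth.make_truths(300, seed=1)
    expr = synth.simulate_expression(design10, truths, noise_sd=0.5, seed=7)
    ercc = synth.spike_ercc(design10, noise_sd=0.1, seed=3)
    return {"design": design10, "truths": truths, "expr": expr, "ercc": ercc}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, design10):
    """A complete on-disk fixture directory for pipeline tests."""
    out = tmp_path_factory.mktemp("fixture")
    truths = synth.make_truths(150, seed=2)
    expr = synth.simulate_expression(design10, truths, 0.5, seed=8)
    probes, ann = synth.expand_to_probes(expr, truths, seed=9)
    ercc = synth.spike_ercc(design10, noise_sd=0.1, seed=10)
    ctd = synth.simulate_ctd(design10)
    synth.write_fixture(out, design10, truths, probes, ann, ercc, ctd,
                        manifest={"seed": 2})
    return out


def truth_series(truths, attr):
    return pd.Series({t.gene_id: getattr(t, attr) for t in truths})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
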