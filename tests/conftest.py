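import numpy as np
import pytest

import datdyn as dd


@pytest.fixture
def rng():
    return dd.make_rng(1, "tests")


@pytest.fixture
def wt_params():
    return dd.genotype_params("WT")


@pytest.fixture
def mut_params():
    return dd.genotype_params("MUT")


def make_ts(x, fs=20.0, unit="au", t0=0.0):
    return dd.TimeSeries(x=np.asarray(x, dtype=float), fs=fs, t0=t0, unit=unit)
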