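import logging

import numpy as np
import pandas as pd
import pytest

from methalc.containers import MethylationMatrix
from methalc.scoring import CoefficientFamily, CoefficientSet, default_family

logging.getLogger("methalc").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def family():
    return default_family()


@pytest.fixture
def tiny_family():
    """Hand-built nested family: 2 CpGs inside 4."""
    small = CoefficientSet("tiny.2", {"cg01": 2.0, "cg02": -1.0})
    large = CoefficientSet("tiny.4", {"cg01": 2.0, "cg02": -1.0, "cg03": 0.5, "cg04": 1.5})
    return CoefficientFamily((small, large))


@pytest.fixture
def make_matrix(rng):
    """Factory for random raw beta matrices."""

    def _make(n_samples=20, cpgs=("cg01", "cg02", "cg03", "cg04"), time_point="t0"):
        values = pd.DataFrame(
            rng.uniform(0.05, 0.95, (n_samples, len(cpgs))),
            index=[f"s{i:04d}" for i in range(n_samples)],
            columns=list(cpgs),
        )
        return MethylationMatrix(values, time_point=time_point)

    return _make


@pytest.fixture
def make_covars(rng):
    def _make(sample_ids, n_wbc=3, smoking=False):
        n = len(sample_ids)
        df = pd.DataFrame(
            {
                "age": rng.normal(50, 5, n),
                "sex": rng.integers(0, 2, n),
                "bmi": rng.normal(25, 4, n),
            },
            index=sample_ids,
        )
        if n_wbc:
            props = rng.dirichlet(np.full(n_wbc, 5.0), size=n)
            for k in range(n_wbc):
                df[f"wbc_c{k}"] = props[:, k]
        if smoking:
            df["smoking"] = rng.integers(0, 2, n)
        return df

    return _make
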