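import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirlens.core import ExpressionMatrix
from mirlens.synthetic import SyntheticDesign, generate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_matrix(values, feature_ids=None, n_case=None):
    """Build an ExpressionMatrix from a 2D array, first half of columns = case."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    n_case = n_samp // 2 if n_case is None else n_case
    feature_ids = feature_ids or [f"f{i + 1}" for i in range(n_feat)]
    samples = [f"KO{i + 1}" for i in range(n_case)] + [
        f"C{i + 1}" for i in range(n_samp - n_case)
    ]
    groups = {s: ("case" if s.startswith("KO") else "control") for s in samples}
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=samples), groups
    )


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale design with uniform strong effects for fast recovery tests."""
    return SyntheticDesign(
        n_mirnas=150,
        n_mrnas=600,
        planted_up_mirnas={f"mir-u{i:02d}": 2.0 for i in range(1, 8)},
        planted_down_mirnas={f"mir-d{i:02d}": 2.0 for i in range(1, 5)},
        mirnas_without_predictions=("mir-u01",),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design, tmp_path_factory):
    out = tmp_path_factory.mktemp("synth-small")
    return generate(small_design, out)
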