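import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from txclock import (CountMatrix, build_reference, make_regression_fixture)


@pytest.fixture(scope="session")
def fixture_data():
    """The frozen end-to-end dataset: 30 signal + 20 noise genes + filler,
    10 grid ages x 4 samples, library size 1e5."""
    return make_regression_fixture()


@pytest.fixture(scope="session")
def fixture_model(fixture_data):
    cm, ann, _ = fixture_data
    return build_reference(cm, ann)


@pytest.fixture
def tiny_counts():
    """A 3-gene x 2-sample matrix for I/O and normalization checks."""
    return CountMatrix(["g1", "g2", "g3"], ["s1", "s2"],
                       np.array([[2, 0], [3, 1], [5, 9]]))
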