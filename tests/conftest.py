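import warnings

import numpy as np
import pytest

from dtameta import fit, load_fixture_panel
from dtameta.study_data import Study2x2, StudyPanel


def make_panel(rows, label="toy"):
    """Build a panel from (tp, fp, fn, tn) tuples."""
    return StudyPanel(
        [
            Study2x2(
                study_id=f"s{i}", author="toy", year=2020, b_value=2000,
                tp=tp, fp=fp, fn=fn, tn=tn, design="prospective",
            )
            for i, (tp, fp, fn, tn) in enumerate(rows)
        ],
        label=label,
    )


@pytest.fixture(scope="session")
def table3():
    return load_fixture_panel()


@pytest.fixture(scope="session")
def table3_fit(table3):
    res = fit(table3, n_quad=21)
    assert res.converged
    return res


@pytest.fixture
def toy4():
    return make_panel([(40, 3, 3, 30), (62, 1, 16, 34), (23, 2, 4, 18), (38, 3, 5, 34)])


@pytest.fixture(autouse=True)
def _quiet_small_panel_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* studies")
        yield
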