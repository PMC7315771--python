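import numpy as np
import pytest

from catgrm import (
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    fit_mml_em,
    generate_respondents,
    load_packaged_bank,
)


@pytest.fixture(scope="session")
def bank68() -> ItemBank:
    """The packaged 68-item calibrated GRM bank."""
    return load_packaged_bank()


@pytest.fixture(scope="session")
def truth_bank10() -> ItemBank:
    """A known 10-item GRM truth used for parameter-recovery checks:
    slopes 0.9..1.8, 4 ordered categories, thresholds spread over [-2, 2]."""
    items = []
    for j in range(10):
        c = -1.0 + 2.0 * j / 9.0
        items.append(ItemParameters(f"t{j + 1}", "GRM", 4, 0.9 + 0.1 * j,
                                    [c - 1.0, c, c + 1.0]))
    return ItemBank(items)


@pytest.fixture(scope="session")
def recovery_data(truth_bank10):
    """n=1000 responses simulated from the truth bank (fixed seed)."""
    respondents = generate_respondents(1000, truth_bank10, seed=20240)
    codes = np.array([r.responses for r in respondents], dtype=float)
    return ResponseMatrix(codes, truth_bank10.ids), respondents


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    """GRM refit of the recovery data, shared across recovery checks."""
    rm, _ = recovery_data
    return fit_mml_em(rm, model="GRM")


@pytest.fixture()
def grm_item() -> ItemParameters:
    return ItemParameters("demo", "GRM", 3, 2.0, [-0.5, 1.0])
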