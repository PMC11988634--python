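import pytest

from eiipkit import parse_formula

# Pesticides with published descriptor values, used across the suite.
REFERENCE_FORMULAS = {
    "boscalid": "C18H12Cl2N2O",
    "abamectin_B1A": "C48H72O14",
    "abamectin_B1B": "C47H70O14",
    "chlorantraniliprole": "C18H14BrCl2N5O2",
}


@pytest.fixture(scope="session")
def reference_compositions():
    return {name: parse_formula(f) for name, f in REFERENCE_FORMULAS.items()}
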