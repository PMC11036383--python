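import matplotlib

matplotlib.use("Agg")

import pytest

from isowash import default_species_table, make_scenario, simulate_filtration


@pytest.fixture(scope="session")
def db():
    return default_species_table()


@pytest.fixture(scope="session")
def mfa2():
    """MFA experiment 2: diglyme-water liquor, heptane wash, 600 mbar."""
    return make_scenario("mfa_expt2")


@pytest.fixture(scope="session")
def mfa2_cake(mfa2):
    """Saturated dryland cake of MFA experiment 2."""
    return simulate_filtration(mfa2).end_state
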