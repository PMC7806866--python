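import numpy as np
import pytest

import cyclekin as ck

#: Initial-guess rates from Steel's formulas, as printed for IMR90.
STEEL_RATES = ck.RateParameters(k1=0.0496, g=0.0740, k2=0.2272, b=3.2577)


@pytest.fixture(scope="session")
def table1():
    return ck.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return ck.load_fixture("table2")


@pytest.fixture(scope="session")
def steel_init(table1):
    """Steel's-formula rates recomputed from the sham averages."""
    return ck.steel_rates(ck.average_fractions(table1), 38.4)


@pytest.fixture(scope="session")
def sham_fit(table1):
    """The chi-square fit of SDD fractions to the sham reference data.

    Session-scoped: several tests reuse the fitted baseline.
    """
    return ck.fit_unperturbed(table1)


def random_rates(rng: np.random.Generator) -> ck.RateParameters:
    """A random parameter set inside the calibration bounds."""
    lo_hi = ck.PAPER_BOUNDS
    return ck.RateParameters(
        k1=rng.uniform(*lo_hi["k1"]), g=rng.uniform(*lo_hi["g"]),
        k2=rng.uniform(*lo_hi["k2"]), b=rng.uniform(*lo_hi["b"]))
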