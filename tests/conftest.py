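import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lifemr import GenerativeSpec, InstrumentTable, example_instrument_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def instrument() -> InstrumentTable:
    return example_instrument_table()


@pytest.fixture()
def two_snp_instrument() -> InstrumentTable:
    return InstrumentTable(
        pd.DataFrame(
            {
                "snp": ["rs1", "rs2"],
                "effect_allele": ["A", "G"],
                "other_allele": ["G", "A"],
                "beta": [0.1, 0.2],
                "se": [0.01, 0.02],
                "eaf": [0.3, 0.6],
            }
        ),
        apoe_ids=(),
    )


def make_spec(instrument, **kwargs) -> GenerativeSpec:
    defaults = dict(n_samples=2000, theta={"m1": 0.1}, noise_sd=1.0, seed=0)
    defaults.update(kwargs)
    return GenerativeSpec(instrument=instrument, **defaults)


@pytest.fixture()
def spec_factory(instrument):
    def _make(**kwargs):
        return make_spec(instrument, **kwargs)

    return _make
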