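import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import seedwebs as sw

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: fixed effects of the published interaction-cost fit
PRINTED_COEFS = (-14.2177, 8.739, 1.720, -1.278)


@pytest.fixture
def coefs() -> sw.CostModelCoefficients:
    return sw.CostModelCoefficients()


@pytest.fixture
def config() -> sw.PipelineConfig:
    return sw.PipelineConfig()


@pytest.fixture
def single_link_field():
    """A field with one granivore and one seed: the whole chain is computable
    by hand. Carabid length is chosen so the allometry yields exactly 10 mg."""
    length = math.exp((math.log(10.0) + 3.4) / 2.6)
    seed_traits = pd.DataFrame(
        {
            "genus": ["Solo"],
            "species": ["Solo species"],
            "seed_mass_mg": [1.0],
            "energy_kJ_per_g": [18.77],
        }
    )
    carabid_traits = pd.DataFrame(
        {
            "species": ["Harpalus solo"],
            "tribe": ["Harpalini"],
            "genus": ["Harpalus"],
            "length_min_mm": [length],
            "length_max_mm": [length],
        }
    )
    census = sw.FieldCensus(
        field_id="SL01",
        seed_counts={"Solo": 100},
        carabid_counts={"Harpalus solo": 1},
    )
    return seed_traits, carabid_traits, census


def hand_single_link_chain():
    """Independent hand computation of the r->F->C->I->P chain for the
    single-link field, straight from the printed constants."""
    b0, b1, b2, b3 = PRINTED_COEFS
    mi, mj, di, nj = 1.0, 10.0, 100.0, 1.0
    log_h = b0 + b1 * mi ** (1 / 3) + b2 * math.log(mj) + b3 * mi ** (1 / 3) * math.log(mj)
    e_i = mi / 1000.0 * 18.77
    r = e_i / math.exp(log_h)
    f = 1.0
    e_j = 0.51 * mj * 18.77 / 1000.0
    c = f * e_j / (f * e_i)
    d_j = nj * mj ** -0.51
    i = c * d_j
    p = i / di
    return {"log_h": log_h, "r": r, "F": f, "C": c, "D_j": d_j, "I": i, "P": p}


@pytest.fixture
def fixture_field():
    return sw.fixture_community()
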