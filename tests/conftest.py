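import numpy as np
import pytest

from crownburden import MutationParams, allocate_time, make_crown

# 2*G*mu*T = 10 with these values: a ~0.8 Gbp diploid genome mutating at
# 5e-10 per base per year over a 25-year crown.
GENOME_SIZE = 4.0e8
MU = 5.0e-10
TOTAL_TIME = 25.0
SUPPLY_TIMES_T = 2 * GENOME_SIZE * MU * TOTAL_TIME  # 2*G*mu*T = 10


@pytest.fixture
def params3():
    return MutationParams(GENOME_SIZE, MU, asc_count=3)


@pytest.fixture
def crown5():
    return make_crown(5)


@pytest.fixture
def alloc5_uniform(crown5):
    return allocate_time(crown5, 0.0, TOTAL_TIME)
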