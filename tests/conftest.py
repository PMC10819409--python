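import numpy as np
import pytest

from crisprqc import GuideQuery, SearchProfile
from crisprqc.fixtures import simulate_genome


@pytest.fixture
def cas9_guide():
    return GuideQuery("kcnq2-g1", "ACCCCCAGACCTGGAACGGC", "NGG", "three_prime", "Cas9")


@pytest.fixture
def cas12a_guide():
    return GuideQuery("ash1l-g1", "ATCAGGAAAGCAGTGTTGGC", "TTTV", "five_prime", "Cas12a")


@pytest.fixture
def small_genome():
    return simulate_genome(11, [3000])


def random_guide(seed: int, length: int = 20) -> GuideQuery:
    rng = np.random.default_rng(seed)
    return GuideQuery(
        f"rg{seed}", "".join(rng.choice(list("ACGT"), size=length)), "NGG", "three_prime"
    )


PROFILES = {
    "strict": SearchProfile("strict", 3, 0),
    "loose": SearchProfile("loose", 5, 0),
    "bulged": SearchProfile("bulged", 5, 2),
}
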