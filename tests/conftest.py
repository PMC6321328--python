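import numpy as np
import pytest
from hypothesis import settings

from cliffscape import ActivityTable, CompoundRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_table() -> ActivityTable:
    """Four hand-picked small molecules with hand-assigned activities."""
    return ActivityTable(
        compounds=[
            CompoundRecord("a", "c1ccccc1O", {"T1": 6.0, "T2": 5.0}),
            CompoundRecord("b", "c1ccccc1N", {"T1": 8.5, "T2": 5.2}),
            CompoundRecord("c", "CCCCCC", {"T1": 6.1, "T2": 7.9}),
            CompoundRecord("d", "c1ccccc1O", {"T1": 6.0, "T2": 5.0}),
        ],
        targets=["T1", "T2"],
    )


def random_table(rng: np.random.Generator, n: int, targets=("T1", "T2")) -> ActivityTable:
    """A random-activity table over a pool of simple valid structures."""
    pool = [
        "c1ccccc1", "c1ccccc1O", "c1ccccc1N", "c1ccccc1C", "c1ccncc1",
        "CCO", "CCN", "CCCC", "CC(=O)O", "CC(=O)N", "c1ccc2ncccc2c1",
        "C1CCNCC1", "C1CCOC1", "CC(C)O", "CCOCC",
    ]
    idx = rng.choice(len(pool), size=n, replace=n > len(pool))
    return ActivityTable(
        compounds=[
            CompoundRecord(
                str(k + 1),
                pool[i],
                {t: float(rng.uniform(4.0, 9.0)) for t in targets},
            )
            for k, i in enumerate(idx)
        ],
        targets=list(targets),
    )
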