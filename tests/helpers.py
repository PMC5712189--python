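"""Small shared helpers for the test suite."""

import numpy as np


def random_genome(rng: np.random.Generator, n: int, gc: float = 0.6) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
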