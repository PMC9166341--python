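"""Deterministic child-seed derivation.

All stochastic stages derive integer child seeds from a master seed plus
a tuple of structural indices (round, point, subject, repeat, ...) via
numpy's SeedSequence, so any part of a run can be reproduced in
isolation and runs may execute concurrently yet match serial execution.
"""

from __future__ import annotations

import numpy as np


def derive_seed(*keys: int) -> int:
    """A stable integer seed (< 2**31) from a tuple of integer keys."""
    ss = np.random.SeedSequence([int(k) for k in keys])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
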