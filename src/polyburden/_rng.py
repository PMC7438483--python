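"""Named random substreams derived from a single master seed.

Every source of randomness in the package draws from a substream obtained via
:func:`substream`, so individual stages can be regenerated independently and
a fixed master seed yields byte-identical outputs.
"""

from __future__ import annotations

import numpy as np

# stable stream identifiers; never renumber, only append
_STREAMS = {
    "frequencies": 11,
    "genotypes": 12,
    "phenotypes": 13,
    "summary": 14,
    "matching": 15,
    "missingness": 16,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    try:
        key = _STREAMS[name]
    except KeyError:
        raise ValueError(f"unknown substream {name!r}; known: {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
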