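"""Deterministic named random substreams.

All randomness in the package flows from a single master seed.  Each
consumer derives an independent generator from (seed, *labels), so results
do not depend on the order in which analyses are executed.
"""

from __future__ import annotations

import hashlib

import numpy as np

_SEP = "\x1f"


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator keyed by the master seed and a tuple of labels.

    The same (seed, labels) always yields the same stream; different labels
    yield statistically independent streams (SeedSequence spawn keys derived
    from a SHA-256 of the labels).
    """
    digest = hashlib.sha256(_SEP.join(str(x) for x in labels).encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
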