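"""Named random substreams.

Every stochastic draw in the simulators comes from a substream identified by a
stable name, so adding a parameter (or reordering draws in one stage) never
silently shifts the draws of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a tuple of stream names.

    Names are hashed with CRC32 (stable across platforms and Python runs,
    unlike ``hash``) into the SeedSequence spawn key.
    """
    key = tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
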