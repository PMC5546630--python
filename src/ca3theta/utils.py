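"""Small shared helpers: named deterministic random substreams."""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named source of randomness.

    All randomness in a run flows from one master seed; components (wiring,
    weights, initial potentials, inputs, ...) draw from named substreams so
    any one can be varied independently of the others.
    """
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(key,)))
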