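"""Named random substreams.

All stochastic steps of the pipeline draw from independent substreams of
one master seed, so that reruns are bit-identical and the outcome of one
step never depends on how many random numbers another step consumed.
"""

from __future__ import annotations

import zlib

import numpy as np


def _token_to_int(token) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    return zlib.crc32(str(token).encode("utf-8"))


def substream(seed: int, *tokens) -> np.random.Generator:
    """Generator for the substream named by ``tokens`` under ``seed``.

    Tokens may be strings or integers; the same (seed, tokens) always
    yields the same stream, and distinct token tuples yield streams that
    are independent for practical purposes (numpy ``SeedSequence``).
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_token_to_int(t) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))
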