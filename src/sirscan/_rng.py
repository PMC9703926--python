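"""Named random substreams derived from one global seed.

Every stochastic stage draws from its own substream so that stages can be
re-run independently without perturbing each other, and the whole pipeline is
bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stage under the given global seed.

    The stage name is hashed (CRC32, stable across processes and Python
    versions) and mixed with the seed through a SeedSequence spawn key.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,))
    return np.random.default_rng(ss)
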