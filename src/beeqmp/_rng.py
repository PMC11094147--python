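"""Named random substreams so one pipeline seed drives every stochastic stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for a named substream of the master seed.

    Each stage (``"synth"``, ``"qmp"``, ``"perm"``, ``"ml"``, ...) draws from
    its own stream, so rerunning one stage never perturbs another and every
    figure of merit is replayable from the single pipeline seed.
    """
    if seed is None:
        raise ValueError("substream requires an explicit integer seed")
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
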