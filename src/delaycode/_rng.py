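"""Named random substreams derived from one master seed.

Every stochastic stage draws from a generator keyed by (seed, *tokens), so
any single unit, trial or decoding repeat is reproducible in isolation and
adding entities never perturbs the streams of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *tokens) -> np.random.Generator:
    key = ":".join(str(t) for t in tokens).encode()
    digest = hashlib.blake2b(key, digest_size=8, key=str(seed).encode()).digest()
    derived = int.from_bytes(digest, "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), derived]))
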