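"""Reproducible seed derivation.

Every stochastic stage derives its seeds from a master seed plus a stream
label, so a whole study is reproducible from one integer and any stage can
be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _as_int(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(str(part).encode())


def child_seed(master_seed: int, *stream) -> int:
    """Derive a deterministic 31-bit child seed from a master seed and labels.

    Labels may be ints or strings (e.g. subject id, segment index,
    surrogate index); strings are CRC-hashed.
    """
    ss = np.random.SeedSequence([_as_int(master_seed)] + [_as_int(p) for p in stream])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(master_seed: int, *stream) -> np.random.Generator:
    """A numpy Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *stream))
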