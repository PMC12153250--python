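"""Seeding helpers.

One integer seed fully determines every simulation in the package.  Distinct
purposes (calibration, power, diagnostics, ...) get independent streams by
folding a stable hash of the purpose string into the seed sequence, so runs
that share a seed never accidentally share randomness across tasks.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for"]


def rng_for(seed: int | np.random.Generator | None, purpose: str = "") -> np.random.Generator:
    """Return a Generator for ``(seed, purpose)``.

    Passing an existing Generator returns it unchanged (caller manages state);
    ``None`` gives fresh OS entropy.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        return np.random.default_rng()
    entropy = [int(seed) & 0x7FFFFFFF]
    if purpose:
        entropy.append(zlib.crc32(purpose.encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))
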