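"""Shared constants and seeding helpers.

Every stochastic routine in the package derives its generator from an
integer seed plus a small tuple of tags, so that the whole pipeline is a
pure function of one global seed.
"""

from __future__ import annotations

import zlib

import numpy as np

#: Canonical class order used everywhere (tie-breaks favour the smaller index).
CLASSES: tuple[str, str, str] = ("Normal", "Myopathy", "Neuropathy")


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag)
    if isinstance(tag, str):
        return zlib.crc32(tag.encode("utf-8"))
    raise TypeError(f"seed tag must be int or str, got {type(tag).__name__}")


def seed_sequence(seed: int, *tags) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed)] + [_tag_to_int(t) for t in tags])


def derive_seed(seed: int, *tags) -> int:
    """Deterministically derive a child seed (< 2**31) from seed + tags."""
    return int(seed_sequence(seed, *tags).generate_state(1)[0] % (2**31))


def rng_from(seed: int, *tags) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(seed, *tags))
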