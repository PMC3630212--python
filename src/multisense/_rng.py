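"""Purpose-keyed random number streams.

Every source of randomness in the package is drawn from a stream obtained
via :func:`seed_stream`, so that changing the amount of randomness consumed
by one stage (e.g. training) does not perturb any other stage (e.g. the
test-data draw).

Registered purpose tags
-----------------------
``train-data``, ``test-data``, ``init``, ``gibbs``, ``decode``,
``calibrator``.  New tags may be introduced freely; independence only
requires that distinct stages use distinct tags.
"""

from __future__ import annotations

import zlib

import numpy as np

KNOWN_TAGS = (
    "train-data",
    "test-data",
    "init",
    "gibbs",
    "decode",
    "calibrator",
)


def seed_stream(master_seed: int, purpose_tag: str) -> np.random.Generator:
    """Return an independent generator keyed by (master seed, purpose tag)."""
    if not isinstance(master_seed, (int, np.integer)):
        raise TypeError(f"master_seed must be an integer, got {master_seed!r}")
    key = zlib.crc32(purpose_tag.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return np.random.default_rng(ss)
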