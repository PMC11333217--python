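"""Named child random streams derived from one root seed.

Every stochastic stage of the pipeline draws from its own stream so that
adding or re-ordering stages never perturbs the draws of another stage.
Streams are keyed by a stable CRC32 hash of the stage name.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed_sequence(root_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic child SeedSequence for a named pipeline stage."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence(root_seed, spawn_key=(key,))


def child_rng(root_seed: int, stage: str) -> np.random.Generator:
    """A Generator seeded for one named stage of the pipeline."""
    return np.random.default_rng(child_seed_sequence(root_seed, stage))


def child_int_seed(root_seed: int, stage: str) -> int:
    """A plain integer seed (< 2**31) derived for a named stage."""
    return int(child_seed_sequence(root_seed, stage).generate_state(1)[0] % (2**31))
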