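"""Named child RNG streams derived from one master seed.

Every stochastic stage (cohort draws, residual error, replicate etas)
pulls its generator from here so that a single master seed fully
determines a run while the streams stay statistically independent.
"""

import zlib

import numpy as np


def child_seed_sequence(master_seed: int, name: str) -> np.random.SeedSequence:
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed_sequence(master_seed, name))
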