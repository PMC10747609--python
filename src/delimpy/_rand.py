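"""Deterministic seed fan-out.

A single master seed drives the whole pipeline; each named stage receives an
independent child seed derived from (master, stage name) so that adding or
reordering stages never perturbs the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, stage: str, counter: int = 0) -> int:
    """A 31-bit child seed keyed by stage name and an optional counter."""
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, tag, int(counter)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(master: int, stage: str, counter: int = 0) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, stage, counter))
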