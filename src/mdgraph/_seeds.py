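"""Seed fan-out: one master seed, independent per-stage child seeds."""

from __future__ import annotations

import numpy as np

# Stable stage tags so a stage can be rerun in isolation with the same child seed.
_STAGE_TAGS = {
    "simulate": 1,
    "graph": 2,
    "split": 3,
    "sage": 4,
    "boost": 5,
    "predict": 6,
}


def child_seed(master: int, stage: str, index: int = 0) -> int:
    """Derive a deterministic child seed < 2**31 for a named pipeline stage."""
    tag = _STAGE_TAGS.get(stage)
    if tag is None:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(_STAGE_TAGS)}")
    ss = np.random.SeedSequence([int(master), tag, int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(master: int, stage: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, stage, index))
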