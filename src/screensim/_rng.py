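"""Labeled random-number substreams derived from a single master seed.

Each pipeline stage draws from its own ``numpy`` Generator so that a stage
is individually reproducible regardless of which other stages ran before it.
"""

from __future__ import annotations

import numpy as np

#: Fixed label -> spawn-key offsets. Never renumber; doing so silently
#: changes every downstream simulation.
STREAM_OFFSETS: dict[str, int] = {
    "cohort": 0,
    "ai_first": 1,
    "ai_second": 2,
    "ai_triage": 3,
    "split": 4,
    "scratch": 5,
}


def substream(seed: int, label: str) -> np.random.Generator:
    """Return the dedicated Generator for *label* under master *seed*."""
    try:
        offset = STREAM_OFFSETS[label]
    except KeyError:
        raise ValueError(
            f"unknown RNG stream label {label!r}; known: {sorted(STREAM_OFFSETS)}"
        ) from None
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(offset,))
    return np.random.default_rng(ss)
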