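"""Small shared helpers: half-up rounding and seed-stream derivation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (the "schoolbook" rule).

    Python's built-in round() is banker's rounding, which would turn
    22.45 into 22.4; printed percentages in lab reports use half-up.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# Fixed per-stage offsets so each simulation stage draws from its own
# stream derived from one master seed.
_STAGE_KEYS = {
    "annotation": 1,
    "expression": 2,
    "alignments": 3,
    "qpcr": 4,
    "image": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, derived from one master seed."""
    if stage not in _STAGE_KEYS:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_KEYS[stage],))
    return np.random.default_rng(ss)
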