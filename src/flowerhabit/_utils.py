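"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (printed-table convention), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def stable_stream_seed(seed: int, *tags) -> np.random.SeedSequence:
    """Derive a child SeedSequence from a global seed and string/int tags.

    Uses a cryptographic hash of the tag tuple so sub-streams are independent of
    iteration order and stable across platforms and runs.
    """
    import hashlib

    h = hashlib.sha256(("\x1f".join(str(t) for t in tags)).encode()).digest()
    words = [int.from_bytes(h[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.SeedSequence(entropy=[int(seed)] + words)
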