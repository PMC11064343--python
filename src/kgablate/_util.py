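"""Small shared helpers: deterministic seed derivation and rounding."""

from __future__ import annotations

import hashlib
import math


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up (never banker's)."""
    return int(math.floor(x + 0.5))


def derive_seed(master: int, *labels: object) -> int:
    """Derive a stage-specific RNG seed from a master seed and a label path.

    Stable across processes and Python versions (sha256, not ``hash``), and
    always below 2**31 so it is safe for any RNG backend.
    """
    key = "|".join([str(int(master))] + [str(lab) for lab in labels])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
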