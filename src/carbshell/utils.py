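"""Small shared helpers: deterministic rounding, hashing, logging setup."""

from __future__ import annotations

import hashlib
import json
import logging
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int) -> float:
    """Round to *ndigits* decimals with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; the tabulated
    statistics in this package are defined with the conventional
    half-away-from-zero rule, so all reported percents/ratios go through
    here.
    """
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-ndigits)
    # repr() round-trips the shortest decimal representation of the float,
    # avoiding artefacts like 0.575 -> 0.5749999999999999556.
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
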