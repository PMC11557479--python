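"""Small shared helpers: half-up rounding and the package logger."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

logger = logging.getLogger("saturn_norms")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Report tables and rank formulas need arithmetic (half-up) rounding;
    Python's builtin ``round`` is banker's and float formatting can drop a
    tie below the boundary (0.105 -> "0.10"). Routing through ``Decimal(str(x))``
    keeps the printed decimal value authoritative.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_half_up(x: float, ndigits: int) -> str:
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))
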