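"""Small shared helpers: rounding and string normalisation."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_WS = re.compile(r"\s+")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed report tables).

    Python's built-in round() is banker's rounding; tallied percentages such as
    51.575 must print as 51.58, not 51.57.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def normalize_term(s: str) -> str:
    """Case-fold and collapse internal whitespace for name/term matching."""
    return _WS.sub(" ", s.strip()).casefold()
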