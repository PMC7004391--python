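"""Small reporting helpers for count roll-ups."""

from __future__ import annotations

import math


def percent(count: int, total: int) -> int:
    """Integer-rounded percentage (half away from zero)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def percent_sig(count: int, total: int, sig: int = 2) -> float:
    """Percentage rounded to ``sig`` significant digits, as printed in
    summary tables (e.g. 26/7646 -> 0.34, 1392/10404 -> 13.0)."""
    if total <= 0:
        raise ValueError("total must be positive")
    x = 100.0 * count / total
    if x == 0:
        return 0.0
    digits = sig - 1 - int(math.floor(math.log10(abs(x))))
    return round(x, digits)
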