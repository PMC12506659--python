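"""Small unit-aware rate comparisons.

Used to check claims of the form "activity A is n orders of magnitude
weaker than activity B" between product-formation rates quoted in
different concentration units (e.g. 2.8 μM/min vs 0.14 nM/min).
"""

from __future__ import annotations

import math
import re

__all__ = ["parse_rate", "orders_of_magnitude"]

_PREFIX = {"": 1.0, "m": 1e-3, "u": 1e-6, "µ": 1e-6, "μ": 1e-6, "n": 1e-9, "p": 1e-12, "f": 1e-15}
_PER_MIN = {"min": 1.0, "s": 60.0, "sec": 60.0, "h": 1.0 / 60.0, "hr": 1.0 / 60.0}

_RATE_RE = re.compile(
    r"^\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*([mnpfuµμ]?)M\s*/\s*(min|sec|s|hr|h)\s*$"
)


def parse_rate(text: str) -> float:
    """Parse a concentration rate like ``"2.8 uM/min"`` into M/min."""
    m = _RATE_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse rate {text!r} (expected e.g. '2.8 uM/min')")
    value, prefix, per = m.groups()
    return float(value) * _PREFIX[prefix] * _PER_MIN[per]


def orders_of_magnitude(rate_a: str | float, rate_b: str | float) -> float:
    """log10 of the ratio of two rates (strings are parsed with units).

    ``orders_of_magnitude("2.8 uM/min", "0.14 nM/min")`` ≈ 4.30: the
    first rate is more than four orders of magnitude faster.
    """
    a = parse_rate(rate_a) if isinstance(rate_a, str) else float(rate_a)
    b = parse_rate(rate_b) if isinstance(rate_b, str) else float(rate_b)
    if a <= 0 or b <= 0:
        raise ValueError("rates must be positive")
    return math.log10(a / b)
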