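"""Duplicate length-board measurement protocol helper.

Reference length measurements are taken twice, to the nearest 0.1 cm, by
two trained measurers.  The recorded value is the average of the two
readings; if they disagree by more than 0.5 cm, a third reading is required
and the average of all three recorded.  Averages are rounded half-up at the
0.05 cm midpoint.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

NEEDS_THIRD = "needs_third"

_TOL = 1e-9


def _round_01(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def record_length(m1: float, m2: float, m3: float | None = None) -> float | str:
    """Recorded length (cm) from duplicate measurements, or ``"needs_third"``.

    The third reading is required only when the first two differ by strictly
    more than 0.5 cm; a difference of exactly 0.5 cm is accepted.

    Raises
    ------
    ValueError
        for non-positive measurements.
    """
    ms = [m1, m2] if m3 is None else [m1, m2, m3]
    if any(m <= 0 for m in ms):
        raise ValueError("measurements must be positive")
    if abs(m1 - m2) <= 0.5 + _TOL:
        return _round_01((m1 + m2) / 2.0)
    if m3 is None:
        return NEEDS_THIRD
    return _round_01((m1 + m2 + m3) / 3.0)
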