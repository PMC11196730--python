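"""Report formatting helpers."""

from __future__ import annotations

__all__ = ["format_percent"]


def format_percent(numerator: int, denominator: int) -> str:
    """Render a count as ``"n/d; p%"`` with the percent rounded half-up.

    Half-up rounding (17.5 -> 18, 67.5 -> 68, 36.25 -> 36) done in exact
    integer arithmetic, immune to binary-float ties.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    pct = (200 * numerator + denominator) // (2 * denominator)
    return f"{numerator}/{denominator}; {pct}%"
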