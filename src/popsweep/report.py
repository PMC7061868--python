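"""Small reporting arithmetic shared by the pipeline outputs."""

from __future__ import annotations

from .variants import round_half_up

__all__ = ["percent_of"]


def percent_of(part: float, whole: float, decimals: int = 2) -> float:
    """100 * part / whole, half-up rounded to ``decimals``.

    The rounding convention matches the reported assembly-style percentages
    (e.g. 313.13 of 320.31 Mb -> 97.76).
    """
    if whole <= 0:
        raise ValueError("whole must be > 0")
    return round_half_up(100.0 * part / whole, decimals)
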