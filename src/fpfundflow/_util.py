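"""Small shared helpers (rounding conventions)."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, ties away from zero.

    Published tables in health-financing reports round half-up (5 always
    rounds away from zero), which differs from Python's built-in
    banker's rounding. Routing through ``Decimal(str(x))`` avoids binary
    float artefacts such as ``round(2.675, 2) == 2.67``.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))
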