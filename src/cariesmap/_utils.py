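"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as tables in the dental-epidemiology
    literature (and SPSS) print percentages.

    Uses the decimal string of ``x`` so that e.g. 2.675 -> 2.68 rather than
    the banker's-rounding 2.67 that ``round()`` gives for binary floats.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def largest_remainder_round(amounts: np.ndarray, unit: float, total: float) -> np.ndarray:
    """Round ``amounts`` to multiples of ``unit`` so they sum exactly to ``total``.

    ``total`` must itself be a multiple of ``unit`` (checked).  Classic
    largest-remainder (Hamilton) apportionment: floor everything, then hand
    the leftover units to the largest fractional remainders, ties broken by
    position for determinism.
    """
    amounts = np.asarray(amounts, dtype=float)
    n_units_total = total / unit
    if abs(n_units_total - round(n_units_total)) > 1e-9:
        raise ValueError(f"total {total} is not a multiple of the rounding unit {unit}")
    n_units_total = int(round(n_units_total))
    scaled = amounts / unit
    floors = np.floor(scaled + 1e-12)
    deficit = n_units_total - int(floors.sum())
    if deficit < 0:  # only from float noise pushing a floor up
        raise ValueError("amounts exceed total")
    remainders = scaled - floors
    order = np.argsort(-remainders, kind="stable")
    floors[order[:deficit]] += 1
    return floors * unit
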