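"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero-half.

    Report tables round shares half-up (79.5 -> 80), not banker's style.
    """
    return int(math.floor(x + 0.5))


def integer_shares(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Percentage shares of ``values``, raw and integer-rounded.

    The rounded shares are reconciled to sum to exactly 100 by the
    largest-remainder method, starting from half-up rounding.  Raises
    ``ValueError`` on a non-positive total.
    """
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("shares undefined: component total is not positive")
    raw = 100.0 * v / total
    rounded = np.array([round_half_up(s) for s in raw], dtype=int)
    deficit = 100 - int(rounded.sum())
    if deficit != 0:
        # adjust the entries whose rounding moved them furthest in the
        # direction that cancels the deficit
        residual = raw - rounded
        order = np.argsort(-np.sign(deficit) * residual)
        for i in order[: abs(deficit)]:
            rounded[i] += int(np.sign(deficit))
    return raw, rounded


def present_value_annuity(annual_amount: float, years: float, rate: float) -> float:
    """Present value of ``annual_amount`` paid at the end of each of ``years``
    years, discounted at ``rate`` per year.

    A fractional final year contributes its fraction of the payment,
    discounted at the following year-end.  With ``rate == 0`` this reduces to
    ``annual_amount * years``.
    """
    if years <= 0:
        return 0.0
    n_full = int(math.floor(years))
    frac = years - n_full
    if rate == 0:
        return annual_amount * years
    d = 1.0 / (1.0 + rate)
    full = annual_amount * d * (1 - d**n_full) / (1 - d) if n_full > 0 else 0.0
    tail = frac * annual_amount * d ** (n_full + 1) if frac > 0 else 0.0
    return full + tail
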