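"""dB <-> log10 contrast-sensitivity conversion and FDT quantization.

SAP and Matrix FDT both report sensitivities in decibels, but the decibel
is defined against different contrast scales: one SAP dB is 0.1 log10 unit
of Weber contrast sensitivity, one FDT dB is 0.05 log10 unit of Michelson
contrast sensitivity.  Dividing SAP values by 10 and FDT values by 20
therefore places both instruments on a common log10 scale (the linear 2:1
dB relationship).  Matrix FDT additionally reports only 15 discrete
sensitivity levels, unevenly spaced, whereas SAP steps in 1 dB.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DB_PER_LOG10", "FDT_LEVELS_DB", "db_to_log10", "log10_to_db",
           "quantize_fdt"]

#: dB change per 1.0 log10-unit change of contrast sensitivity.
DB_PER_LOG10: dict[str, float] = {"SAP": 10.0, "FDT": 20.0}

#: the 15 discrete sensitivity levels reported by Matrix FDT (dB).
FDT_LEVELS_DB = np.array(
    [0, 2, 3, 6, 7, 11, 12, 13, 18, 20, 23, 27, 32, 34, 38], dtype=float
)


def _factor(test_type: str) -> float:
    try:
        return DB_PER_LOG10[test_type]
    except KeyError:
        raise ValueError(f"unknown test_type {test_type!r}; expected 'SAP' or 'FDT'") from None


def db_to_log10(value, test_type: str):
    """Convert dB to common log10 units (SAP: /10, FDT: /20)."""
    return np.asarray(value, dtype=float) / _factor(test_type) if np.ndim(value) else float(value) / _factor(test_type)


def log10_to_db(value, test_type: str):
    """Inverse of :func:`db_to_log10` (SAP: x10, FDT: x20)."""
    return np.asarray(value, dtype=float) * _factor(test_type) if np.ndim(value) else float(value) * _factor(test_type)


def quantize_fdt(sensitivity, tie_break: str = "lower"):
    """Snap sensitivities to the nearest of the 15 FDT levels.

    Equidistant inputs resolve to the lower (worse-sensitivity) level by
    default.  Idempotent; scalar in, scalar out.
    """
    if tie_break not in ("lower", "upper"):
        raise ValueError("tie_break must be 'lower' or 'upper'")
    v = np.atleast_1d(np.asarray(sensitivity, dtype=float))
    # insertion point between bracketing levels, then compare distances
    hi = np.clip(np.searchsorted(FDT_LEVELS_DB, v), 0, len(FDT_LEVELS_DB) - 1)
    lo = np.clip(hi - 1, 0, None)
    d_lo = np.abs(v - FDT_LEVELS_DB[lo])
    d_hi = np.abs(FDT_LEVELS_DB[hi] - v)
    if tie_break == "lower":
        take_hi = d_hi < d_lo
    else:
        take_hi = d_hi <= d_lo
    out = FDT_LEVELS_DB[np.where(take_hi, hi, lo)]
    return float(out[0]) if np.ndim(sensitivity) == 0 else out
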