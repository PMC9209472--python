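"""Circular-permutation null helpers shared by the classification stages.

Nulls are built by circularly shifting a series by fixed increments of
T / n_shuffles samples (k = 1..n_shuffles).  Shifts that are congruent to
zero modulo the series length reproduce the observed statistic and are
dropped, so the default 100 increments yield 99 informative null values.
Thresholds use order-statistic percentiles (``method='higher'`` for upper
tails, ``'lower'`` for lower tails), which gives an exact 5% tail rate per
side under exchangeability.
"""

from __future__ import annotations

import numpy as np


def cyclic_offsets(n_samples: int, n_shuffles: int = 100) -> np.ndarray:
    """Evenly spaced circular-shift offsets, identity shifts excluded."""
    if n_samples < 2:
        raise ValueError("need at least two samples to shift")
    k = np.arange(1, n_shuffles + 1)
    offsets = np.rint(k * n_samples / n_shuffles).astype(int) % n_samples
    offsets = offsets[offsets != 0]
    # fixed increments can collide for short series; keep distinct shifts
    _, order = np.unique(offsets, return_index=True)
    return offsets[np.sort(order)]


def upper_threshold(null_values: np.ndarray, percentile: float = 95.0) -> float:
    """Order-statistic upper percentile of a null distribution."""
    return float(np.percentile(null_values, percentile, method="higher"))


def lower_threshold(null_values: np.ndarray, percentile: float = 5.0) -> float:
    return float(np.percentile(null_values, percentile, method="lower"))
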