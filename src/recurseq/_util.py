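"""Small shared numerics."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided t-based p; (nan, nan) + warning on constant axis."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn(
            "constant vector: Pearson correlation undefined, returning NA",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
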