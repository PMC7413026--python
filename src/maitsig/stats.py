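"""Small shared statistical utilities.

``bh_adjust`` is the Benjamini-Hochberg step-up FDR adjustment used by
every testing stage; it is implemented here directly (and cross-checked
against statsmodels in the test-suite) so its step-up/ordering semantics
are explicit and identical everywhere.
"""

from __future__ import annotations

import numpy as np


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped
    at 1 and reported back in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d array")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def mad_outlier_mask(values, k: float = 3.0) -> np.ndarray:
    """Boolean mask of values farther than k raw MADs from the median.

    The MAD is unscaled (no 1.4826 consistency factor).  When the MAD is
    zero but the values are not all identical, no point can be flagged
    coherently; the mask is all-False and a warning is raised.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        if not np.all(x == x[0]):
            import warnings

            warnings.warn("MAD is zero with non-constant values; skipping outlier removal")
        return np.zeros(x.shape, dtype=bool)
    return np.abs(x - med) > k * mad
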