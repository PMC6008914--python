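"""Pearson chi-square homogeneity test over k strata x 2 allele categories.

The statistic is the textbook ``sum (O - E)^2 / E`` with expected counts
``E_ij = row_i * col_j / grand``, ``k - 1`` degrees of freedom for the
two-column case, and no continuity correction (Yates' correction is a 2x2
device; this is stated in the result metadata).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray  # k x 2
    expected: np.ndarray  # k x 2
    statistic: float
    df: int
    p_value: float
    correction: str = "none (no Yates continuity correction)"

    @property
    def p_band(self) -> str:
        """The "<0.001"-style banding used in clinical reporting."""
        for cut in (0.001, 0.01, 0.05):
            if self.p_value < cut:
                return f"<{cut}"
        return f"{self.p_value:.3f}"


def chisq_homogeneity(observed) -> ContingencyResult:
    """Chi-square homogeneity test on a k x 2 table of allele counts.

    Raises ``ValueError`` on negative counts or a zero row/column total
    (expected counts would be degenerate).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError(f"observed must be k x 2, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column total: expected counts undefined")
    expected = np.outer(rows, cols) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[0] - 1
    p = float(sps.chi2.sf(statistic, df))
    return ContingencyResult(observed=obs, expected=expected, statistic=statistic, df=df, p_value=p)
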