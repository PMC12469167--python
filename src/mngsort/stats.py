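"""Cross-recording statistics over feature-set accuracies.

Feature sets are compared pairwise with the Wilcoxon signed-rank test on
matched per-recording accuracies (two-sided; zero differences discarded,
exact null distribution for small samples without ties, normal
approximation with continuity correction otherwise). Because all pairs are
tested, the alpha level is Bonferroni-corrected: alpha_adj = alpha / n
comparisons, with alpha = 0.01 and strict inequality p < alpha_adj for
significance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


def wilcoxon_pairwise(acc: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank p-values between feature sets.

    Parameters
    ----------
    acc : DataFrame
        Recordings as rows, feature sets as columns, accuracies as values.
        No missing cells.

    Returns a symmetric feature-set x feature-set DataFrame of two-sided
    p-values with a degenerate diagonal of 1.0. A pair whose accuracies are
    identical on every recording has no signed ranks; its p-value is 1.0
    (logged as degenerate).
    """
    if acc.isna().any().any():
        raise ValueError("accuracy table has missing cells")
    cols = list(acc.columns)
    p = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            diff = acc[a].to_numpy() - acc[b].to_numpy()
            if np.all(diff == 0):
                logger.info("degenerate pair %s vs %s: all differences zero", a, b)
                pv = 1.0
            else:
                nz = diff[diff != 0]
                if len(nz) <= 25:
                    kw = {"method": "exact"}
                else:
                    kw = {"method": "approx", "correction": True}
                pv = float(
                    scipy.stats.wilcoxon(
                        diff, zero_method="wilcox",
                        alternative="two-sided", **kw,
                    ).pvalue
                )
            p.loc[a, b] = p.loc[b, a] = pv
    return p


def bonferroni(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted alpha level, alpha / n."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def significance_table(p: pd.DataFrame, alpha_adj: float) -> pd.DataFrame:
    """Boolean matrix: True iff p < alpha_adj (strict inequality)."""
    return p < alpha_adj
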