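"""Cross-sample statistics: PCA, correlations, rank and t tests.

PCA follows prcomp semantics — columns centered, unscaled by default,
computed by singular value decomposition — with component signs fixed
deterministically.  The Wilcoxon rank-sum test is exact for small groups
(both sizes <= 20, no ties) and switches to the normal approximation
beyond; the matched t test is the standard two-tailed paired test.
P-values are reported raw, with the conventional significance tiers
(*p<.05, **p<.01, ***p<.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_WILCOXON_MAX_N = 20


@dataclass
class PCAResult:
    scores: np.ndarray       # samples x components
    loadings: np.ndarray     # features x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(matrix, n_components: int | None = None, scale: bool = False) -> PCAResult:
    """Principal components of a samples-by-features matrix.

    Columns are centered (and optionally scaled to unit variance), then
    decomposed by SVD; scores are the centered data projected on the
    loadings, explained variances are non-increasing.  Each component's
    sign is fixed so its largest-magnitude loading is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not np.any(Xc):
        warnings.warn("constant matrix: all components have zero variance",
                      stacklevel=2)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic orientation
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    if n_components is not None:
        U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    var = S**2 / (X.shape[0] - 1)
    total = var.sum()
    return PCAResult(
        scores=U * S,
        loadings=Vt.T,
        explained_variance=var,
        explained_variance_ratio=var / total if total > 0 else var,
    )


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when both groups have <= 20 observations and
    there are no ties; normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = (
        "exact"
        if no_ties and max(len(x), len(y)) <= EXACT_WILCOXON_MAX_N
        else "asymptotic"
    )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def paired_t(x, y) -> tuple[float, float]:
    """Matched two-tailed Student t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("matched test requires equal-length groups")
    if len(x) < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    if np.ptp(d) == 0 and d[0] == 0:
        raise ValueError("all paired differences are zero; t is undefined")
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def stars(p: float) -> str:
    """Significance tier: ns, *p<.05, **p<.01, ***p<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def rank_and_t_tests(
    group_a, group_b, paired: bool = False, label: str = ""
) -> pd.DataFrame:
    """Run the rank-sum (and, when paired, the matched t) comparison."""
    rows = []
    w, pw = wilcoxon_rank_sum(group_a, group_b)
    rows.append((label, "wilcoxon_rank_sum", w, pw, stars(pw)))
    if paired:
        t, pt = paired_t(group_a, group_b)
        rows.append((label, "paired_t", t, pt, stars(pt)))
    return pd.DataFrame(
        rows, columns=["comparison", "test", "statistic", "p", "stars"]
    )
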