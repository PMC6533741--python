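"""Small statistical primitives shared by the enrichment and TDT modules."""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, EmptyInputError

__all__ = [
    "fisher_exact_one_sided",
    "bh_fdr",
    "cohen_kappa",
    "bonferroni_threshold",
]


def fisher_exact_one_sided(k: int, K: int, n: int, N: int) -> float:
    """One-sided (enrichment) Fisher's exact test on a 2x2 overlap table.

    Returns ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``: the chance of
    drawing at least ``k`` foreground genes when ``n`` targets are drawn
    from a universe of ``N`` genes of which ``K`` are foreground.

    Parameters use the gene-set enrichment convention: ``k`` overlap,
    ``K`` foreground size, ``n`` target-set size, ``N`` universe size.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v:
            raise DomainError(f"{name} must be an integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N <= 0:
        raise DomainError("N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise DomainError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    # survival function of the hypergeometric: P(X > k-1)
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values, clipped
    at 1; tied p-values share a q-value.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise EmptyInputError("bh_fdr on an empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa inter-rater agreement for two equal-length label vectors.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the raters' marginal label frequencies.  When
    ``p_e == 1`` both raters used a single identical label everywhere, so
    agreement is perfect and 1.0 is returned.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise DomainError(f"rating length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise DomainError("empty rating vectors")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    labels = set(ca) | set(cb)
    p_e = sum((ca[l] / n) * (cb[l] / n) for l in labels)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def bonferroni_threshold(alpha: float, n_genes: int) -> float:
    """Candidate-wise significance threshold alpha / n_genes."""
    if not (0 < alpha <= 1):
        raise DomainError(f"alpha must lie in (0, 1], got {alpha}")
    if int(n_genes) != n_genes or n_genes < 1:
        raise DomainError(f"n_genes must be a positive integer, got {n_genes}")
    return alpha / int(n_genes)
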