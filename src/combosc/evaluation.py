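"""Ranking-agreement and enrichment statistics.

Two evaluation statistics accompany the pipeline: a discounted cumulative
gain (DCG) over rank discrepancies between predicted and experimental drug
orderings (lower = better top-rank agreement), and the hypergeometric upper
tail probability that at least k of the n externally registered combinations
land in the top tranche (10% of N) of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .expression import ValidationError


def _check_permutation(ranks, name: str) -> np.ndarray:
    r = np.asarray(ranks, dtype=int)
    if sorted(r) != list(range(1, len(r) + 1)):
        raise ValidationError(f"{name} is not a permutation of 1..{len(r)}")
    return r


def dcg(rank_predict, rank_experiment) -> float:
    """DCG = sum_i r_i / log2(i + 1), items ordered by predicted rank.

    ``rank_predict`` and ``rank_experiment`` are item-aligned permutations of
    1..k; r_i = |rank_predict - rank_experiment| for the item holding
    predicted rank i.  0 iff the rankings are identical.
    """
    pred = _check_permutation(rank_predict, "rank_predict")
    exp = _check_permutation(rank_experiment, "rank_experiment")
    if len(pred) != len(exp):
        raise ValidationError("rankings must have equal length")
    diff = np.abs(pred - exp).astype(float)
    order = np.argsort(pred)  # item with predicted rank i at discount slot i
    i = np.arange(1, len(pred) + 1)
    return float(np.sum(diff[order] / np.log2(i + 1)))


def ranks_from_scores(scores, ids=None, ascending: bool = False) -> np.ndarray:
    """Strict 1..k ranks from scores; ties broken by id order.

    By default higher scores rank first (rank 1 = best).
    """
    s = np.asarray(scores, dtype=float)
    ids = np.arange(len(s)) if ids is None else np.asarray(ids)
    key = s if ascending else -s
    order = np.lexsort((ids, key))
    ranks = np.empty(len(s), dtype=int)
    ranks[order] = np.arange(1, len(s) + 1)
    return ranks


@dataclass
class EnrichmentQuery:
    """Counts for the top-tranche enrichment test.

    N: all predictions; M: top tranche size (defaults to floor(0.10*N),
    at least 1); n: externally registered combinations among the N;
    k: registered combinations found inside the top tranche.
    """

    N: int
    n: int
    k: int
    M: int | None = None

    def __post_init__(self) -> None:
        if self.M is None:
            self.M = max(1, int(np.floor(0.10 * self.N)))
        if not (0 < self.M <= self.N):
            raise ValidationError("need 0 < M <= N")
        if not (0 <= self.n <= self.N):
            raise ValidationError("need 0 <= n <= N")
        if not (0 <= self.k <= min(self.M, self.n)):
            raise ValidationError("need 0 <= k <= min(M, n)")


def enrichment_p(q: EnrichmentQuery) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts registered combinations inside a random tranche of size M drawn
    from N predictions containing n registered ones; k = 0 gives p = 1.
    """
    if q.k == 0:
        return 1.0
    return float(hypergeom.sf(q.k - 1, q.N, q.M, q.n))
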