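"""Signed-significance gene rankings and permutation tests for ordered-list overlap.

Two differential-expression experiments can be compared without choosing a
significance cutoff by ranking each gene list (here by the sign of the fold
change times -log10 of the p-value, so that significant up-regulation sits at
the top and significant down-regulation at the bottom) and asking whether the
top-n sets of the two lists share more members than expected when the lists
are unrelated.  The null distribution of the overlap size is obtained by
randomly shuffling the rank order of one list; for independent lists the
expected overlap at depth n out of N shared genes is hypergeometric, with
mean n^2/N.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .errors import ParameterError, UniverseError

__all__ = [
    "RankedList",
    "OverlapResult",
    "rank_metric",
    "ordered_overlap_test",
    "screen_rank",
]

logger = logging.getLogger(__name__)


def rank_metric(fold_change: float, p_value: float) -> float:
    """Signed-significance score: sign(fold change) * -log10(p).

    A p-value at (or below) the machine floor is clamped with a warning; a
    fold change of exactly zero scores zero.
    """
    eps = np.finfo(float).tiny
    if p_value <= 0:
        warnings.warn(f"p-value {p_value} clamped to machine floor {eps}", stacklevel=2)
        p_value = eps
    if p_value > 1:
        raise ParameterError(f"p-value {p_value} > 1")
    if fold_change == 0:
        return 0.0
    return float(np.sign(fold_change) * -np.log10(max(p_value, eps)))


@dataclass
class RankedList:
    """Genes ordered by a signed score.

    By default the ordering is descending (largest score first — the
    signed-significance convention); screens ranked most-depleted-first use
    ``ascending=True``.
    """

    ids: np.ndarray
    scores: np.ndarray
    ascending: bool = False

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.ids.shape != self.scores.shape or self.ids.ndim != 1:
            raise ParameterError("ids and scores must be 1-D and of equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ParameterError("ranked list contains duplicate ids")
        if np.isnan(self.scores).any():
            raise ParameterError("ranked list contains missing scores")
        order = np.lexsort((self.ids, self.scores if self.ascending else -self.scores))
        self.ids = self.ids[order]
        self.scores = self.scores[order]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, float]], ascending: bool = False) -> "RankedList":
        ids, scores = zip(*pairs) if pairs else ((), ())
        return cls(np.array(ids, dtype=object), np.array(scores, dtype=float), ascending=ascending)

    def __len__(self) -> int:
        return len(self.ids)

    def restrict(self, universe: set) -> "RankedList":
        mask = np.array([i in universe for i in self.ids])
        return RankedList(self.ids[mask], self.scores[mask], ascending=self.ascending)


@dataclass
class OverlapResult:
    """Observed and null overlap sizes per depth from a permutation test."""

    depths: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    null_q025: np.ndarray
    null_q975: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: int
    ends: str
    universe_size: int


def _end_sets(ids: np.ndarray, depth: int, ends: str) -> set:
    s: set = set()
    if depth == 0:
        return s
    if ends in ("top", "both"):
        s |= set(ids[:depth])
    if ends in ("bottom", "both"):
        s |= set(ids[-depth:])
    return s


def ordered_overlap_test(
    list_a: RankedList,
    list_b: RankedList,
    depths: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
    ends: str = "top",
) -> OverlapResult:
    """Permutation test for the overlap of two ordered lists at given depths.

    The id universes are intersected first (with a warning when genes are
    dropped).  The observed statistic at depth n is ``|top-n(A) & top-n(B)|``
    (bottom or both ends analogously, summed).  The null shuffles list B's
    rank order ``n_perm`` times; the one-sided empirical p-value is
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if ends not in ("top", "bottom", "both"):
        raise ParameterError(f"ends must be top/bottom/both, got {ends!r}")
    universe = set(list_a.ids) & set(list_b.ids)
    if not universe:
        raise UniverseError("ranked lists share no ids")
    n_lost = (len(list_a) - len(universe)) + (len(list_b) - len(universe))
    if n_lost:
        logger.warning("ordered_overlap_test: %d entries outside the shared universe dropped", n_lost)
    a = list_a.restrict(universe)
    b = list_b.restrict(universe)
    n_univ = len(universe)
    depths_arr = np.asarray(sorted(depths), dtype=int)
    if np.any(depths_arr < 0) or np.any(depths_arr > n_univ):
        raise ParameterError(f"depths must lie in 0..{n_univ}")

    observed = np.array(
        [len(_end_sets(a.ids, d, ends) & _end_sets(b.ids, d, ends)) for d in depths_arr],
        dtype=float,
    )

    # Vectorized null: membership masks of A's end-sets over B's current order,
    # permuted and cumulatively counted.
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    b_ids = b.ids
    null = np.zeros((n_perm, len(depths_arr)))
    max_d = int(depths_arr.max()) if len(depths_arr) else 0
    # rank of each gene within A's ends; membership in A's top-d (bottom-d) is
    # then a rank comparison, so one pass serves every requested depth
    a_top_rank = {g: r for r, g in enumerate(a.ids[:max_d])}
    a_bot_rank = {g: r for r, g in enumerate(a.ids[::-1][:max_d])}
    for k in range(n_perm):
        perm = rng.permutation(n_univ)
        for di, d in enumerate(depths_arr):
            count = 0
            if ends in ("top", "both") and d > 0:
                head = b_ids[perm[:d]]
                count += sum(1 for g in head if a_top_rank.get(g, max_d) < d)
            if ends in ("bottom", "both") and d > 0:
                tail = b_ids[perm[-d:]]
                count += sum(1 for g in tail if a_bot_rank.get(g, max_d) < d)
            null[k, di] = count

    p = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (1.0 + n_perm)
    p = np.where(depths_arr == 0, 1.0, p)
    return OverlapResult(
        depths=depths_arr,
        observed=observed,
        null_mean=null.mean(axis=0),
        null_q025=np.quantile(null, 0.025, axis=0),
        null_q975=np.quantile(null, 0.975, axis=0),
        p_values=p,
        n_perm=n_perm,
        seed=seed,
        ends=ends,
        universe_size=n_univ,
    )


def screen_rank(hits: Sequence[Tuple[str, float, str]]) -> RankedList:
    """Rank screen hits by p-value from most depleted to most enriched.

    Depleted hits come first, ordered by ascending p; enriched hits follow,
    ordered by descending p.  Emitted as an ascending-score list where
    depleted entries score ``-(-log10 p)`` (negative) and enriched entries
    ``+(-log10 p)``, consistent with the signed-significance convention.
    Ties in p are broken by id, lexicographically.
    """
    ids = [h[0] for h in hits]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate ids in screen hits")
    pairs: List[Tuple[str, float]] = []
    for gene, p, direction in hits:
        if not 0 < p <= 1:
            raise ParameterError(f"{gene}: p-value {p} outside (0, 1]")
        if direction == "depleted":
            pairs.append((gene, rank_metric(-1.0, p)))
        elif direction == "enriched":
            pairs.append((gene, rank_metric(+1.0, p)))
        else:
            raise ParameterError(f"{gene}: direction must be 'depleted' or 'enriched'")
    return RankedList.from_pairs(pairs, ascending=True)
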