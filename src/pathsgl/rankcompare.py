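"""Top-k Canberra comparison of (possibly partial) ranked lists.

Two cohorts each produce a ranked list of variables (pathways or genes).
The top-k Canberra distance

    Ca(k) = sum_i |min(tau1(i), k+1) - min(tau2(i), k+1)|
                  / (min(tau1(i), k+1) + min(tau2(i), k+1))

weights disagreements at high ranks most heavily; ranks are capped at
``k+1`` and a variable unranked in a list carries the sentinel rank
``p*+1`` (``p*`` = universe size), so variables outside both top-k lists
contribute nothing.  ``Ca(k)`` is normalised by the expected distance
between two random lists, estimated by Monte Carlo (or exact enumeration at
tiny sizes).  Significance per k comes from permuting which identifiers
carry the second list's multiset of ranks; Benjamini-Hochberg converts the
per-k p-values to q-values, and the k minimising the normalised distance
defines the consensus set: the intersection of the two top-k* lists ordered
by average rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedList",
    "CanberraReport",
    "canberra_topk",
    "expected_canberra_random",
    "normalized_canberra",
    "permutation_curve",
    "consensus",
]


@dataclass
class RankedList:
    """Partial ranking over a fixed universe of identifiers.

    ``ranks[i]`` is the rank of ``universe[i]`` (1 = best) or the sentinel
    ``p* + 1`` when the item is unranked in this list.  Assigned ranks must
    be distinct and form ``{1..m}`` for ``m`` ranked items.
    """

    universe: list[str]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int64)
        p = len(self.universe)
        if self.ranks.shape != (p,):
            raise ValueError("one rank per universe item required")
        if len(set(self.universe)) != p:
            raise ValueError("universe identifiers must be unique")
        assigned = np.sort(self.ranks[self.ranks <= p])
        if assigned.size and not np.array_equal(
            assigned, np.arange(1, assigned.size + 1)
        ):
            raise ValueError("assigned ranks must be distinct and form 1..m")
        if (self.ranks > p + 1).any() or (self.ranks < 1).any():
            raise ValueError(f"ranks must lie in 1..{p + 1}")

    @property
    def p_star(self) -> int:
        return len(self.universe)

    @property
    def n_ranked(self) -> int:
        return int((self.ranks <= self.p_star).sum())

    def top_k(self, k: int) -> set[str]:
        return {u for u, r in zip(self.universe, self.ranks) if r <= k}

    def rank_of(self, item: str) -> int:
        return int(self.ranks[self.universe.index(item)])

    @classmethod
    def from_scores(
        cls, universe: list[str], scores: dict[str, float]
    ) -> "RankedList":
        """Rank scored items descending; ties break by identifier; items
        without a score get the unranked sentinel."""
        scored = sorted(
            (u for u in universe if u in scores),
            key=lambda u: (-scores[u], u),
        )
        p = len(universe)
        rank_map = {u: i + 1 for i, u in enumerate(scored)}
        ranks = np.array([rank_map.get(u, p + 1) for u in universe], dtype=np.int64)
        return cls(list(universe), ranks)


@dataclass
class CanberraReport:
    """Per-k distances, p/q-values and the consensus extraction."""

    table: pd.DataFrame  # columns: k, ca, ca_star, p_value, q_value
    k_star: int
    consensus: pd.DataFrame = field(default_factory=pd.DataFrame)
    Q: int = 0


def _check_universe(list1: RankedList, list2: RankedList) -> None:
    if list1.universe != list2.universe:
        raise ValueError("ranked lists must share the same universe, in order")
    if list1.p_star == 0:
        raise ValueError("empty universe")


def _canberra_from_ranks(tau1: np.ndarray, tau2: np.ndarray, k: int) -> float:
    c1 = np.minimum(tau1, k + 1)
    c2 = np.minimum(tau2, k + 1)
    num = np.abs(c1 - c2)
    return float(np.sum(num / (c1 + c2)))


def canberra_topk(list1: RankedList, list2: RankedList, k: int) -> float:
    """Top-k Canberra distance between two rankings of the same universe."""
    _check_universe(list1, list2)
    if not (1 <= k <= list1.p_star):
        raise ValueError("k must lie in [1, p*]")
    return _canberra_from_ranks(list1.ranks, list2.ranks, k)


def expected_canberra_random(
    p_star: int, k: int, Q: int = 2000, seed: int = 0
) -> float:
    """Expected top-k Canberra distance between two random full rankings.

    Monte-Carlo average over ``Q`` independent pairs of uniform
    permutations of ``1..p_star`` (equivalently, one fixed list against a
    random permutation, by symmetry).
    """
    if p_star < 1 or not (1 <= k <= p_star):
        raise ValueError("need 1 <= k <= p_star")
    rng = np.random.default_rng(seed)
    tau1 = np.arange(1, p_star + 1)
    total = 0.0
    for _ in range(Q):
        tau2 = rng.permutation(p_star) + 1
        total += _canberra_from_ranks(tau1, tau2, k)
    return total / Q


def normalized_canberra(
    list1: RankedList, list2: RankedList, k: int, E: float
) -> float:
    """``Ca(k) / E``: 0 for exact agreement, about 1 for random lists."""
    if E <= 0:
        raise ValueError("expected distance must be positive")
    return canberra_topk(list1, list2, k) / E


def permutation_curve(
    list1: RankedList,
    list2: RankedList,
    k_range: range | list[int],
    Q: int = 1000,
    seed: int = 0,
    Q_expected: int = 2000,
) -> CanberraReport:
    """Normalised distance curve with permutation p-values and BH q-values.

    For each k the p-value is ``(1 + #{q: Ca*_perm,q(k) <= Ca*_obs(k)}) /
    (Q + 1)`` (one-sided: a small distance means agreement; add-one keeps
    p > 0).  Permutations shuffle which identifiers carry list 2's multiset
    of ranks, including the unranked sentinel, so partial lists are handled
    naturally.  ``k*`` is the k minimising the observed normalised
    distance, ties to the smallest k.
    """
    _check_universe(list1, list2)
    k_cap = min(list1.n_ranked, list2.n_ranked)
    ks = list(k_range)
    if not ks or min(ks) < 1 or max(ks) > k_cap:
        raise ValueError(f"k_range must lie within [1, {k_cap}]")
    rng = np.random.default_rng(seed)
    p_star = list1.p_star
    tau1, tau2 = list1.ranks, list2.ranks
    perms = [tau2[rng.permutation(p_star)] for _ in range(Q)]

    rows = []
    for k in ks:
        E = expected_canberra_random(p_star, k, Q=Q_expected, seed=seed + k)
        ca_obs = _canberra_from_ranks(tau1, tau2, k)
        ca_star = ca_obs / E
        n_le = sum(
            1 for tp in perms if _canberra_from_ranks(tau1, tp, k) <= ca_obs
        )
        p = (1 + n_le) / (Q + 1)
        rows.append({"k": k, "ca": ca_obs, "ca_star": ca_star, "p_value": p})
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    k_star = int(table.loc[table["ca_star"].idxmin(), "k"])
    cons = consensus(list1, list2, k_star)
    return CanberraReport(table=table, k_star=k_star, consensus=cons, Q=Q)


def consensus(list1: RankedList, list2: RankedList, k_star: int) -> pd.DataFrame:
    """Intersection of the two top-k* sets, ordered by average rank.

    Ties in average rank break by the smaller of the two ranks, then by
    identifier.
    """
    _check_universe(list1, list2)
    common = list1.top_k(k_star) & list2.top_k(k_star)
    rows = []
    for item in common:
        r1, r2 = list1.rank_of(item), list2.rank_of(item)
        rows.append(
            {
                "variable": item,
                "rank1": r1,
                "rank2": r2,
                "average_rank": (r1 + r2) / 2.0,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["variable", "rank1", "rank2", "average_rank"])
    df = pd.DataFrame(rows)
    df["_min"] = df[["rank1", "rank2"]].min(axis=1)
    df = df.sort_values(
        ["average_rank", "_min", "variable"], kind="stable"
    ).drop(columns="_min")
    return df.reset_index(drop=True)
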