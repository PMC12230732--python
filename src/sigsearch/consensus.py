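"""Consensus perturbation ranking: aggregate per-signature hits per perturbation.

A perturbation profiled in many contexts contributes many signatures to a
search result list.  Consensus ranking asks which perturbations are
*consistently* at the top, by three methods:

* **Top-N Fisher** — per perturbation, a 2x2 table of its up-role vs down-role
  results inside vs outside the top-N positions of the ranked list
  (``a`` = up in top-N, ``b`` = down in top-N, ``c`` = up outside,
  ``d`` = down outside); one-sided Fisher p for the "consensus up" direction,
  and the column-flipped table for "consensus down".  For paired queries the
  mimicker/reverser roles play the up/down parts.
* **KS** — two-sided Kolmogorov-Smirnov statistic of the perturbation's
  normalized ranks against a uniform reference, or against a normal reference
  fit to the pooled normalized ranks of the whole list.
* **MW** — Mann-Whitney U of the perturbation's ranks against all other
  results' ranks; small U means its signatures sit atop the list.

Perturbations with fewer than ``min_signatures`` results (default 10) are
excluded from every consensus ranking.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .engine import ContingencyTable, EnrichmentResult, bh_adjust, fisher_one_sided

__all__ = [
    "ConsensusParams",
    "ConsensusResult",
    "RankVector",
    "topn_consensus",
    "extract_rank_vectors",
    "ks_consensus",
    "mw_consensus",
]

_UP_ROLES = {"up", "mimicker"}
_DOWN_ROLES = {"down", "reverser"}


@dataclass(frozen=True)
class ConsensusParams:
    top_n: int = 10_000
    min_signatures: int = 10
    significance_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_signatures < 1:
            raise ValueError("min_signatures must be >= 1")


@dataclass(frozen=True)
class ConsensusResult:
    perturbation: str
    n_signatures: int
    table_up: ContingencyTable
    table_down: ContingencyTable
    p_up: float
    p_down: float
    adj_p_up: float
    adj_p_down: float
    direction_labels: tuple[str, str]  # ("up","down") or ("mimicker","reverser")


@dataclass(frozen=True)
class RankVector:
    """Positions of one perturbation's signatures in the full ranked list."""

    perturbation: str
    ranks: tuple[int, ...]
    total: int

    def __post_init__(self) -> None:
        if len(set(self.ranks)) != len(self.ranks):
            raise ValueError("ranks must be unique")
        if self.ranks and not (1 <= min(self.ranks) and max(self.ranks) <= self.total):
            raise ValueError("ranks must lie within 1..total")


def _role_split(results: Sequence[EnrichmentResult]) -> tuple[str, str]:
    roles = {r.role for r in results}
    if roles <= {"mimicker", "reverser"}:
        return "mimicker", "reverser"
    if roles <= {"up", "down"}:
        return "up", "down"
    raise ValueError(f"mixed result roles cannot be aggregated: {sorted(roles)}")


def _by_perturbation(results: Sequence[EnrichmentResult]):
    groups: dict[str, list[EnrichmentResult]] = defaultdict(list)
    for r in results:
        groups[r.meta.perturbation].append(r)
    return groups


def topn_consensus(
    results: Sequence[EnrichmentResult], params: ConsensusParams = ConsensusParams()
) -> list[ConsensusResult]:
    """Top-N Fisher consensus over one ranked result list.

    Mimickers and reversers (or up and down rows) are interleaved in the one
    global ranking; the top-N window counts positions among all returned
    results.  p-values are BH-adjusted per direction family across
    perturbations, and the output is sorted by ``min(adj_p_up, adj_p_down)``
    ascending with deterministic tie-breaks.
    """
    if not results:
        return []
    up_role, down_role = _role_split(results)
    groups = _by_perturbation(results)
    records = []
    for pert in sorted(groups):
        rs = groups[pert]
        if len(rs) < params.min_signatures:
            continue
        a = sum(1 for r in rs if r.role == up_role and r.rank <= params.top_n)
        b = sum(1 for r in rs if r.role == down_role and r.rank <= params.top_n)
        c = sum(1 for r in rs if r.role == up_role and r.rank > params.top_n)
        d = sum(1 for r in rs if r.role == down_role and r.rank > params.top_n)
        t_up = ContingencyTable(a, b, c, d)
        t_down = ContingencyTable(b, a, d, c)  # columns flipped
        records.append((pert, len(rs), t_up, t_down))
    if not records:
        return []
    p_up = [fisher_one_sided(t) for _, _, t, _ in records]
    p_down = [fisher_one_sided(t) for _, _, _, t in records]
    adj_up = bh_adjust(p_up)
    adj_down = bh_adjust(p_down)
    out = [
        ConsensusResult(
            perturbation=pert,
            n_signatures=n,
            table_up=t_up,
            table_down=t_down,
            p_up=pu,
            p_down=pd_,
            adj_p_up=float(au),
            adj_p_down=float(ad),
            direction_labels=(up_role, down_role),
        )
        for (pert, n, t_up, t_down), pu, pd_, au, ad in zip(
            records, p_up, p_down, adj_up, adj_down
        )
    ]
    out.sort(
        key=lambda r: (
            min(r.adj_p_up, r.adj_p_down),
            min(r.p_up, r.p_down),
            -(r.table_up.a + r.table_down.a),
            r.perturbation,
        )
    )
    return out


def extract_rank_vectors(
    results: Sequence[EnrichmentResult], min_signatures: int = 10
) -> list[RankVector]:
    """One :class:`RankVector` per perturbation with at least *min_signatures*
    results, positions taken from the global ranking."""
    total = len(results)
    groups = _by_perturbation(results)
    return [
        RankVector(pert, tuple(sorted(r.rank for r in groups[pert])), total)
        for pert in sorted(groups)
        if len(groups[pert]) >= min_signatures
    ]


def ks_consensus(
    vectors: Sequence[RankVector], reference: str = "uniform"
) -> list[tuple[str, float]]:
    """Rank perturbations by the two-sided KS statistic of their normalized
    ranks against a reference distribution.

    Ranks are normalized to (0, 1] by dividing by the list length.  The
    ``uniform`` reference is U(0,1); the ``normal`` reference is a normal with
    the mean and standard deviation of the normalized ranks of the *whole*
    list (1..total).  Output is sorted by D descending (most top- or
    bottom-concentrated first).  Singleton vectors are allowed; D is then the
    one-point ECDF supremum.
    """
    if reference not in ("uniform", "normal"):
        raise ValueError(f"unknown reference {reference!r}")
    out: list[tuple[str, float]] = []
    for v in vectors:
        if not v.ranks:
            continue
        x = np.asarray(v.ranks, dtype=float) / v.total
        if reference == "uniform":
            d = stats.kstest(x, stats.uniform.cdf).statistic
        else:
            pooled = np.arange(1, v.total + 1, dtype=float) / v.total
            mu, sigma = pooled.mean(), pooled.std()
            if sigma == 0:
                raise ValueError("pooled normalized ranks have zero variance")
            d = stats.kstest(x, stats.norm(mu, sigma).cdf).statistic
        out.append((v.perturbation, float(d)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def mw_consensus(vectors: Sequence[RankVector]) -> list[tuple[str, float, float]]:
    """Rank perturbations by the Mann-Whitney U of their ranks vs all others.

    ``U = R1 - n1(n1+1)/2`` with ``R1`` the perturbation's rank sum; U = 0 is
    maximal top-concentration, so the output is sorted by U ascending.  The
    p-value is the asymptotic one-sided (its ranks stochastically smaller)
    Mann-Whitney p.
    """
    out: list[tuple[str, float, float]] = []
    for v in vectors:
        if not v.ranks:
            continue
        mine = np.asarray(v.ranks, dtype=np.int64)
        n1 = mine.size
        u = float(mine.sum() - n1 * (n1 + 1) / 2)
        others = np.setdiff1d(np.arange(1, v.total + 1, dtype=np.int64), mine)
        if others.size:
            p = float(
                stats.mannwhitneyu(mine, others, alternative="less", method="asymptotic").pvalue
            )
        else:
            p = 1.0
        out.append((v.perturbation, u, p))
    out.sort(key=lambda t: (t[1], t[2], t[0]))
    return out
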