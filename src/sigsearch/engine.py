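"""Up/down gene-set enrichment search over a bit-vector index.

Every stored gene set (or up/down pair) is compared against a query with a
one-sided Fisher's exact test on a 2x2 contingency table

    a = overlap        b = query_size - a
    c = set_size - a   d = background - a - b - c

where the background is the gene-universe size.  One-sided means the
hypergeometric upper tail ``P(X >= a)``: only over-representation ranks a hit,
never depletion.

For paired up/down queries, each stored pair yields two tests:

* **mimicker** — overlap = ``|up_q & up_s| + |down_q & down_s|`` (the stored
  signature pushes expression the same way as the query), and
* **reverser** — overlap = ``|up_q & down_s| + |down_q & up_s|`` (a candidate
  for reversing the queried expression state),

with ``query_size`` and ``set_size`` the summed sizes of the two halves.
Benjamini-Hochberg adjusted p-values are computed across all tests of one
submission; by default only hits with raw ``p < 0.05`` are returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .store import BitIndex, GeneSet, GeneUniverse, SignatureMeta

__all__ = [
    "ContingencyTable",
    "SearchParams",
    "EnrichmentResult",
    "EmptyQueryError",
    "intersect_count",
    "fisher_one_sided",
    "odds_ratio",
    "build_single_table",
    "mimicker_reverser_overlaps",
    "bh_adjust",
    "search_single",
    "search_paired",
    "filter_results",
    "results_to_frame",
]


class EmptyQueryError(ValueError):
    """No query symbol resolved against the index universe."""

    def __init__(self, unresolved: Sequence[str]):
        self.unresolved = list(unresolved)
        super().__init__(
            f"query resolves to 0 universe genes; unresolved symbols: {sorted(self.unresolved)}"
        )


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"contingency cells must be non-negative: {self}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all-zero")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SearchParams:
    """Knobs of one search submission.

    ``background_size`` defaults to the index universe size.  With
    ``apply_threshold`` (the default) only rows with raw
    ``p < significance_threshold`` are returned, mirroring an API that only
    reports significant perturbations.
    """

    background_size: Optional[int] = None
    significance_threshold: float = 0.05
    max_results: Optional[int] = None
    apply_threshold: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_threshold < 1.0):
            raise ValueError("significance_threshold must lie strictly in (0, 1)")
        if self.background_size is not None and self.background_size <= 0:
            raise ValueError("background_size must be positive")
        if self.max_results is not None and self.max_results <= 0:
            raise ValueError("max_results must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    """One query-vs-signature hit."""

    meta: SignatureMeta
    role: str  # "up" | "down" | "mimicker" | "reverser"
    overlap_count: int
    set_size: int
    odds_ratio: float
    p_value: float
    adj_p_value: float
    rank: int
    overlap_genes: Optional[frozenset[str]] = None


def intersect_count(row: np.ndarray, query_mask: np.ndarray) -> int:
    """popcount(row AND mask) — the overlap of the two underlying sets."""
    if row.shape != query_mask.shape:
        raise ValueError("bit arrays have different lengths")
    return int(np.bitwise_count(row & query_mask).sum())


def fisher_one_sided(t: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p: hypergeometric ``P(X >= a)``
    with all margins fixed.  Degenerate tables return 1."""
    return float(stats.hypergeom.sf(t.a - 1, t.n, t.a + t.c, t.a + t.b))


def _fisher_sf_many(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = a + b + c + d
    return stats.hypergeom.sf(a - 1, n, a + c, a + b)


def odds_ratio(t: ContingencyTable) -> float:
    """``(a*d)/(b*c)`` with zero-cell conventions: ``a*d == 0 -> 0``,
    else ``b*c == 0 -> +inf``; never NaN."""
    ad, bc = t.a * t.d, t.b * t.c
    if ad == 0:
        return 0.0
    if bc == 0:
        return math.inf
    return ad / bc


def _odds_ratio_many(a, b, c, d) -> np.ndarray:
    ad = (a * d).astype(float)
    bc = (b * c).astype(float)
    out = np.full(ad.shape, np.inf)
    np.divide(ad, bc, out=out, where=bc > 0)
    out[ad == 0] = 0.0
    return out


def build_single_table(
    query_size: int, set_size: int, overlap: int, background: int
) -> ContingencyTable:
    """Assemble the 2x2 table from the three observed margins."""
    if overlap > min(query_size, set_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(query_size={query_size}, set_size={set_size})"
        )
    if background < query_size + set_size - overlap:
        raise ValueError(
            f"background {background} smaller than the union "
            f"query_size + set_size - overlap = {query_size + set_size - overlap}"
        )
    return ContingencyTable(
        a=overlap,
        b=query_size - overlap,
        c=set_size - overlap,
        d=background - query_size - set_size + overlap,
    )


def mimicker_reverser_overlaps(
    up_q: np.ndarray,
    down_q: np.ndarray,
    up_s: np.ndarray,
    down_s: np.ndarray,
    universe: GeneUniverse,
) -> tuple[int, frozenset[str], int, frozenset[str]]:
    """Mimicker and reverser overlaps of one query pair vs one stored pair.

    mimic  = |up_q & up_s| + |down_q & down_s|
    reverse = |up_q & down_s| + |down_q & up_s|

    returned with the corresponding gene lists.  The query halves must be
    disjoint.
    """
    if int(np.bitwise_count(up_q & down_q).sum()) != 0:
        raise ValueError("query up and down halves overlap")
    mimic_mask_u = up_q & up_s
    mimic_mask_d = down_q & down_s
    rev_mask_u = up_q & down_s
    rev_mask_d = down_q & up_s
    mimic = int(np.bitwise_count(mimic_mask_u).sum() + np.bitwise_count(mimic_mask_d).sum())
    reverse = int(np.bitwise_count(rev_mask_u).sum() + np.bitwise_count(rev_mask_d).sum())
    mimic_genes = universe.unmask(mimic_mask_u) | universe.unmask(mimic_mask_d)
    rev_genes = universe.unmask(rev_mask_u) | universe.unmask(rev_mask_d)
    return mimic, frozenset(mimic_genes), reverse, frozenset(rev_genes)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1,
    order-preserving with the input positions."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def _sort_key(res: EnrichmentResult):
    # p asc -> odds ratio desc -> overlap desc -> label asc
    return (res.p_value, -res.odds_ratio, -res.overlap_count, res.meta.signature_id)


def _finalize(
    metas: Sequence[SignatureMeta],
    roles: Sequence[str],
    overlaps: np.ndarray,
    set_sizes: np.ndarray,
    ors: np.ndarray,
    ps: np.ndarray,
    params: SearchParams,
    gene_lookup,
) -> list[EnrichmentResult]:
    adj = bh_adjust(ps)
    results = [
        EnrichmentResult(
            meta=metas[i],
            role=roles[i],
            overlap_count=int(overlaps[i]),
            set_size=int(set_sizes[i]),
            odds_ratio=float(ors[i]),
            p_value=float(ps[i]),
            adj_p_value=float(adj[i]),
            rank=0,
        )
        for i in range(len(metas))
        if not (params.apply_threshold and ps[i] >= params.significance_threshold)
    ]
    results.sort(key=_sort_key)
    if params.max_results is not None:
        results = results[: params.max_results]
    out = []
    for rank, res in enumerate(results, start=1):
        genes = gene_lookup(res) if gene_lookup is not None else None
        out.append(replace(res, rank=rank, overlap_genes=genes))
    return out


def search_single(
    query: GeneSet,
    index: BitIndex,
    params: SearchParams = SearchParams(),
    collect_genes: bool = True,
) -> list[EnrichmentResult]:
    """Fisher-test a single query set against every stored row.

    Each row keeps its own direction as the result role.  BH adjustment spans
    all tested rows; ranking is total (p asc, odds ratio desc, overlap desc,
    label asc) and ranks are reassigned 1..n over the returned hits.
    """
    resolved, unresolved = index.universe.resolve(query.members)
    if not resolved:
        raise EmptyQueryError(unresolved)
    mask = index.universe.mask(resolved)
    q_size = len(set(resolved))
    background = params.background_size or index.universe.size
    overlaps = index.overlap_counts(mask)
    set_sizes = index.set_sizes
    a = overlaps
    b = q_size - a
    c = set_sizes - a
    d = background - a - b - c
    if np.any(d < 0):
        raise ValueError("background smaller than a query/set union; enlarge background_size")
    ps = _fisher_sf_many(a, b, c, d)
    ors = _odds_ratio_many(a, b, c, d)
    metas = [m for m, _ in index.row_meta]
    roles = [role for _, role in index.row_meta]
    row_of = {id(m): i for i, m in enumerate(metas)}

    def gene_lookup(res: EnrichmentResult) -> Optional[frozenset[str]]:
        if not collect_genes:
            return None
        return index.row_genes(row_of[id(res.meta)], mask)

    return _finalize(metas, roles, overlaps, set_sizes, ors, ps, params, gene_lookup)


def search_paired(
    up_query: GeneSet,
    down_query: GeneSet,
    index: BitIndex,
    params: SearchParams = SearchParams(),
    collect_genes: bool = True,
) -> list[EnrichmentResult]:
    """Search an up/down query pair: one mimicker and one reverser test per
    stored pair, BH-adjusted jointly over all ``2 * n_pairs`` tests.

    One query half may resolve to zero genes (the search degenerates to the
    other half); resolving to zero on both halves is an error, as is a
    non-disjoint pair after resolution.
    """
    res_up, unres_up = index.universe.resolve(up_query.members)
    res_down, unres_down = index.universe.resolve(down_query.members)
    if not res_up and not res_down:
        raise EmptyQueryError(unres_up + unres_down)
    if set(res_up) & set(res_down):
        raise ValueError(
            f"query halves share genes after resolution: {sorted(set(res_up) & set(res_down))}"
        )
    up_mask = index.universe.mask(res_up)
    down_mask = index.universe.mask(res_down)
    q_size = len(set(res_up)) + len(set(res_down))
    background = params.background_size or index.universe.size

    up_rows = index.rows[0::2]
    down_rows = index.rows[1::2]
    pop = index.set_sizes
    pair_sizes = pop[0::2] + pop[1::2]

    def _pc(rows, mask):
        return np.bitwise_count(rows & mask[np.newaxis, :]).sum(axis=1).astype(np.int64)

    mimic = _pc(up_rows, up_mask) + _pc(down_rows, down_mask)
    reverse = _pc(up_rows, down_mask) + _pc(down_rows, up_mask)

    overlaps = np.concatenate([mimic, reverse])
    set_sizes = np.concatenate([pair_sizes, pair_sizes])
    a = overlaps
    b = q_size - a
    c = set_sizes - a
    d = background - a - b - c
    if np.any(d < 0):
        raise ValueError("background smaller than a query/set union; enlarge background_size")
    ps = _fisher_sf_many(a, b, c, d)
    ors = _odds_ratio_many(a, b, c, d)

    pair_metas = [replace(m, signature_id=_base_id(m), direction=None) for m, _ in index.row_meta[0::2]]
    metas = pair_metas + pair_metas
    n = len(pair_metas)
    roles = ["mimicker"] * n + ["reverser"] * n
    pos_of = {(id(m), r): i for i, (m, r) in enumerate(zip(metas, roles))}

    def gene_lookup(res: EnrichmentResult) -> Optional[frozenset[str]]:
        if not collect_genes:
            return None
        k = pos_of[(id(res.meta), res.role)] % n
        if res.role == "mimicker":
            mu = index.universe.unmask(up_rows[k] & up_mask)
            md = index.universe.unmask(down_rows[k] & down_mask)
        else:
            mu = index.universe.unmask(down_rows[k] & up_mask)
            md = index.universe.unmask(up_rows[k] & down_mask)
        return frozenset(mu | md)

    return _finalize(metas, roles, overlaps, set_sizes, ors, ps, params, gene_lookup)


def _base_id(meta: SignatureMeta) -> str:
    from .store import split_direction

    base, _ = split_direction(meta.signature_id)
    return base


def filter_results(
    results: Sequence[EnrichmentResult],
    fda_only: bool = False,
    ko_only: bool = False,
    role: Optional[str] = None,
    direction: Optional[str] = None,
    term: Optional[str] = None,
) -> list[EnrichmentResult]:
    """Conjunctive post-filters over a ranked result list; ranks reassigned.

    *term* is matched case-insensitively against the perturbation name and the
    signature id.
    """
    t = term.lower() if term else None
    kept = []
    for r in results:
        if fda_only and not r.meta.fda_approved:
            continue
        if ko_only and r.meta.perturbation_kind != "crispr_ko":
            continue
        if role is not None and r.role != role:
            continue
        if direction is not None and r.meta.direction != direction:
            continue
        if t is not None and t not in r.meta.perturbation.lower() and t not in r.meta.signature_id.lower():
            continue
        kept.append(r)
    return [replace(r, rank=i) for i, r in enumerate(kept, start=1)]


def results_to_frame(results: Sequence[EnrichmentResult]):
    """Result list as a pandas DataFrame with the standard TSV columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "signature_id": [r.meta.signature_id for r in results],
            "perturbation": [r.meta.perturbation for r in results],
            "perturbation_kind": [r.meta.perturbation_kind for r in results],
            "cell_line": [r.meta.cell_line for r in results],
            "time_point": [r.meta.time_point for r in results],
            "concentration": [r.meta.concentration for r in results],
            "role": [r.role for r in results],
            "set_size": [r.set_size for r in results],
            "overlap": [r.overlap_count for r in results],
            "overlap_genes": [
                ";".join(sorted(r.overlap_genes)) if r.overlap_genes is not None else ""
                for r in results
            ],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p_value": [r.adj_p_value for r in results],
            "rank": [r.rank for r in results],
        }
    )
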