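"""ROC recovery benchmark for consensus perturbation ranking methods.

The design: query the index with signature pairs derived independently for a
known *target* perturbation, rank perturbations with a consensus method, and
score how highly the target ranks.  Each consensus-listed perturbation becomes
one binary decision (1 iff it is the query's target) scored by its negative
consensus position; decisions are pooled across queries into one ROC curve and
its AUC.  Perturbations absent from a consensus list receive the worst score
by default (a flag drops them instead).

``auc_vs_n_sweep`` repeats the benchmark over a grid of top-N window sizes and
over three query modes — up half only, down half only, and the up/down pair —
to expose how the leading-edge size and query pairing affect recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn import metrics as _skm

from .consensus import (
    ConsensusParams,
    extract_rank_vectors,
    ks_consensus,
    mw_consensus,
    topn_consensus,
)
from .engine import EnrichmentResult, SearchParams, search_paired, search_single
from .store import BitIndex, GeneSet

__all__ = [
    "METHODS",
    "MODES",
    "LabeledQuery",
    "BenchmarkCurve",
    "roc_auc",
    "consensus_order",
    "recovery_benchmark",
    "benchmark_suite",
    "auc_vs_n_sweep",
]

METHODS = ("topn", "ks-uniform", "ks-normal", "mw")
MODES = ("up", "down", "paired")


@dataclass(frozen=True)
class LabeledQuery:
    """An up/down query pair labelled with the perturbation that produced it."""

    query_id: str
    up: GeneSet
    down: Optional[GeneSet]
    target_perturbation: str


@dataclass(frozen=True)
class BenchmarkCurve:
    method: str
    mode: str
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def n_decisions(self) -> int:
        return int(self.labels.size)


def synthetic_recovery_setup(
    seed: int,
    signal_fraction: float = 0.6,
    n_targets: int = 3,
    n_queries_per_target: int = 25,
    library_spec=None,
):
    """Build the standard synthetic recovery benchmark: a default library, its
    bit index, and labeled query collections for *n_targets* perturbations
    (chosen pseudo-randomly from the library) with *n_queries_per_target*
    queries each.  Returns ``(index, queries, truth)``."""
    from .store import build_bit_index, build_universe
    from .synthetic import LibrarySpec, QuerySpec, generate_library, generate_queries

    spec = library_spec or LibrarySpec(signal_fraction=signal_fraction, seed=seed)
    pairs, truth = generate_library(spec)
    index = build_bit_index(pairs, build_universe(pairs))
    rng = np.random.default_rng(seed + 1)
    targets = [str(t) for t in rng.choice(sorted(truth.effects), size=n_targets, replace=False)]
    queries: list[LabeledQuery] = []
    for i, t in enumerate(targets):
        queries.extend(
            generate_queries(
                QuerySpec(
                    target_perturbation=t,
                    signal_fraction=signal_fraction,
                    n_queries=n_queries_per_target,
                    seed=seed + 100 + i,
                ),
                truth,
            )
        )
    return index, queries, truth


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """Standard ROC (descending score, ties pooled) and trapezoid AUC.

    Returns ``(fpr, tpr, auc)``.  Raises on single-class labels.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    return fpr, tpr, float(_skm.auc(fpr, tpr))


def consensus_order(
    results: Sequence[EnrichmentResult],
    method: str,
    params: ConsensusParams = ConsensusParams(),
) -> list[str]:
    """Perturbations in consensus order (best first) under *method*."""
    if method == "topn":
        return [r.perturbation for r in topn_consensus(results, params)]
    vectors = extract_rank_vectors(results, min_signatures=params.min_signatures)
    if method == "ks-uniform":
        return [p for p, _ in ks_consensus(vectors, reference="uniform")]
    if method == "ks-normal":
        return [p for p, _ in ks_consensus(vectors, reference="normal")]
    if method == "mw":
        return [p for p, _, _ in mw_consensus(vectors)]
    raise ValueError(f"unknown consensus method {method!r}; expected one of {METHODS}")


def _search_for_mode(
    q: LabeledQuery, index: BitIndex, mode: str, params: SearchParams
) -> list[EnrichmentResult]:
    if mode == "paired":
        down = q.down if q.down is not None else GeneSet(q.query_id + " down", frozenset())
        return search_paired(q.up, down, index, params, collect_genes=False)
    if mode == "up":
        return search_single(q.up, index, params, collect_genes=False)
    if mode == "down":
        if q.down is None:
            raise ValueError(f"query {q.query_id!r} has no down half")
        return search_single(q.down, index, params, collect_genes=False)
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _pool_decisions(
    per_query: Sequence[tuple[LabeledQuery, list[str]]],
    all_perturbations: Sequence[str],
    impute_missing: bool,
):
    """Turn per-query consensus orders into pooled (scores, labels)."""
    worst = -(len(all_perturbations) + 1.0)
    scores: list[float] = []
    labels: list[int] = []
    for q, order in per_query:
        pos = {p: i for i, p in enumerate(order, start=1)}
        universe = all_perturbations if impute_missing else order
        for p in universe:
            if p in pos:
                scores.append(-float(pos[p]))
            elif impute_missing:
                scores.append(worst)
            else:
                continue
            labels.append(1 if p == q.target_perturbation else 0)
    return np.asarray(scores), np.asarray(labels)


def _curve_from_orders(per_query, all_perts, method, mode, impute_missing) -> BenchmarkCurve:
    scores, labels = _pool_decisions(per_query, all_perts, impute_missing)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        raise ValueError(
            f"benchmark for method={method!r} mode={mode!r} is degenerate: the targets "
            "never appear in any consensus list (single-class labels)"
        )
    fpr, tpr, auc = roc_auc(scores, labels)
    return BenchmarkCurve(method, mode, scores, labels, fpr, tpr, auc)


def recovery_benchmark(
    queries: Sequence[LabeledQuery],
    index: BitIndex,
    method: str = "topn",
    mode: str = "paired",
    search_params: SearchParams = SearchParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
    impute_missing: bool = True,
) -> BenchmarkCurve:
    """Pooled ROC/AUC of target recovery for one consensus method and mode."""
    if len(queries) < 2:
        raise ValueError("need at least 2 labeled queries")
    per_query = [
        (q, consensus_order(_search_for_mode(q, index, mode, search_params), method, consensus_params))
        for q in queries
    ]
    return _curve_from_orders(per_query, index.perturbations(), method, mode, impute_missing)


def benchmark_suite(
    queries: Sequence[LabeledQuery],
    index: BitIndex,
    methods: Sequence[str] = METHODS,
    mode: str = "paired",
    search_params: SearchParams = SearchParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
    impute_missing: bool = True,
) -> dict[str, BenchmarkCurve]:
    """Evaluate several consensus methods on one shared set of searches.

    Runs each query's search once and reuses the ranked results across
    methods; equivalent to calling :func:`recovery_benchmark` per method.
    """
    if len(queries) < 2:
        raise ValueError("need at least 2 labeled queries")
    searches = [(q, _search_for_mode(q, index, mode, search_params)) for q in queries]
    all_perts = index.perturbations()
    out: dict[str, BenchmarkCurve] = {}
    for method in methods:
        per_query = [(q, consensus_order(res, method, consensus_params)) for q, res in searches]
        out[method] = _curve_from_orders(per_query, all_perts, method, mode, impute_missing)
    return out


def auc_vs_n_sweep(
    queries: Sequence[LabeledQuery],
    index: BitIndex,
    n_grid: Sequence[int],
    modes: Sequence[str] = MODES,
    search_params: SearchParams = SearchParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
    impute_missing: bool = True,
):
    """Top-N consensus AUC across a grid of window sizes and query modes.

    Returns a pandas DataFrame with columns ``N``, ``mode``, ``auc``.  Searches
    are run once per (query, mode) and the consensus recomputed per window.
    """
    import pandas as pd

    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    if list(n_grid) != sorted(n_grid):
        raise ValueError("n_grid must be ascending")
    rows = []
    all_perts = index.perturbations()
    for mode in modes:
        searches = [(q, _search_for_mode(q, index, mode, search_params)) for q in queries]
        for n in n_grid:
            cp = ConsensusParams(
                top_n=int(n),
                min_signatures=consensus_params.min_signatures,
                significance_threshold=consensus_params.significance_threshold,
            )
            per_query = [(q, consensus_order(res, "topn", cp)) for q, res in searches]
            curve = _curve_from_orders(per_query, all_perts, "topn", mode, impute_missing)
            rows.append({"N": int(n), "mode": mode, "auc": curve.auc})
    return pd.DataFrame(rows)
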