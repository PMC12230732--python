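"""Seeded generator of synthetic perturbation-signature libraries and queries.

The generator emulates the statistical structure of a large perturbational
signature resource: many perturbations (compounds and CRISPR KOs), each
profiled in several contexts (cell line, time point, concentration), with each
context contributing one up- and one down-regulated gene set over a fixed gene
universe.  Every perturbation owns disjoint "true effect" up/down gene sets;
each of its signatures draws a fraction of its members from those effect sets
(the signal) and fills the rest with background genes sampled outside them, so
signatures of one perturbation cohere across contexts exactly as the search
and consensus methods assume.

The number of signal genes per signature is ``round(signal_fraction *
signature_set_size)`` capped at ``effect_size``; with the defaults
(fraction 0.6, set size 250, effect size 100) the cap binds and every
signature carries the full effect set, i.e. a strongly planted signal.
Setting ``signal_fraction = 0`` yields a pure-noise (null) library.

All randomness flows from the single seed in the spec; identical seeds
reproduce identical libraries byte-for-byte when written as GMT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmark import LabeledQuery
from .store import GeneSet, SignaturePair, pair_signatures

__all__ = [
    "LibrarySpec",
    "QuerySpec",
    "TruthTable",
    "generate_library",
    "generate_gene_sets",
    "generate_queries",
    "expected_same_target_overlap",
]

_CELL_LINES = ("HCC515", "MCF7", "PC3", "A375", "HA1E", "HT29")
_TIME_POINTS = ("3H", "6H", "24H")
_CONCENTRATIONS = ("10 uM", "3.33 uM", "1.11 uM", "0.37 uM")


@dataclass(frozen=True)
class LibrarySpec:
    """Shape of a synthetic signature library.

    Defaults give 100 perturbations x 20 contexts = 2 000 signature pairs
    (4 000 index rows) over a 2 000-gene universe, with 250-gene signatures of
    which up to ``effect_size`` genes are perturbation-specific signal.
    """

    universe_size: int = 2_000
    n_perturbations: int = 100
    contexts_per_perturbation: int = 20
    effect_size: int = 100
    signature_set_size: int = 250
    signal_fraction: float = 0.6
    seed: int = 0
    crispr_fraction: float = 0.1
    fda_fraction: float = 0.25
    background_skew: float = 0.0  # >0: power-law gene-frequency skew

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must lie in [0, 1]")
        if not (self.effect_size <= self.signature_set_size <= self.universe_size // 2):
            raise ValueError(
                "need effect_size <= signature_set_size <= universe_size / 2"
            )
        if self.universe_size < 2 * self.signature_set_size:
            raise ValueError("universe too small for the background draw")

    @property
    def n_signal(self) -> int:
        """Signal genes per signature: fraction of the set size, capped at the
        effect-set size."""
        return min(round(self.signal_fraction * self.signature_set_size), self.effect_size)


@dataclass(frozen=True)
class QuerySpec:
    """Shape of a labeled query collection for one target perturbation."""

    target_perturbation: str
    query_size: int = 250
    signal_fraction: float = 0.6
    n_queries: int = 25
    seed: int = 0
    reversed_halves: bool = False  # swap up/down to probe reverser recovery

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.n_queries < 1 or self.query_size < 1:
            raise ValueError("n_queries and query_size must be positive")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a generated library."""

    effects: dict[str, tuple[frozenset[str], frozenset[str]]]  # pert -> (up, down)
    universe_symbols: tuple[str, ...]
    ko_genes: frozenset[str]
    fda_compounds: frozenset[str]
    spec: LibrarySpec


def _symbols(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _draw_signature(
    rng: np.random.Generator,
    eff_up: np.ndarray,
    eff_down: np.ndarray,
    universe_size: int,
    n_signal: int,
    set_size: int,
    skew: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one (up, down) pair of gene-index arrays.

    Background genes are drawn without replacement from the whole universe
    minus the already-drawn signal genes (not minus the full effect sets), so
    a zero-signal library is fully exchangeable across perturbations.
    """
    up_sig = rng.choice(eff_up, size=n_signal, replace=False) if n_signal else eff_up[:0]
    down_sig = rng.choice(eff_down, size=n_signal, replace=False) if n_signal else eff_down[:0]
    n_bg = set_size - n_signal
    pool = np.setdiff1d(np.arange(universe_size), np.concatenate([up_sig, down_sig]))
    if skew > 0:
        w = (pool + 1.0) ** (-skew)
        bg = rng.choice(pool, size=2 * n_bg, replace=False, p=w / w.sum())
    else:
        bg = rng.choice(pool, size=2 * n_bg, replace=False)
    return np.concatenate([up_sig, bg[:n_bg]]), np.concatenate([down_sig, bg[n_bg:]])


def generate_gene_sets(spec: LibrarySpec) -> tuple[list[GeneSet], TruthTable]:
    """Generate the raw up/down :class:`GeneSet` lines of a synthetic library.

    Labels follow the grammar ``batch_cell_time_well_pert_conc direction`` so
    that metadata parsing, pairing, and filtering are all exercised on
    generator output.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = np.array(_symbols(spec.universe_size))

    n_ko = round(spec.crispr_fraction * spec.n_perturbations)
    n_chem = spec.n_perturbations - n_ko
    ko_targets = rng.choice(spec.universe_size, size=n_ko, replace=False)
    ko_genes = [str(symbols[i]) for i in ko_targets]
    chems = [f"CPD{i:03d}" for i in range(n_chem)]
    perturbations = chems + ko_genes
    n_fda = round(spec.fda_fraction * n_chem)
    fda = frozenset(str(c) for c in rng.choice(chems, size=n_fda, replace=False)) if n_fda else frozenset()

    effects: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    sets: list[GeneSet] = []
    wells = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]
    for pert in perturbations:
        eff = rng.choice(spec.universe_size, size=2 * spec.effect_size, replace=False)
        eff_up, eff_down = eff[: spec.effect_size], eff[spec.effect_size :]
        effects[pert] = (
            frozenset(symbols[eff_up]),
            frozenset(symbols[eff_down]),
        )
        for ctx in range(spec.contexts_per_perturbation):
            cell = str(rng.choice(_CELL_LINES))
            time = str(rng.choice(_TIME_POINTS))
            conc = str(rng.choice(_CONCENTRATIONS))
            well = str(rng.choice(wells))
            base = f"B{ctx:03d}_{cell}_{time}_{well}_{pert}_{conc}"
            up_idx, down_idx = _draw_signature(
                rng,
                eff_up,
                eff_down,
                spec.universe_size,
                spec.n_signal,
                spec.signature_set_size,
                spec.background_skew,
            )
            sets.append(GeneSet(f"{base} up", frozenset(symbols[up_idx]), "synthetic"))
            sets.append(GeneSet(f"{base} down", frozenset(symbols[down_idx]), "synthetic"))
    truth = TruthTable(
        effects=effects,
        universe_symbols=tuple(str(s) for s in symbols),
        ko_genes=frozenset(ko_genes),
        fda_compounds=fda,
        spec=spec,
    )
    return sets, truth


def generate_library(spec: LibrarySpec) -> tuple[list[SignaturePair], TruthTable]:
    """Generate a paired synthetic library and its ground truth."""
    sets, truth = generate_gene_sets(spec)
    pairs, unpaired = pair_signatures(sets, ko_genes=truth.ko_genes, fda_compounds=truth.fda_compounds)
    assert not unpaired, "generator emits complete up/down pairs"
    return pairs, truth


def generate_queries(qspec: QuerySpec, truth: TruthTable) -> list[LabeledQuery]:
    """Labeled up/down query pairs drawn from one target's effect sets with the
    same signal/background mixing as the library signatures."""
    if qspec.target_perturbation not in truth.effects:
        raise KeyError(f"unknown target perturbation {qspec.target_perturbation!r}")
    rng = np.random.default_rng(qspec.seed)
    spec = truth.spec
    symbols = np.array(truth.universe_symbols)
    sym_index = {s: i for i, s in enumerate(truth.universe_symbols)}
    eff_up_syms, eff_down_syms = truth.effects[qspec.target_perturbation]
    eff_up = np.array(sorted(sym_index[s] for s in eff_up_syms))
    eff_down = np.array(sorted(sym_index[s] for s in eff_down_syms))
    n_signal = min(round(qspec.signal_fraction * qspec.query_size), eff_up.size)
    if symbols.size < 2 * qspec.query_size:
        raise ValueError("universe too small for the query background draw")
    queries: list[LabeledQuery] = []
    for i in range(qspec.n_queries):
        up_idx, down_idx = _draw_signature(
            rng, eff_up, eff_down, symbols.size, n_signal, qspec.query_size, spec.background_skew
        )
        if qspec.reversed_halves:
            up_idx, down_idx = down_idx, up_idx
        qid = f"{qspec.target_perturbation}-q{i:03d}"
        queries.append(
            LabeledQuery(
                query_id=qid,
                up=GeneSet(f"{qid} up", frozenset(symbols[up_idx])),
                down=GeneSet(f"{qid} down", frozenset(symbols[down_idx])),
                target_perturbation=qspec.target_perturbation,
            )
        )
    return queries


def expected_same_target_overlap(
    spec: LibrarySpec, query_size: int, query_signal_fraction: float
) -> float:
    """Analytic expected per-half (up vs up) overlap between a query and a
    same-target signature.

    Sums per-gene inclusion probabilities over the three gene strata (the
    target's up-effect genes, its down-effect genes, the rest), treating the
    two draws as independent; the without-replacement correlation it neglects
    is small at realistic sizes.
    """
    U, E = spec.universe_size, spec.effect_size
    m_s, S = spec.n_signal, spec.signature_set_size
    m_q = min(round(query_signal_fraction * query_size), E)
    b_s = (S - m_s) / (U - 2 * m_s)
    b_q = (query_size - m_q) / (U - 2 * m_q)
    p_s_up = m_s / E + (1 - m_s / E) * b_s
    p_q_up = m_q / E + (1 - m_q / E) * b_q
    p_s_dn = (1 - m_s / E) * b_s
    p_q_dn = (1 - m_q / E) * b_q
    return E * p_s_up * p_q_up + E * p_s_dn * p_q_dn + (U - 2 * E) * b_s * b_q
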