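# Methods

## Search model

A signature library is a collection of perturbation-in-context entries, each
contributing one up-regulated and one down-regulated gene set. The gene
universe is the sorted union of all member symbols in the loaded library
(plus optional extras); it defines both the bit positions of the index and
the background margin *B* of every contingency table. Symbols are uppercased
before matching; no alias resolution is attempted.

Each stored set is one packed bit row. A query mask ANDed with a row and
popcounted gives the overlap *a*, which together with the query size *q*,
set size *s*, and background *B* fills the 2×2 table
(a, q−a, s−a, B−q−s+a). Significance is the one-sided Fisher exact
(hypergeometric upper-tail) p-value. One-sidedness is deliberate: a
two-sided test would also rank depleted overlaps, which is meaningless for
connectivity search. Degenerate tables return p = 1, and the odds ratio
conventions are (a·d)/(b·c) with a·d = 0 → 0 and b·c = 0 (with a·d > 0) →
+∞, never NaN.

For paired queries, each stored pair is tested twice — once with the
mimicker overlap (same-direction intersections summed) and once with the
reverser overlap (cross-direction) — using the summed query and set sizes
in a single shared background. Because the two overlap terms draw from
disjoint halves, a random pair's mimicker overlap is systematically *below*
the hypergeometric expectation for the summed sizes; the test is therefore
conservative for unrelated signatures, which suits a search engine that
should only surface strong concordance.

BH adjustment spans all tests of one submission (all rows for a single-set
query; all 2·n_pairs tests jointly for a paired query) — that is the family
of hypotheses actually evaluated. The default return gate is raw p < 0.05
(a flag disables it); adjusted p-values are reported alongside. Ranking is
total and deterministic: p ascending, then odds ratio descending, overlap
descending, label ascending.

## Consensus ranking

Perturbations with at least `min_signatures` (default 10) results are
aggregated three ways:

* **Top-N Fisher** (default N = 10 000): the table (a, b, c, d) counts the
  perturbation's up-role vs down-role results inside vs outside the top-N
  positions of the one global ranking (mimickers and reversers interleaved);
  one-sided Fisher for the consensus-up direction, the column-flipped table
  for consensus-down. Each direction family is BH-adjusted across
  perturbations, and output is ordered by min(adj_p_up, adj_p_down) with
  deterministic tie-breaks (smaller raw p, larger in-window count,
  perturbation name).
* **KS**: two-sided Kolmogorov–Smirnov statistic of the perturbation's ranks
  normalized by the list length, against U(0,1) or against a normal whose
  mean and standard deviation are those of the normalized ranks of the whole
  list (the reference parameterization was an open choice; fitting to the
  pooled ranks makes the reference library-independent). Perturbations are
  ordered by D descending. Singleton vectors are allowed (one-point ECDF).
* **MW**: U = R₁ − n₁(n₁+1)/2 of the perturbation's ranks against all other
  results' ranks, ordered ascending so top-concentrated perturbations come
  first; the asymptotic one-sided p accompanies the statistic.

The rank-based methods default to operating on the thresholded (p < 0.05)
result list. This matters: on an unthresholded list a true target's
near-null reverser rows sit at random positions and dilute its MW/KS
ranking, whereas the Top-N table treats them correctly as the b/d cells.

## Recovery benchmark

Labeled queries (independent signature pairs for a known target) are
searched, ranked by a consensus method, and every consensus-listed
perturbation becomes one pooled binary decision scored by its negative list
position. Perturbations absent from a list are imputed the worst score
(−(#perturbations + 1)) so that every query contributes a complete decision
set; a flag drops them instead, which reproduces the "fewer entries" variant
where absent targets simply leave the curve. Pooling across queries (rather
than averaging per-query AUCs) is used throughout. ROC/AUC computation uses
scikit-learn with ties pooled; AUC equals the concordant-pair probability.

## Synthetic data

The generator emulates a perturbational signature resource: each
perturbation owns disjoint true-effect up/down sets (`effect_size` genes
each, default 100) sampled from a `universe_size`-gene vocabulary (default
2 000, in the spirit of the ~1 000 landmark genes of high-throughput
transcriptional profiling, doubled to give background headroom). Each of
`contexts_per_perturbation` (default 20) contexts draws a signature pair:
`round(signal_fraction × signature_set_size)` genes from the effect set
(capped at `effect_size`) plus background genes sampled uniformly from the
universe *minus the drawn signal genes*. The exclusion is deliberately
minimal: excluding the full effect sets would leak perturbation identity
through the background pool and bias a zero-signal library away from
chance-level recovery. Defaults: set size 250 (a typical thresholded
signature size), signal fraction 0.6 — at which the cap binds, so default
signatures carry their full effect set; weaker regimes are reached by
lowering `signal_fraction` or raising `signature_set_size`. 10% of
perturbations are CRISPR KOs (named by their target gene), 25% of compounds
are flagged FDA-approved, and context metadata is drawn from small fixed
vocabularies so that the label grammar
(`batch_cell_time_well_pert_conc direction`) and every results-table filter
are exercised. An optional power-law `background_skew` stresses BH and
odds-ratio behaviour under non-uniform gene usage.

Queries are drawn by the same recipe from a target's effect sets; a
`reversed_halves` flag swaps the halves to probe reverser recovery. The
expected per-half overlap between a query and a same-target signature has a
closed form (per-gene inclusion probabilities summed over the three gene
strata), tested against simulation.

What the generator does **not** model: expression-level noise,
landmark-vs-inferred gene reliability, gene–gene correlation, dose/time
response structure, or realistic per-perturbation signature-count imbalance
(all perturbations get equal context counts unless varied by hand). Passing
benchmarks on synthetic data therefore demonstrate the correctness and
relative behaviour of the statistics, not field performance on real
libraries.

## Benchmark conditions and problem sizes

The standard synthetic benchmark uses the library defaults (100 × 20 pairs,
4 000 rows), 3 targets × 25 queries, and a top-N window of 1 000 — a quarter
of the result list, playing the role that a 10 000 window plays against a
multi-million-row production library (the default N = 10 000 would exceed
the whole synthetic list and degenerate every table to its up/down split,
which is exercised separately as the saturation identity). The window sweep
uses N ∈ {100, 500, 1 000, 2 000, 4 000}. The null benchmark sets
signal_fraction = 0 in both library and queries and searches without the
significance gate, since a gated null search returns (correctly) nothing.
At these defaults the planted signal is strong and all four methods saturate
near AUC 1; the interesting orderings emerge at lower signal fractions.

## Numerical choices

* Fisher tails come from `scipy.stats.hypergeom.sf`, vectorized across rows;
  agreement with exact integer enumeration is verified to ≤ 10⁻¹² over every
  table with all margins ≤ 50 and random larger tables.
* BH uses `scipy.stats.false_discovery_control`, cross-checked against the
  literal step-up definition and statsmodels.
* Bit rows are uint8-packed numpy arrays (`np.bitwise_count` popcounts); the
  index serializes to a versioned `.npz` that round-trips bit-exactly.
* All randomness flows from explicit `numpy.random.default_rng` seeds; GMT
  output writes members sorted, so equal seeds give byte-identical files.
* Ties: every ranking has a total deterministic order (documented above);
  ranks are reassigned 1..n after any filtering.

## Known limitations

* The mimicker/reverser construction takes the summed-overlap definition
  literally; a gene shared between one signature's up set and another's down
  set can contribute to both a mimic and a reverse count across different
  pairs.
* Whether mimicker and reverser families should be BH-adjusted jointly or
  separately is a design choice; joint adjustment (one submission = one
  family) is implemented.
* The p < 0.05 return gate is applied to raw p-values; gating on adjusted
  values would be stricter and is not currently exposed.
* Consensus-of-mechanism-of-action rollups are out of scope; MoA annotation
  is a post-hoc join on the perturbation column.
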