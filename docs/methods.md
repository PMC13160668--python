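# Methods

This note documents the models and procedures implemented in `themescape`,
the parameter conventions, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Corpus model and normalization

A corpus is a list of records with title, abstract, year, journal, author
keywords, MeSH terms, affiliations, and an optional relative citation ratio
(RCR). Retention requires a non-empty abstract, at least one author keyword,
and a year inside the study window; the counts log keeps the arithmetic
identity `retained = retrieved − excluded` on every run. The year is the
first 4-digit token of the publication-date field; records without one are
excluded with a logged reason, since every downstream stage (recency,
bursts, slices) is year-indexed.

Keyword normalization applies, in order: lowercasing and whitespace
collapse, abbreviation expansion, synonym mapping, MeSH entry-term mapping,
plural folding, and per-record deduplication. Plural folding is deliberately
conservative — a trailing `s`/`es` is stripped only when the singular form
is attested elsewhere in the corpus or as a map target — so lexical
singular-less terms ("measles") are untouched. Each map must be idempotent;
chains and cycles are rejected at construction, which makes the whole
normalization idempotent (tested). Rule tables are user-editable YAML, since
any concrete study's synonym inventory is domain-specific.

Country attribution uses the last comma-separated token of the first
affiliation matched against a bundled country list, with "unknown" as the
fallback; affiliation strings are too heterogeneous for anything stronger
without a geocoding service.

## Keyword selection and co-occurrence weighting

Two rules: drop keywords appearing in fewer than `min_freq = 3` records
(noise suppression), then drop the `drop_top = 2` most frequent survivors
(they co-occur with nearly everything and flatten the network). Boundary
ties at the top-frequency cut are removed reverse-lexicographically and
logged, so the rule is deterministic.

Edge weightings: `raw` (co-occurring record count), `fractional` (default;
a record with m retained keywords adds 1/(m−1) per pair, hence m/2 total —
records with many keywords are not over-weighted), and `association`
(raw / sqrt(freq_a·freq_b)). Fractional is the default because the
reference table's printed strengths are non-integers, which rules out raw
counting; the exact production scheme behind that table is not public, so
the weighting is a configurable enum and exact reproduction of individual
printed strengths is not claimed. Invariants tested: the handshake identity
Σ strength = 2·Σ weights, the per-record m/2 total under fractional
weighting, and record-order independence.

## Semantic backend and hybrid similarity

The semantic space is built from document embeddings of title + abstract.
The backend contract is: deterministic, unit-norm output of fixed dimension.
The shipped backend maps each token to a fixed Gaussian direction seeded by
a stable (MD5-based) hash of the token — directions are corpus-independent —
and embeds a document as the normalized count-weighted sum. By the
Johnson–Lindenstrauss argument, cosine in this space concentrates around
token-overlap cosine (at dimension 256, disjoint token sets give |cos| < 0.2
in all 100 seeded trials). This is exactly the property the pipeline
consumes: token overlap drives similarity. Transformer document encoders
(e.g., biomedical-domain BERT variants) plug into the same interface; when
several backends are configured, each sub-vector is normalized before
concatenation so no backend dominates, then the concatenation is
renormalized.

Keyword semantic vectors are renormalized means of the containing records'
vectors; keywords with no embedded record or a cancelling aggregate are
excluded. Structural similarity between keywords a and b is the cosine of
their co-occurrence weight profiles with positions a and b zeroed in both
rows, so it measures shared third-party neighborhoods, not the direct edge.
Fusion is the convex combination S_hyb = α·S_sem + (1−α)·S_str; keywords
must survive in *both* spaces (a network node and a valid semantic vector)
to enter fusion. α defaults to 0.5 — equal weight absent evidence for
either side — and is exposed in config; the tests sweep α ∈ {0.25, 0.5,
0.75} through the linearity property. The downstream distance is
1 − S_hyb clipped to [0, 2] with a zero diagonal.

## Clustering and presentation conventions

UMAP (n_neighbors = 15, min_dist = 0.1, precomputed metric, fixed
`random_state`, single-threaded) reduces the hybrid distance to 2D; HDBSCAN
clusters the embedding under two named profiles — `balanced`
(min_cluster_size = 8, min_samples = 5) and `fine` (5, 3). Profile values
were chosen once so the balanced profile yields the planted 5 clusters on
the 300-record, 5-topic reference synthetic corpus; both are
config-exposed. Unassigned points are retained as **cluster 1** — treated
as an incubator pool of peripheral or cross-cutting keywords — and thematic
clusters are renumbered 2..C+1 by descending size (ties: lexicographically
smallest member), so numbering is deterministic. Noise is excluded from
silhouette / Calinski–Harabasz / Davies–Bouldin (which assume compact
clusters) but included in the across-seed adjusted Rand index and bootstrap
Jaccard. With fewer than two thematic clusters the geometric metrics are
reported as not-applicable, never coerced to zero. The multi-seed stability
protocol runs 3 seeds {11, 23, 42} by default.

A K-constrained HDBSCAN variant (post-hoc cluster merging to a target K) is
not implemented: HDBSCAN has no K parameter and any merging rule would be
guesswork; the package reports whatever cluster count the density structure
supports.

## Strategic coordinates and octants

x (*maturity*) is the population-standardized keyword frequency — mean(x)=0
holds by construction to 1e-9 and is asserted on every corpus. Population
rather than sample standard deviation is used; both satisfy the centering
identity, and the choice is visible only as a uniform scale factor.
y (*influence*) is the **unstandardized** network strength, so its natural
threshold is the mean strength; on the packaged 78-keyword reference table
that mean is 3.51, matching the table's own octant boundaries, which fixes
the convention. z (*recency*) is the fraction of the keyword's records with
year > reference_year − 5.

The octant planes default to x = 0, y = mean(y), z = 0.5. The source
material for the reference table uses z = 0.5 in its octant definitions but
also reports a mean-z plane of 0.66; both conventions are supported
(`z_mode = "fixed" | "mean"`) and the active mode is written to the run
log. Boundary equality counts as the ≥ side. Seven octant names follow the
reference table; the eighth octant (high maturity, high influence, low
recency) never occurs there, so it carries the package-chosen name "Core
consolidated theme", overridable in config.

## Coupling and dual attribution

Pair coupling is the sum of weights on edges crossing two clusters; the
noise cluster participates as a regular cluster (its values carry a
heterogeneity caveat in the report). A keyword's contribution to a pair is
the total weight of its own crossing edges, crediting **both** endpoints of
every edge; contributions per pair therefore sum to exactly twice the pair
strength. Dual attribution is forced by the packaged coupling table: one
pair's printed top-5 contributions sum to 10.83 against a pair strength of
10.40, impossible under single attribution. The loader enforces the 2×
bound as a sanity check. That table also stores two readings of two pair
strengths (its source's table and body text disagree); both are preserved
rather than silently resolved.

## Burst detection

The batch multi-level Kleinberg automaton: base rate p₀ = Σr/Σd, level-i
rate min(p₀·sⁱ, 1−1e-6) with s = 2 and up to 20 levels (deep levels are
reachable but saturate; the cap keeps log-likelihoods finite). Emitting year
t from level i costs the negative binomial log-likelihood; moving up j−i
levels costs (j−i)·γ·ln(n_years), moving down is free. The optimal state
sequence starts at level 0 and is found by dynamic programming with ties
resolved toward the lower level; maximal runs at level ≥ 1 of duration ≥
min_length become burst intervals, carrying the deepest state reached and
the emission-cost saving versus staying at level 0. The DP is verified
against exhaustive enumeration over all state sequences for short series —
exact agreement on 200 random series — and burst years are empirically
non-increasing in γ.

"Slice width" W is implemented as a centered moving sum of width W (odd,
default 3) applied to both r and d before detection, turning single-year
spikes into multi-year evidence; W = 1 is the identity. Configurations are
named `G<gamma>_W<width>_L<minlen>`, with `G0.5_W3_L1` the baseline. The
robustness grid reports pairwise Jaccard (bursting-keyword sets) and
Spearman (per-keyword burst-year counts) across configurations, plus
**coverage** (fraction of eligible keywords with ≥ 1 burst under the
baseline) and **realism** (mean burst duration in years under the
baseline); these two are operational definitions printed in the report
header, since no canonical formula exists for them.

## Time slices and spectral clustering

Slices default to 2015–2019 / 2020–2023 / 2024–2025 (pre-growth, explosive
growth, consolidation). Each slice re-applies the same frequency filter and
weighting as the global network (shared code path; the config fingerprint
in the log attests it). Spectral clustering uses the symmetric-normalized
Laplacian, the bottom-K eigenvectors row-normalized, and a fully
deterministic k-means: greedy farthest-point initialization seeded by the
run seed, ties to the lowest index. K is scanned over 2..20 (clipped to
n−1); K* maximizes weighted Newman–Girvan modularity
Q = Σ_c [w_in,c/m − (s_c/2m)²], cross-checked against networkx's
implementation in the tests. When the Q curve is flat
(max − median < 0.01), the Davies–Bouldin elbow (largest second difference)
decides instead, and the decision path is logged. Silhouette and CH are
deliberately not used for selection — they are uninformative in the
spectral embedding space. Slice clusters map to the global solution by
best-match Jaccard on keyword sets, matched when above 0.3.

## Validation and trend projection

External validation is strictly post-hoc: RCR is read only here, never by
selection, embedding, or clustering. Per-keyword mean RCR is correlated
with network strength (Spearman ρ); the two-sided p-value comes from ≥ 999
seeded permutations of the strength vector, so p ≥ 1/(n_perm+1) and the
null distribution is uniform (KS-tested at reduced n). The stage is skipped
with an explicit reason when fewer than 10 keywords have RCR-bearing
records.

The trend projection fits ARIMA orders (p, d, q) ∈ {0,1,2}×{0,1}×{0,1} by
AIC on complete years only (the final, possibly partial year never enters
the fit), with a drift term under differencing so a linear series forecasts
its continuation; forecasts and intervals are floored at 0, and a constant
series degenerates to the mean with a nominal interval. With roughly ten
annual observations this is an exploratory projection; the wide intervals
are the honest output.

## Synthetic benchmark: what it shows and what it does not

The generator plants: disjoint (configurable-overlap) topic keyword
vocabularies with a mixture concentration controlling cross-topic
borrowing; topic-conditioned token-bag titles/abstracts; per-topic year
profiles with optional burst windows; keyword-level burst injection as an
independent Bernoulli inclusion whose corpus-wide base rate is multiplied
inside the window (so the in/out count ratio equals the multiplier);
lognormal RCR (σ = 0.5) around a topic mean, optionally with a prevalence
gradient so higher-impact topics also have higher-strength keywords — the
planted effect the RCR validation must detect. All randomness flows from
one integer seed; identical configs are byte-identical.

Reference conditions used throughout the tests: 300 records / 5 topics for
clustering recovery, 400 records / multiplier 5 / 3-year window for burst
recovery, 15-node 3-block planted partitions for spectral K — sizes chosen
to be comfortably inside the method's operating regime while keeping the
suite fast. Passing these benchmarks shows the pipeline recovers structure
*of the kind it assumes*: well-separated vocabularies, stationary topic
mixtures, token-overlap-driven semantics. Real corpora have polysemous
keywords, correlated topics, non-stationary vocabularies, and natural
language abstracts; the synthetic results bound implementation correctness,
not real-world thematic validity. The packaged reference tables provide the
complementary anchor to a real published corpus.

## Interfaces

The library is the primary interface; the `themescape` CLI wraps ingest,
simulation, network construction, burst analysis, and the full pipeline
(`run --config`), whose single YAML document carries every default named
above. The middle pipeline stages (embedding, clustering, mapping,
coupling, slicing, validation) operate on in-memory intermediates and are
exercised through `run`, which writes each stage's CSV/JSON artifacts and a
JSONL run log (config fingerprint, seeds, counts, decision flags). With the
offline backend, artifacts are byte-identical across reruns; the run log
holds the only timestamps.

## Known limitations

- The offline embedding backend captures token overlap only — no synonymy
  without shared tokens; transformer backends are pluggable but optional.
- UMAP determinism is per-platform (fixed seed, single thread), not
  guaranteed across BLAS/OS variants.
- Fixture-exact reproduction of the reference table's individual strengths
  is out of scope (the producing weight normalization is unpublished); the
  package reproduces its *identities* (mean threshold, octant consistency,
  dual attribution) instead.
- Coverage/realism are operational definitions; alternative formulas exist.
- The country heuristic fails on affiliations without a trailing country
  token.
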