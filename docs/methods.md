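# Methods

## Functional labels and TU classification

The unit of "protein function" is the functional label (FL): the canonical
form of a protein's keyword annotation, i.e. the sorted tuple of its unique
keyword IDs. Keywords are opaque, case-sensitive strings; no case folding
or vocabulary mapping is applied, so two spellings that differ only in case
remain distinct labels. A catalogue assigns each distinct nonempty tuple an
identifier `FL{scope}{n}`, where *scope* is an organism mnemonic and *n*
the 1-based rank of the tuple in lexicographic order. The lexicographic
sort key is this package's choice: it makes catalogue construction
deterministic and invariant to input order, which historical id schemes
for the same construction did not guarantee. Consequently ids are stable
across runs but are not comparable to ids issued by other tools.

Proteins without keywords are retained but carry no FL; a TU whose
proteins are all unannotated is classed *unannotated* and excluded from
the monoform/polyform statistics. A TU is *monoform* with exactly one
distinct FL and *polyform* with two or more. The headline summary
statistic is 100·n_poly/n_mono, displayed at two decimals; the polyform
*fraction* n_poly/(n_poly+n_mono) is used for the cross-organism
correlation against the mean splice-variant count (Pearson r, with an
explicit organism exclusion list for outlier handling).

## Functional switches

A switch candidate is an annotated isoform pair within one polyform TU
whose keyword sets are disjoint — Jaccard index 0, distance 1. Disjointness
is the operative criterion because a genuine functional switch (e.g. from
protease activity to oxygen transport) implies no shared annotation at
all. Pairs involving an unannotated protein are skipped, since the Jaccard
index is undefined against an empty set. The switch fraction is reported
over annotated TUs by default; the denominator is configurable (all TUs or
polyform TUs) because the population of a percentage like this is a
reporting convention, not a property of the data.

## Frequency distributions and their models

Three relation histograms are computed over annotated TUs: distinct FLs
per TU, distinct TUs per FL, and splice variants per TU. Each is a map
m → frequency with totals M (objects), Σ m·f (events), and J = max m. The
FLs-per-TU and TUs-per-FL relations count the same incidences from the two
sides, so their event totals coincide — an identity the tests assert.

Model components:

- Exponential decay `a·e^(−bm)` with a, b > 0.
- Generalized discrete Pareto (GDP): `f(m) = C/(m+b)^(k+1)` on a finite
  support m_min..J, with shape k > 0 and shift b > −1; b = 0 is the
  standard discrete Pareto and k+1 the log-log slope. The b > −1 bound is
  the admissibility condition actually required for the pmf to exist on
  the support (the constraint is sometimes printed as b > 1, which would
  exclude the standard-Pareto case that the analysis itself uses).
  Normalization uses the finite sum by default; an infinite-support mode
  normalizes by the Hurwitz zeta function ζ(k+1, 1+b).
- Two-component mixture `P = s·P₁ + (1−s)·P₂` split at a breakpoint m\*
  (default 10, from the observed onset of the heavy splice-variant tail at
  m > 9): P₁ is fitted on m < m\*, P₂ (always GDP) on m ≥ m\*, and s is
  the observed fraction of objects below the breakpoint. Each component is
  renormalized on its own regime so the mixture pmf sums to 1 over 1..J.
  This is the published two-regime procedure, not a joint EM; joint
  maximum-likelihood estimation of s would be a natural extension. When
  the tail regime has fewer than two support points (e.g. breakpoint = J),
  the tail component is reported as absent (NaN parameters) and s = 1,
  mirroring how such fits are tabulated in practice; an under-supported
  *body* regime is an error instead.

Fitting is unweighted nonlinear least squares on the observed nonzero
frequencies (`scipy.optimize.curve_fit`), emulating the SigmaPlot-style
workflow the original analysis used: parameter standard errors come from
the fit covariance, p-values from two-sided t-tests with n−p degrees of
freedom, and the reported "std error of estimator" is √(SSR/(n−p)). For
the GDP the least-squares model is A·f(m) with f normalized over the fit
range and A the observed object count inside that range, so full-range and
tail-range fits use the same rule. A truncated-multinomial
maximum-likelihood mode (`method="mle"`, L-BFGS-B with finite-difference
observed information for standard errors) is provided because
least-squares on sparse heavy tails leaves k and b poorly identified; the
parameter-recovery simulations use it for the mixture tail.

Degenerate inputs: flat frequencies drive the exponential rate to the b=0
boundary and raise a fit error rather than returning a boundary estimate;
a fit range with fewer distinct support points than parameters is
rejected. Descriptive statistics (events/objects ratio, singleton count n₁
and percentage p₁, skewness) use the adjusted Fisher–Pearson sample
skewness (G1) computed on the object-level expanded values, with the
convention that constant samples have skewness 0.

## Contingency matrix and splice-function networks

The contingency matrix counts annotated proteins per (TU, FL) cell. The
SFN is its polyform projection: for every polyform TU, each unordered pair
of its distinct FLs gains +1 edge weight — one per TU, regardless of how
many isoform pairs realize the co-occurrence, because the matrix element
of interest is the number of shared TUs. Isolated (degree-0) FL nodes are
added only on request, since whether the published node counts include
them is ambiguous; hub degree likewise counts distinct neighbors, with
weighted degree exported separately. Network heterogeneity is the
coefficient of variation of the degree sequence (population variance), the
definition Cytoscape reports, consistent with the magnitude of published
values (≈0.35–1.9).

Graphs export to Cytoscape's SIF (`node1 TAB sw TAB node2`, isolated nodes
as bare lines) and GraphML. SIF itself carries no attributes, so edge
weights are written to a Cytoscape edge-attribute sidecar (`<path>.eda`);
GraphML stores `weight` as a numeric edge attribute. Round-trips preserve
the node set and weighted edge set in both formats.

## Keyword over-representation

Enrichment counts at the TU level: a keyword counts once per TU when any
of the TU's proteins carries it. The raw p-value is the upper tail
P(X ≥ x) of Hypergeometric(N, K, n) via `scipy.stats.hypergeom.sf`; the
correction is GeneMerge's modified Bonferroni — multiply by the number of
distinct keywords represented in the study set, cap at 1 — and the default
reporting threshold on the corrected p-value is 10⁻⁴. The background
population is all annotated TUs by default, switchable to all TUs. Only
over-representation is tested.

## Synthetic data generator

`generate_organism(SimConfig)` emulates the statistical structure of the
real annotation sources; its defaults are the human-study conditions:

| parameter | default | meaning |
|---|---|---|
| n_tus | 20 000 | TU count, near the ~18–21k classified mammalian TUs |
| unannotated_fraction | 0.30 | ~70 % of proteins receive keywords |
| polyform_target | 0.127 | polyform share of annotated TUs (2315/18259) |
| sv_model.s | 0.985 | body weight; 280/18260 TUs exceed 9 variants |
| sv_model.exp_b | 0.49 | exponential rate of the splice-variant body |
| sv_model.gdp_k, gdp_b | 4.16, 8.75 | GDP tail of splice-variant counts |
| sv_model.breakpoint, J | 10, 73 | tail onset and maximum variant count |
| fl_per_tu_exp_b | 2.2 | decay of extra FLs in polyform TUs (~88 % singletons) |
| max_fls_per_tu | 9 | observed maximum distinct FLs in one TU |
| keyword_vocab_size | 800 | keyword universe |
| mean_keywords_per_fl | 2.5 | FL prototype size, 1 + Poisson(1.5) |
| fl_pool_size | 5 000 | FL prototype pool (~5k distinct FLs per organism) |
| switch_fraction | 0.008 | share of annotated TUs with a disjoint pair |

Mechanics: splice-variant counts are drawn i.i.d. from the configured
mixture for *all* TUs, so the empirical SVs-per-TU marginal matches the
model pmf (Kolmogorov–Smirnov distance < 0.02 at 2·10⁴ TUs). Exact-count
subsets (rounded) are then designated unannotated and — among annotated
TUs with ≥ 2 variants — polyform, so realized fractions sit within
sampling error of the targets. FL identities come from a pool of distinct
random keyword subsets with Zipf popularity weights ∝ 1/rank; sampling FLs
by those weights makes the TUs-per-FL relation heavy-tailed with slope
≈ 2. A polyform TU draws its FLs around an *anchor keyword* — the widest-
membership keyword of its first-drawn FL — so isoform keyword sets
overlap, as they do in real annotations; disjoint pairs occur only in the
TUs designated as functional switches, whose first two isoforms receive
fresh keyword sets from disjoint halves of the vocabulary. Each of a TU's
FLs is realized by at least one isoform; remaining isoforms reuse the TU's
FLs at random. All randomness flows through one seeded generator, so a
fixed seed yields a byte-identical annotation table.

What the generator does not emulate: keyword semantics (keywords are
arbitrary tokens, so enrichment results on synthetic data reflect set
structure only); correlations between a TU's variant count and the
popularity of its FLs; cross-organism homology (two synthetic organisms
share FLs only through chance pool overlap); and any sequence-level
signal. Tests passing on synthetic data therefore validate the
bookkeeping, the estimators and the network construction — not biological
conclusions about real proteomes.

`fixture_from_counts` builds exact degenerate objects from printed
marginal totals: a histogram with prescribed (events, objects, singletons,
J) — singletons at m=1, one object pinned at m=J, the remainder spread
over 2..J as evenly as feasible, which leaves the ratio and singleton
statistics exact while the spread is arbitrary — or a minimal dataset with
prescribed monoform/polyform/unannotated/switch counts. Both assert their
marginals post hoc.

## Problem sizes and tolerances

The test suite and the acceptance script run the Monte-Carlo checks at the
sizes the analyses themselves use: 2·10⁴ draws for the exponential and
mixture recoveries, 5·10⁴ for the standard Pareto, 10³ random parameter
draws for GDP normalization (|Σf−1| < 10⁻¹², Hurwitz-zeta limit vs closed
ζ(2), ζ(3), ζ(4) values within 10⁻⁸), and exhaustive hypergeometric
verification for all populations N ≤ 20. Recovery tolerances are 3
standard errors (exponential rate), 10 % (Pareto shape at n = 5·10⁴), 0.05
(mixture weight) and 15 % (mixture tail shape by maximum likelihood). The
default seed for stochastic procedures is 2010.

## Known limitations

- FL ids are not comparable to externally issued ids (different sort key).
- The mixture's s is a plug-in regime fraction, not a likelihood estimate;
  no confidence interval is attached to it.
- Least-squares GDP fits on sparse tails are ill-conditioned in (k, b);
  use the MLE mode there.
- The switch-fraction denominator and the isolated-node/weighted-degree
  network conventions are configurable because the published conventions
  are ambiguous; defaults are annotated TUs, no isolated nodes, unweighted
  degree.
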