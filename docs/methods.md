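# Methods

## The urn formulation

A vertex-labeled multigraph with n vertices and m edges is identified with
its adjacency count matrix A (undirected: symmetric, diagonal = twice the
self-loop multiplicity, so row sums are degrees). The number of distinct
ways to wire an out-stub of i to an in-stub of j is Ξ_ij = k_out_i·k_in_j.
Treating each stub pairing as a ball of colour (i,j) maps edge generation
to sampling m balls without replacement from an urn of M = ΣΞ_ij = m²
balls.

* **HypE** (unbiased urn): A follows the multivariate hypergeometric
  distribution. The edge count is fixed exactly; degrees are preserved in
  expectation with per-vertex variance k(m−k)/(m+1).
* **gHypEG** (urn biased by propensities Ω ≥ 0, defined up to scale): A
  follows the multivariate Wallenius non-central hypergeometric law

      Pr(A) = [Π C(c_k, a_k)] · ∫₀¹ Π (1 − z^{Ω_k/S})^{a_k} dz,
      S = Σ_k Ω_k (c_k − a_k),

  where k ranges over urn colours with ball counts c_k.

Undirected models are not the directed model with directions dropped: the
symmetry of stub wiring gives 2Ξ_ij balls per unordered pair i<j and Ξ_ii
per diagonal colour, for M = (2m)² in total. All undirected code paths use
this colour set (upper triangle plus diagonal); a diagonal "draw" is one
self-loop, i.e. A_ll/2 balls. The undirected marginals and expectations
mirror the directed ones on these urn counts; the test suite validates
this interpretation against exhaustive enumeration of small supports
rather than against any external reference.

All probability mass is computed in log space with log-gamma (urn totals
of order m² overflow naive binomials quickly) and exponentiated only at
the API edge.

## Wallenius numerics

On (0,1) the integrand Π(1−z^{e_k})^{a_k} is monotone and, for large
urns, vanishingly small everywhere except near 0 — hopeless for direct
quadrature in double precision. We substitute z = e^{−v}, giving

    I = ∫₀^∞ exp(g(v)) dv,   g(v) = −v + Σ a_k log(1 − e^{−e_k v}),

whose integrand is bell-shaped with a unique interior peak: g′(v) =
−1 + Σ a_k e_k/(e^{e_k v}−1) decreases monotonically from +∞ to −1. The
peak v\* is bracketed by doubling/halving and located with Brent's method;
the integral is computed as e^{g(v\*)}·∫exp(g(v)−g(v\*)) split at v\*
(adaptive quadrature, relative tolerance 1e−12, the two pieces on (0, v\*]
and [v\*, ∞)). `log(1−e^{−x})` is evaluated via `expm1` throughout.
Degenerate cases: m = 0 returns the certain empty draw; S = 0 with a valid
outcome means no positively-weighted ball remains, so the outcome was
forced and the integral is 1; a colour with Ω = 0 and a positive draw has
probability 0.

Quadrature accuracy is verified against an exact ordered-path dynamic
program (module `oracle`) to 1e−8 on all tested urns, and the uniform-Ω
reduction to the hypergeometric law holds to 1e−10.

**Marginals.** The joint law does not restate its normalizer for a single
colour; we collapse the other colours into one complement colour with the
count-weighted mean propensity Ω̄ = Σ_{l≠k} c_l Ω_l / (M − c_k) and use the
two-colour Wallenius form, whose normalizer is S = Ω_k(c_k − a) +
Ω̄((M−c_k)−(m−a)). This is the standard univariate non-central form; it
reduces exactly to the hypergeometric marginal when Ω is constant and is
checked numerically for normalization (1e−8).

**Expectations.** E[A] solves c_k(1 − t^{Ω_k}) = E_k with a single scalar
t ∈ (0,1) fixed by Σ E_k = m. The left side is monotone in t, so t is
found by bracketed root-finding (Brent, tolerance at machine precision);
Ω is rescaled to max 1 first, which changes t but not E (scale freedom).
When m equals the total ball count over positive-propensity colours the
outcome is forced and E_k = c_k is returned directly; m beyond that is an
error. This system characterizes the expectation of the model as
specified; it coincides with the classical Wallenius mean equations, whose
small deviations from enumerated exact means at tiny n are inherited, not
hidden (the estimation round trip below is exact regardless, because
estimation inverts the same system).

**Propensity estimation.** Centring the ensemble on an observed graph
inverts the expectation system in closed form: Ω_k ∝ −log(1 − a_k/c_k),
normalized to max 1 (any negative constant c in Ω = log(1−a/c_k)/c yields
the same ensemble; the canonical scale aids comparability). Pairs with
a_k = 0 get Ω_k = 0. A saturated dyad (a_k = c_k) has no finite propensity;
this is a hard error by default, or, with `regularize=ε`, the count is
shrunk to (1−ε)c_k (default suggestion 1e−9) — a modelling decision made
explicit rather than silently clamped. The round trip (estimate, then
solve for E[A]) reproduces A to < 1e−6 on random non-saturated graphs, and
exactly in infinite precision (t = e^c solves the constraint by
construction).

## Samplers

* **HypE**: numpy's exact multivariate hypergeometric generator (its
  "marginals" method is the sequential conditional univariate scheme,
  implemented in C). A pure-Python sequential sampler with a configurable
  colour ordering exists alongside it; a property test confirms the
  sampled law is invariant to the ordering. Colour order is fixed
  (row-major) for reproducibility.
* **gHypEG**: exact ball-by-ball biased sampling — at each of m steps a
  colour is drawn with probability ∝ Ω_k × remaining_k — vectorized across
  samples (O(m · n²) per sample). Exactness at desk scale was preferred
  over approximate conditional decompositions; the empirical law matches
  the enumerated PMF by chi-square goodness-of-fit.
* **Chung–Lu** (multigraph form): independent Poisson entries with rates
  k_out_i·k_in_j/m; undirected, k_i k_j/2m per unordered pair and k_i²/4m
  per loop, so the total rate is m and E[k_i] = k_i.
* **Stub matching (CM)**: a uniformly random bijection of out-stubs onto
  in-stubs (directed) or a uniformly random perfect matching of the 2m
  stubs (undirected). Degrees are preserved exactly in every sample. This
  is the classical realization process; it is *not* uniform over
  vertex-labeled multigraphs (a known property of stub matching) and no
  MCMC edge-swap chain is provided — the realization process itself is the
  object of comparison.

Every sampling entry point takes one explicit seed; there is no global RNG
state.

## Ensemble statistics and the comparison experiment

Per realization we record the edge count, the mean squared error of the
degree sequence against the reference (directed: averaged over the
concatenated out+in sequences), degree centralization, and degree
assortativity.

* *Centralization* has no canonical multigraph definition; we use the
  Freeman form Σ(k_max − k_i)/((n−1)(n−2)) (directed: total degrees),
  applied identically to every model — only cross-model comparability
  matters here. Undefined for n < 3 (NaN).
* *Assortativity* is the Pearson correlation of endpoint degrees over the
  multi-edge list, each edge counted with its multiplicity (undirected:
  both orientations; directed: source out-degree vs target in-degree).
  NaN when an endpoint degree sequence is constant; NaN values are dropped
  from KS contrasts and their count reported.

The comparison experiment samples CM, HypE and Chung–Lu ensembles induced
by one reference graph and applies three contrasts: a one-sided Welch
t-test on degree-MSE (HypE < CL), a one-sided bootstrap-t test on the
variance of centralization (HypE < CL; studentized bootstrap, 2,000
resamples, seeded), and two-sided Kolmogorov–Smirnov tests on
assortativity for all model pairs. The standard tests delegate to scipy;
the bootstrap is implemented here. The default scale — 2,000 realisations
per model on a ~50-vertex reference — is where the qualitative ordering
(CM MSE = 0 < HypE < CL, with the Welch contrast significant at 0.01 and
no detectable assortativity difference between HypE and CM at 0.1)
resolves reliably; larger ensembles and references are plain parameters.

## Synthetic fixtures

The generator emulates the shape of empirical collaboration networks — a
few hundred vertices, heavy-tailed degrees, ≈ 5–10 mean degree — without
reproducing any particular data set. Degrees are drawn i.i.d. from a
truncated discrete power law P(k) ∝ k^(−α), k ∈ [k_min, k_min+10n]
(defaults α = 2.2, k_min = 1); parity is repaired by incrementing
uniformly chosen vertices; the graph is realised by one uniform stub
matching, so the drawn sequence is exact. With an `m_target`, sequences
are redrawn (≤ 200 times) until the implied edge count is within 5% of the
target, keeping the closest draw otherwise. At n = 285, α = 2.0,
k_min = 2 this lands near 1,366 edges — the scale of the collaboration
network used as the reference experiment in the literature. The fixtures
share none of a real network's clustering, community structure or degree
correlations; tests passing on them demonstrate the correctness of the
models' distributions and samplers, not any claim about real data.

## Numerical and design notes

* Ξ is stored dense (int64 with an explicit overflow guard on M); at the
  package's intended scales (n up to a few thousand) this is simpler and
  faster than an implicit rank-1 representation.
* `degree_pmf` / `degree_variance` implement the directed out-degree law
  (m·k_out_i favourable balls of M); undirected per-vertex degree laws mix
  single- and double-contribution balls and are not a plain univariate
  hypergeometric, so they are not exposed.
* Internal tolerances are fixed (quadrature 1e−12 relative, root-finding
  at machine epsilon) rather than user-tunable: they are already at the
  precision floor, and the CLI stays simpler.
* Edge-list readers accept either 0-based integer ids or string labels
  (first-appearance order); writers embed `# n=` and `# labels=` comments
  so empty graphs and isolated labelled vertices round-trip.
* Known limitations: no simple-graph (binary) variants, no loopless mode,
  no structured propensity parametrizations (block models, kernels), no
  MCMC samplers — all deliberate non-goals.
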