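# Methods

## The ESABO statistic

ESABO (Entropy Shifts of Abundance Vectors under Boolean Operations) scores
the association of a pair of taxa from binarized presence/absence data.
Let `b_i`, `b_j` be the two abundance vectors (columns of the samples ×
taxa 0/1 matrix).  The observed statistic is the binary entropy

    H(p) = −p ln p − (1−p) ln(1−p),   p = ones-fraction of b_i OP b_j,

where OP is a Boolean operation, AND by default.  The null ensemble
recomputes H with `b_j` replaced by uniform random permutations of itself;
`b_i` stays fixed, so both marginal presence frequencies are preserved and
only the sample-wise pairing is destroyed.  The score is

    z = (H_observed − mean_null) / sd_null.

Taxa that tend to co-occur put more ones into the AND vector than random
pairing would, shifting its entropy away from the null and producing z > 0;
mutually exclusive taxa produce z < 0.  The magnitude is directly
interpretable as "standard deviations away from random pairing".

Closed forms.  Everything a pair contributes is captured by the four joint
counts (α, β, γ, δ) = #(0,0), #(0,1), #(1,0), #(1,1).  A Boolean operation
only relabels these cells (AND sends the γ cell to the (0,0) cell, OR sends
β to (1,1), …), so post-operation counts, entropies, the co-occurrence
z-score and the binary Jaccard indices are all exact functions of
(α, β, γ, δ); `esabo.core` exposes them.  For AND the permutation null
itself is closed-form: under a random permutation of `b_j` the overlap δ
follows a hypergeometric law, so the null mean and standard deviation of
the entropy are finite sums over its support (`esabo_score_exact`).  This
exact score is the oracle the Monte-Carlo estimator is tested against; the
library default remains the Monte-Carlo permutation score because it
generalizes to every supported operation.

Conventions worth stating explicitly:

- Entropies are in nats with 0·ln 0 = 0; z-scores are invariant under a
  change of logarithm base (the scale cancels), which is asserted in tests.
- The null standard deviation uses the population convention (ddof = 0).
- `cooccurrence_zscore` divides the deviation of δ from its binomial
  expectation by the *variance* (γ+δ)(β+δ)(α+γ)/n², reproducing the
  convention of the worked co-abundance example it mirrors;
  `cooccurrence_zscore_std` provides the standard-deviation-normalized
  variant for conventional use.
- The permutation null shuffles the second vector only, so the ordered
  score is not exactly symmetric; all-pairs scoring computes both orders
  and reports their mean, and logs the largest asymmetry seen.
- A constant column (taxon present in every sample or in none) has a
  degenerate null; its z is flagged undefined (NaN), never silently 0.
- Ten informative Boolean operations are supported (AND, OR, XOR, NAND,
  NOR, EQL, GT, GE, LT, LE); the six remaining two-argument functions are
  constants, projections or their complements and carry no pairwise
  information.

## The calibration simulator

Real interaction ground truth is unavailable, so the statistic is
calibrated on a minimal community model that produces presence/absence
patterns directly.  A community is a connected undirected graph on N
species with M+ synergistic (+1) and M− competitive (−1) edges, drawn
uniformly among connected configurations by rejection sampling, signs
assigned by a uniform random partition of the accepted edge set.  States
s ∈ {0,1}^N evolve synchronously by a signed threshold rule: species i
becomes present when its summed signed input is positive, absent when
negative, and keeps its state on a zero input.  Every trajectory ends in a
fixed point or cycle; these attractors play the role of steady-state
community compositions, and the data matrix is the set of attractors
reached from random initial compositions.

Choices made where the design was open:

- Initial compositions are i.i.d. Bernoulli(1/2) per species — the uniform
  distribution on the state space, the natural reading of "random binary
  compositions".
- Cycle attractors (rare; fixed points dominate at these sizes) are
  recorded by their lexicographically smallest state so that deduplication
  is deterministic.
- `distinct` sampling keeps one row per distinct attractor (the default:
  it samples the steady-state repertoire homogeneously);
  `basin_weighted` keeps one row per initial condition.  Basin weighting
  demonstrably lowers edge detectability and is included for exactly that
  comparison.
- `run_to_attractor` defaults to max_steps = 2^N + 1 (a guaranteed revisit)
  for N ≤ 20 and demands an explicit cap above that.
- Measurement error is modelled as substitution noise: a fraction p of
  entries is replaced by a fair coin flip, so the expected fraction of
  entries actually changed is p/2.

Ensemble protocol: benchmark ensembles regenerate any network whose
sampled repertoire does not exceed 100 distinct attractors, and sweep
defaults (20 networks of 15 nodes, 200 permutations per z-score, noise
sweeps at M+ = M− = 10, outlier ensembles of 40 networks at M+ = M− = 15
with 500 initial conditions each) follow the calibration study design this
package reproduces.

## What the synthetic data does and does not emulate

The generator reproduces the *logical* structure of co-occurrence under
synergy and competition, including network-mediated indirect effects.  It
does not emulate read-count noise, compositionality, the abundance
hierarchy (except optionally, via the heavy-tailed pseudo-count mapping in
`esabo.io.generate_fixture`, whose per-taxon magnitudes are log-uniform on
[1, 1000]), phylogenetic correlation, or sample covariates.  Passing tests
therefore demonstrate that the statistic recovers interaction signs from
steady-state presence/absence patterns of the model — not that it is
robust to every artefact of real amplicon data.

## Known limitations

- Reachability bias.  Random initial compositions do not sample attractors
  uniformly: attractors with larger basins and, empirically, higher
  presence density are overrepresented.  On the built-in 15-species
  demonstration network the exhaustive attractor set (2^15 initial states,
  228 attractors) yields the correct sign for all 20 edges, while
  1000-sample tables systematically flip two synergistic edges to strongly
  negative scores.  The same mechanism biases the sampled absent-pair mean
  z slightly negative (≈ −0.3) and inflates the fraction of synergistic
  edges scoring z ≤ −1 in dense ensembles (≈ 20–27% at N = 15,
  M± = 15 under this protocol).  When the state space is small enough,
  prefer `enumerate_attractors` over sampled tables.
- Skewed null at extreme densities.  When a taxon is present in well over
  half the samples the discrete entropy null becomes strongly skewed, so
  tail probabilities are asymmetric; thresholding |z| treats the two tails
  as exchangeable, which they are not in that regime.
- No multiple-testing control.  Edges are thresholded on z alone
  (defaults +1.0 / −1.0, independently adjustable, matching the analysis
  this package reproduces); with T taxa there are T(T−1)/2 hypotheses, and
  users who need familywise control should correct the thresholds
  themselves.
- The as-printed Jaccard prediction-quality rule (+1 for J > 0.6, −1 for
  0.4 < J ≤ 0.6, −1 for J < −0.4) contains a vacuous clause for a
  non-negative index; it is implemented as stated for comparability, with
  this caveat.
- Ubiquitous taxa are unscorable after binarization (degenerate null) and
  are reported as such rather than dropped.

## Problem sizes

Default test and benchmark sizes (15-node networks, 1000 initial
conditions, 200–1000 permutations, 20–40 network ensembles) match the
calibration study design; all are parameters, and larger runs only
tighten the Monte-Carlo error.
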