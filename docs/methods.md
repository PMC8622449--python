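# Methods

## Model and scope

`mixmerge` operates downstream of mixture estimation. Its core consumes
only an N×K posterior matrix γ with row sums 1; the Gaussian adapter
(`posteriors_from_mixture`) is a convenience for producing γ from
parameters and data, not core logic, and non-Gaussian families would work
identically through a user-supplied γ. Merged components are represented
purely by summed posterior columns; we never re-fit a merged pair as a
single new component — keeping the merged cluster's (possibly complex,
multi-modal) shape is the point of merging rather than re-estimating.

All logarithms are natural. The entropy kernel Ψ(x) = −x ln x is defined
exactly at the endpoints (Ψ(0) = Ψ(1) = 0) and no epsilon-clipping is
applied to interior posterior values: clipping would bias mixture
complexity, whose terms are differences of Ψ sums.

## Criteria and their numerics

All six criteria are computed vectorized over rows; each is checked in the
test suite against an independent scalar-loop implementation at 1e-12.

Numerical choices that matter:

- **Argmax ties** (in `demp`'s global hard assignment and `demp2`'s
  pair-restricted one) break to the smallest component index,
  deterministically.
- **Degenerate pairs** — a member with zero effective mass — evaluate, via
  the dispatch layer, to the criterion's *best* value, so empty components
  are absorbed first: an empty component is vacuously "entirely
  overlapped" with anything. The low-level functions raise instead, so the
  choice is visible.
- **Zero pair-mass rows** inside the conditional construction of `mc`
  (and of the within-cluster summaries) get conditional value 1/2 (or
  1/|I\_l|) and zero point weight; the value never contributes, the
  convention only avoids 0/0.
- Posterior computation runs in log-density space with per-row max
  subtraction; a row where every component underflows raises an error
  naming the row.

`nmc` equals `1 + nent1/pair_entropy` analytically; the identity is
asserted to 1e-10 on random fixtures as a cross-oracle between the
entropy-based and complexity-based implementations.

## Essential-condition certification

`check_conditions` certifies BO/WS/SI numerically rather than symbolically:

- **Extremes.** Closed-form best/worst values per criterion are re-verified
  by brute-force search over a gridded posterior simplex (N = 4, K = 2,
  grid step 0.25), where every extreme is attained exactly.
- **BO fixtures.** Entire overlap means equal component *densities*; under
  weight bias this makes the posterior columns proportional (ratio
  ρ\_i : ρ\_j), not identical. Fixtures therefore use equal-density pairs at
  weight ratios 1:1, 1:3 and 1:9, plus three-component fixtures in which a
  dominant or spatially distinct third component exists. This is precisely
  what separates `nent1` (fails BO under bias) from `nmc`, and `demp`
  (argmax captured by the third component) from `demp2`. The report carries
  both the strict BO verdict and a pair-only variant; they differ only for
  `demp`.
- **WS fixtures.** Two 1-D unit-variance components with mean gaps up to 40
  standard deviations (where posterior cross-products underflow to zero),
  under balanced (1:1) and biased (1:9) weights, with deterministic
  per-component quantile grids as data. `mc`'s failure is weight-driven:
  under bias it converges to Ψ(0.1)+Ψ(0.9) ≈ 0.325 < ln 2.
- **SI fixtures.** Scale invariance concerns data drawn from the rescaled
  model: with a frozen data set every posterior-ratio criterion would be
  trivially invariant. The checker therefore replicates a fixed
  per-component quantile grid with integer multiplicities proportional to
  the rescaled weights (a ∈ {0.1, 1, 10} on an isolated, partially
  overlapped pair). Non-`ent` criteria are then exactly invariant, while
  `ent` scales with the pair's point count — a clean discrimination with
  no discretization noise.
- Limits are compared at tolerance 1e-3 (adjustable); the separation and
  isolation settings are asymptotic stand-ins for the defining limits.

## Merging loop and stopping

The loop greedily merges the criterion-minimizing pair, ties broken by
lexicographically smallest column positions. NMC0 is computed once on the
initial matrix — it characterizes the *unmerged* model — and the rule
halts, without merging, when the selected pair's NMC is ≥ NMC0
(non-strict). Consequences we keep as-is: a fully overlapped two-component
model has NMC0 = 0 and pair-NMC 0, so nothing merges; a hard assignment
has NMC0 = 1 and every pair at 1, so nothing merges. A `refresh_nmc0`
switch recomputes the threshold on the current merged matrix before each
comparison, off by default, for experimentation.

Pair scores are cached: after a merge only scores involving the new
cluster are recomputed. `demp` is the exception — its global argmax can
move any pair's score after any merge — so its score table is rebuilt each
step by a single vectorized pass (one argmax + one scatter-add, O(NK)).
Both paths are contractually identical to full recomputation and tested as
such.

## Summarization

For a partition I\_1..I\_L, the upper-level MC uses the L-column merged
matrix with unit weights; NMC(up) divides by Σ Ψ(τ̃\_l). Within cluster l,
the member columns are conditioned on the cluster's posterior mass and fed
to MC with that mass as point weights; NMC(l) divides by the entropy of
the relative member weights. Undefined NMC (L = 1 at the top; singletons
within) is a first-class `None`, rendered as `-` — never 0 or a silent
NaN, since "no structure to normalize" and "fully overlapped" are
different findings. Reports order clusters by descending weight.

## Synthetic data: what it emulates and what it does not

`random_mixture` reproduces the artificial-experiment generator: 50
two-dimensional components, Dirichlet(1) weights, means N(0, 3²I₂) — the
"3² × I₂" scatter is read as variance 9 per axis — and diagonal
covariances with entries U[0.5, 1.5]. Every artifact of a trial is a pure
function of (root seed, trial index) via `SeedSequence([seed, trial,
stream])` substreams.

`two_pair_fixture` is a synthetic stand-in for the two-cluster
demonstration model (whose exact parameters are not published): means
(0, 1.2, 10, 11.2), unit variances, equal weights. The 1.2σ within-pair
gap keeps pair NMC (≈ 0.2) well below NMC0 (≈ 0.6) and the 10σ
between-pair gap pushes cross-pair NMC to ≈ 1, so the NMC-stopped result
is exactly two clusters with exp(MC_up) ≈ 2.

`grouped_mixture` builds labelled data for the purity study: four groups
on a circle of radius 20, each a bundle of three unit-variance components
jittered with scale 1.5 around the group center. Merges inside a group are
overlapped and label-pure; merges across groups are scattered and impure,
which is the regime in which within-cluster MC/NMC should co-vary with
label entropy.

These generators emulate overlap structure, weight bias and separation;
they do not emulate non-Gaussian cluster shapes, outliers, or estimation
error in γ (posteriors come from the true generating model, not a fit).
Passing tests therefore validate the merging and summarization machinery,
not robustness to model misspecification on real data.

## Ranking experiment

The benchmark merges each trial's model under all six criteria down to 5
clusters and scores, at cluster counts {40, 30, 20, 10, 5}: the maximum
posterior-weighted within-cluster spread (D\_intra, squared distances — the
within-cluster scatter convention; the Euclidean variant is exposed and
changes D\_intra values but not D\_inter rankings, because the square root
is monotone) and the minimum pairwise distance between posterior-weighted
centers (D\_inter). Criteria are ranked within each trial (ties averaged)
and ranks averaged over trials.

Problem sizes: the package's acceptance run uses 50 trials and the test
suite 30 trials (the original experiment used 100); at 30–50 trials the
headline cells are stable to a few hundredths–tenths of a rank across
seeds, comfortably inside the ±0.5 comparison band used in the tests.

## Known limitations

- Greedy pairwise merging has no look-ahead; criteria quantify pairwise
  overlap only, and no guarantees exist for moderate (partial) overlap —
  the essential conditions constrain extremes only.
- The stopping rule's non-strict comparison freezes fully degenerate
  models (see above) rather than merging them.
- `ent`'s best value scales with N, so cross-data-set comparisons of raw
  `ent` values are meaningless; use the normalized criteria.
- The Gaussian adapter assumes well-conditioned covariances; it validates
  positive-definiteness but does not regularize.
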