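# Methods

## Problem and model

Given a labelled matrix `X ∈ R^{n×p}` (samples × features) with integer
class labels `y`, the task is to find a small feature subset whose
cross-validated classification accuracy is at least that of the full
matrix. The method is a hybrid: a deterministic filter proposes a
candidate subset, a stochastic wrapper searches inside it, and a
restart controller decides when the proposal should be refreshed.

### Relevance: tie-corrected Kendall correlation

Feature–label relevance is the absolute tie-corrected Kendall
coefficient `|C − D| / √((N₃ − N₁)(N₃ − N₂))`, with `C`/`D` the
concordant/discordant pair counts, `N₃ = N(N−1)/2`, and `N₁`, `N₂` the
per-vector tie corrections `Σ uᵢ(uᵢ−1)/2` over groups of equal values.
Class labels are heavily tied by construction, so the tie corrections
are essential; the absolute value is used because a feature that
separates classes in reverse order is exactly as useful to a
classifier. Pair counting is exact integer arithmetic in O(N²) — N is
a sample count (tens to hundreds), and the quadratic form is directly
checkable against pair enumeration, which the test suite does to
1e−12. A constant vector makes the denominator vanish; such features
carry no rank information and score 0 (with a logged warning) rather
than raising, which keeps the greedy filter total. Ties are exact
numeric equality; real-valued inputs are accepted (the statistic is
well defined and the worked examples confirm that reading).

### Redundancy: maximum normalized Euclidean distance

Redundancy is measured metrically: the candidate's Euclidean distance
to the already-selected set, maximized (a far candidate is least
redundant). Distances are computed on per-feature min-max normalized
columns, `(v − min)/(max − min)`, so that the distance term (bounded by
√n) and the Kendall term (bounded by 1) live on commensurate scales and
the mixing weights act as intended; constant columns normalize to zero
and contribute nothing. Normalization is idempotent and
shape-preserving. Pairwise distances are cached per filter pass.

### The greedy MKMD ranking

Step one picks the feature with maximal Kendall relevance. Each later
step picks the not-yet-selected feature maximizing
`a·MK(F_j, L) + b·max_{s∈S} D(F_j, F_s)`. Scoring the set-level
maximum distance per candidate inside the argmax is algebraically the
same as the set-to-set formulation, which embeds the same argmax. All
tie-breaks are toward the lowest feature index, making the ranking a
pure function of (data, weights, K).

The weights follow `a = 1 − (t/T)², b = (t/T)²` where `t` is the outer
iteration at which the filter is invoked and `T` the total budget
(default 100). Treating `t` as the outer iteration — frozen within one
filter pass — is what makes successive filter invocations produce
*different* candidate subsets from the same deterministic ranking rule;
the alternative (advancing the weights per selected feature within one
pass) would make every pass identical and the restarts pointless.

Only the top `K = min(100, n_features)` ranked features are handed to
the wrapper (matching the candidate-size convention of comparable
filter–wrapper pipelines); ranking beyond K is wasted work, and a
`K = n_features` call (CLI `--rank-all`) restores the full ordering.

### The binary grey-wolf wrapper

Subsets of the candidate list are encoded as bit vectors. Each of the
three elitist leaders (best-so-far alpha/beta/delta) casts a per-bit
vote via the stochastic encircling step: `A = 2a̅r₁ − a̅`, `C = 2r₂`
with `a̅` decreasing linearly 2 → 0 over the budget, leader distance
`D = |C·x_lead − x|`, `cstep = σ(10(A·D − 0.5))`, a Bernoulli step
`bstep`, and the vote `1 iff x_lead + bstep ≥ 1`. The improved update
fuses the three votes through the trigonometric gate
`1 iff |x₁+x₂+x₃| > 3 sin(x)`, `x ~ U(0, π/2)` drawn per dimension,
then mixes with the previous position: `v = t₁·gate + t₂·x_prev`,
where `t₁ = t·sin(x*)`, `t₂ = 1 − 4t·sin(x*)` share one draw `x*` per
wolf per iteration and `t = (T − l)/T`. The value `v` is re-binarized
at a deterministic threshold of 0.5 (a stochastic-sigmoid mode is a
config option).

Numerical conventions worth stating: `t₂` can be negative early in the
run; it is deliberately not clamped — the thresholding absorbs it, and
the effect is aggressive early exploration. At the final iteration
`t = 0` forces `t₁ = 0, t₂ = 1`, freezing positions. Wolves whose
subset empties are repaired by switching one uniformly chosen bit on.
Leaders are best-so-far (elitist) rather than per-generation, which
guarantees a monotone best-fitness trace; the two classic binary
update rules (per-dimension leader roulette; sigmoid transfer on the
leader mean) are available behind the same interface and obey the same
invariants.

### Wrapper fitness

Fitness of a subset is the maximum, over an SVM parameter grid, of
stratified 10-fold cross-validated accuracy on the subset's columns,
in percent. Min-max scaling is fit inside each training fold and
applied to its test fold, the leakage-free choice. Folds are fixed by
a fold seed, so fitness is a pure function of the subset — required
for memoization (subsets are cached by index set, and the cache
survives restarts) and for monotone traces. The default grid is the
standard coarse power-of-two grid `C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}`,
`γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}`; a fast 4×4 profile
(`C ∈ {0.1, 1, 10, 100}`, `γ ∈ {0.001, 0.01, 0.1, 1}`) serves
desk-scale runs. The grid winner maximizes the same CV accuracy that
is reported — no nested CV — so reported accuracies carry the usual
optimistic selection bias; this matches the protocol the method is
defined with and is flagged here rather than silently "fixed".
Ordering of fitness values is accuracy first, then shorter subset; a
length-only improvement is still an improvement. If the smallest class
has fewer members than the fold count, the fold count is reduced to it
(logged).

### Restart controller

The schedule `y(t) = ⌈|2e^(2−t/60) cos(t/6)|⌉ + ⌈5·rand⌉` is evaluated
on integer t ∈ [0, 100]. Its deterministic envelope has exactly six
local maxima (t = 0 and near each half-period of the cosine, pulled
slightly left by the decay; integer peak times 0, 18, 37, 56, 75, 94
with deterministic heights 15, 11, 8, 6, 5, 4 — sum 49, so with lifts
of at most 5 each the six thresholds always sum below 100). The
random lift is drawn once per peak at extraction, giving each phase a
fixed threshold — a per-iteration redraw would make the "just greater
than" crossing ill-defined; a redraw mode exists for diagnostics. The
patience counter `savemax` starts at a sentinel of 100 (forcing a
filter pass at iteration 0), resets to 1 on improvement, increments on
stagnation, and triggers a restart when it strictly exceeds the
current threshold; each trigger consumes its peak, so a 100-iteration
run re-filters at most 7 times, and once the peaks are exhausted the
run continues without restarts. Restarts never discard the global
best, which is archived in original feature indices.

## Synthetic data

The generator emulates the structure the method targets, at desk
scale: `n_informative` columns with class-conditional means shifted by
`δ` per class (unit variance), `n_redundant` near-copies of
informative columns (parent assigned round-robin, Gaussian jitter
`σ_r`), and `n_noise` label-independent standard normal columns, with
balanced shuffled labels and the ground-truth partition returned
alongside. Defaults: 100 samples, 2 classes, 5 informative, 10
redundant, 35 noise, `δ = 1.5`, `σ_r = 0.1` — a separation at which
single features are informative but not individually decisive, and
copies are metrically near their parents without being exact
duplicates. The generator is deliberately idealized: it has none of a
real expression matrix's batch effects, heteroscedasticity, or
correlated noise, so passing recovery tests demonstrate the machinery
works under its own assumptions, not performance on real microarrays.

**Recovery is counted per signal, not per column.** A redundant group
(an informative feature plus its near-copies) carries one signal, and
a redundancy-minimizing selector is *supposed* to keep exactly one
member of each group — which member is immaterial. A planted signal
counts as recovered when the best subset contains the informative
column or any of its copies; counting only parent columns would fail a
selector precisely for doing its job.

## Problem sizes and defaults

Paper-scale defaults are `T = 100` iterations, 30 wolves, `K = 100`
candidates, RBF kernel with the full grid. The stochastic test suites
run the same pipeline at desk scale — `T = 20`, 8 wolves, `K = 20`,
fast grid, linear kernel, 20 master-seeded repeats on the default
synthetic conditions — sizes chosen so the whole suite runs comfortably
on a single CPU while still exercising every phase transition
(multiple restarts occur within 20 iterations because the later,
smaller thresholds are reached quickly). With `T < 100` the schedule
horizon is truncated to `T`, so fewer peaks exist; the ≤ 7 restart
bound is a property of the full 100-iteration horizon.

## Known limitations

- Wrapper accuracy is optimistically biased (grid selection on the
  reported CV); rank comparisons between subsets are unaffected, which
  is all the search needs.
- The Kendall statistic is computed per feature per filter pass in
  O(p·n²); for very large p a cached or O(n log n) variant would pay,
  but verifiability was preferred at these sizes.
- The filter's candidate size K caps how many features the final
  subset can contain.
- Multi-class problems rely on the SVM's built-in one-vs-one handling;
  no bespoke multi-class fitness is defined.
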