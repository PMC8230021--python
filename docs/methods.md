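# Methods

## The selection criterion

Given a decision table with numeric condition attributes normalized into
[0, 1] and a categorical decision, a neighborhood decision system fixes a
Minkowski order p (default 2) and radius δ (default 0.3).  On attribute
subset B, each sample's neighborhood granule is the inclusive δ-ball
n_B^δ(x) = {y : d_B(x,y) ≤ δ}; its decision class [x]_D is the set of
same-label samples.  Three quantities combine into the criterion:

* **Approximate precision** P_B(D): |∪_s N_B(Y_s)| / |∪_s N̄_B(Y_s)| over
  decision classes Y_s.  Because every granule contains its own sample,
  the upper union is always the full universe, so P_B(D) reduces to the
  fraction of samples whose granule lies entirely inside their own class.
  P is monotone non-decreasing under subset growth.
* **Credibility** nα = |granule ∩ class| / |granule ∪ class| and
  **coverage** nκ = |granule ∩ class| / |class|, both in (0, 1] since the
  sample itself is in every one of these sets.
* **Neighborhood joint entropy**
  Hδ(D,B) = −(P_B(D)/|U|) Σ log(nα·nκ), equivalently
  −(P/|U|) Σ log(|granule∩class|² / (|granule∪class|·|class|)).

Hδ(D,B) is 0 both when P = 0 (no granule is class-pure) and when every
granule coincides with its class (nα = nκ = 1); it is maximized by fine,
class-pure granulation — singleton granules give the closed form
(2/|U|) Σ log|[x]_D|.  It is **non-monotonic** under subset growth, which
is why the greedy search stops on "no strict improvement" rather than on
reaching the full-set value.

Marginal (Hδ(B)) and conditional (Hδ(D|B)) companions satisfy
Hδ(D|B) = Hδ(D,B) − Hδ(B) exactly; the test suite asserts this and the
credibility/coverage identity to 1e−12 on randomized systems.

## Greedy search

From B = ∅, every candidate b ∉ B is scored by Hδ(D, B∪{b}); the argmax
joins B if its score strictly exceeds the current Hδ(D,B), else the
search stops.  Published pseudocode for this family of algorithms is
ambiguous about the loop guard; the implementation follows the worked
example's behavior (stop at the first step where the best candidate's
significance is ≤ 0).  Numerical choices:

* Entropy equality uses an absolute tolerance of 1e−12 — the stop rule
  compares two float pipelines for equality.
* Ties among equal-best candidates break toward the lowest attribute
  index, making runs deterministic.
* P_B(D) = 0 short-circuits every entropy to exactly 0 (each log term is
  finite anyway — intersections are never empty — but the short-circuit
  documents intent and skips work).
* The δ-boundary is inclusive with no epsilon slack: a pair at distance
  exactly δ are neighbors.  Distances are compared as Σ|Δ|^p ≤ δ^p,
  avoiding the p-th root (monotone, so order-identical).
* A one-class decision is degenerate (every entropy 0): the selector
  returns an empty subset with a warning rather than raising.

The subset verifier reports the two reduct conditions — entropy of B at
least that of the full attribute set, and every member necessary — but
the greedy search does not enforce the first (non-monotonicity means the
greedy optimum may exceed the full set) and implements no repair sweep
for late-redundant members, as the method defines none.

## Evaluation protocol

Min–max normalization statistics are computed once on the full table, and
selection runs on the full normalized table before cross-validation.
This mirrors the selection protocol the method was published with; it is
optimistic relative to nested (per-fold) selection, and results should be
read accordingly.  The radius sweep evaluates δ ∈ {0.05, 0.10, …, 1.0}
(20 points) by default; δ choice from the sweep is left to the user — no
formal criterion is imposed.  Cross-validation is stratified k-fold
(default k = 10, seeded), falling back to plain folds with a warning when
a class has fewer samples than folds.  The built-in classifier is 3-NN
(Euclidean, majority vote, ties broken by the single nearest neighbor);
any fit/predict object with a `name` plugs in via the same contract, and
empty selections are scored at the majority-class baseline so sweep rows
stay well-defined.

## Comparison statistics

Accuracy matrices are ranked per dataset with rank 1 = highest accuracy
and midranks for ties (each column sums to M(M+1)/2).  χF² follows the
standard Friedman formula over average ranks R_i; F_F is the
Iman–Davenport correction, compared against the numeric inverse-CDF F
critical value at (M−1, (M−1)(N−1)) degrees of freedom (arbitrary df, no
embedded F table).  `friedman_chi2` also accepts an average-rank vector
directly so published rank rows — often rounded to two decimals — can be
reproduced exactly as printed.  Nemenyi q_α values are embedded for
α ∈ {0.05, 0.10} and M = 2…20 (two-tailed studentized range at infinite
df divided by √2, Demšar 2006); the test suite cross-checks them against
`scipy.stats.studentized_range`.  Other post-hoc procedures (Holm,
Shaffer, …) and exact permutation p-values are out of scope.

## Synthetic data generator

The generator emulates the statistical shape of microarray benchmarks —
a few informative dimensions among many irrelevant ones — at desk scale
so the full pipeline runs in seconds.  Relevant features are
class-conditional Gaussians whose class means are spaced by
`class_separation` × `noise_sd` (defaults 5.0 and 0.05: clearly separable
but overlapping at the tails); redundant features are affine copies of
random relevant features plus 5% jitter; noise features are uniform on
[0, 1] independent of the class.  Labels are balanced up to rounding,
columns are min–max normalized, and the generator is a pure function of
its spec (fixed seed ⇒ byte-identical tables).  Defaults (80 samples, 2
relevant + 20 noise features, 2 classes) keep the planted-recovery tests
in the regime the method targets.

What the generator does **not** emulate: feature-feature correlation
structure beyond explicit redundant copies, heavy-tailed expression
distributions, batch effects, and class imbalance as found in real tumor
panels.  Passing recovery tests therefore show the selector finds planted
class-informative axes under Gaussian class-conditional geometry; they do
not certify performance on real microarray data.

## Problem sizes

Property suites run on randomized systems with ≤ 10 samples and ≤ 4
features (hundreds of instances, brute-force set-enumeration oracles);
recovery checks use 80 × 22 tables over five seeds.  These sizes make the
brute-force oracles exact and the whole suite fast while covering every
code path; the selector itself is O(steps · features · n²) and handles
desk-scale tables (hundreds of samples, ~200 features) in seconds.

## Known limitations

* Continuous condition attributes only; mixed nominal/numeric distances
  are not implemented, and missing values are rejected at ingestion.
* The criterion's non-monotonicity means the greedy subset carries no
  optimality guarantee; the verifier reports, but cannot repair,
  violations of the reduct conditions.
* Whole-table normalization and pre-CV selection leak test information by
  design of the reproduced protocol.
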