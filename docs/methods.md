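# Methods

## Model

A rooted binary species tree carries, per branch *i*, a duration in
generations τᵢ, a haploid effective population size Nᵢ and a per-generation
substitution rate νᵢ.  The coalescent-unit (CU) length is Tᵢ = τᵢ/Nᵢ, the CU
substitution rate μᵢ = νᵢNᵢ, and the substitution-unit (SU) length
tᵢ = τᵢνᵢ = Tᵢμᵢ.  Gene genealogies follow the multispecies coalescent
(MSC): within a branch, j lineages coalesce at rate C(j,2) per CU; surviving
lineages enter the parent branch; above the root coalescence continues
indefinitely.  A gene-tree branch segment spending CU duration d inside
species branch *i* contributes d·μᵢ to its SU length.  Unequal νᵢ make the
species tree (and the gene trees) non-ultrametric.  Per-gene rate
multipliers with mean one leave all the expectations used below intact; they
and per-gene-per-branch multipliers (heterotachy, outside the model) are
available in the simulator as robustness perturbations.

## Quartet expectations (forward model)

For the unbalanced quartet (((A,B),C),D) with internal CU lengths T₁ (above
the AB ancestor, rate μ₁) and T₂ (above the ABC ancestor, rate μ₂), rate μ₃
above the root, the expected matching-minus-non-matching SU differences of
the five gene-quartet branches (internal, cherry pendant, middle pendant,
root-adjacent pendant) have closed forms implemented in
`estimators.expected_gene_quartet_deltas`, e.g.

    ΔI = [3(e^(−T₂) − e^(−3T₂))(1 − e^(−T₁))(μ₂ − μ₃) + 6μ₁(e^(−T₁) − 1 + T₁)]
         / [2(3 − 2e^(−T₁))].

The non-matching bucket pools both discordant topologies.  These forms are
verified two ways: algebraically (ΔI collapses to its single-rate form for
any T₂ when μ₂ = μ₃; the cherry and middle forms reproduce their T₂ → ∞
limits) and by Monte Carlo against the simulator (3 SE at three parameter
points with 2·10⁵ genes each, including all three rates distinct).  Because
coalescent durations are independent of the rates, the μ-coefficients of
each difference are linear functions that paired same-seed simulations can
measure exactly up to shared noise; this was used to validate the
μ₂−μ₃-dependent structure of the cherry difference.

## Estimators (inverse direction)

**Internal branch.**  Under a local clock (the rates around the focal branch
taken equal), the expected non-matching internal length is the focal rate
itself, so μ̂₁ = L̄ᵢ′, and the normalized difference obeys
δ̄ = 3(T₁ + e^(−T₁) − 1)/(3 − 2e^(−T₁)).  Two inversions are provided:

* `solver="exact"` (default): bracketed Brent root finding on [0, 50]
  (tolerance 10⁻¹²; the bracket extends automatically in the unreachable
  regime).  This equals the closed-form Lambert-W inverse while avoiding
  branch selection and complex intermediate values.
* `solver="taylor"`: T̂₁ = δ̄/2 + √(3δ̄(3δ̄+4))/6, from substituting
  e^(T₁) ≈ 1 + T₁.  This substitution doubles the leading T₁²/2 term of the
  numerator, so the Taylor inverse tends to T₁/√2 as T₁ → 0 and sits 20–30 %
  below the exact root throughout δ̄ ∈ (0, 1]; the absolute deviation decays
  like √δ̄.  The discrepancy curve is asserted in the test suite.  The exact
  inverse is the default because the Taylor bias propagates into every
  downstream correction (terminals and root sum use T̂₁).

**Terminal branches.**  The cherry terminal (a leaf child of the focal
node) and the middle terminal (a leaf sibling) are corrected using the
T₂ → ∞ limits of the quartet expectations:

    t̂_A = L̄_A′ + [μ̂₁(e^(−T̂₁) − 1 + T̂₁) + Δ̄_A(1 − (2/3)e^(−T̂₁))] / (1 − (4/5)e^(−T̂₁)) − T̂₁μ̂₁
    t̂_C = L̄_C′ − (1/3)(2 − 1/(2 − e^(−T̂₁))) Δ̄_C

(the grouping of the first formula was re-derived by eliminating μ₂ between
the limit forms of the cherry difference and the non-matching cherry mean).
Because the upper path is finite in real trees, these limits leave a small
positive residual of order e^(−T₂)·μ per terminal (~1–2 % of branch scale in
the 10-taxon test conditions); a sign test across many replicates detects
this residual even though its magnitude is small.  It is asserted to be
< 2.5 % of the mean branch scale at the test conditions.

**Root-incident branches.**  Only the sum of the two branches below the root
is identifiable.  With one root child a leaf, the sum is estimated from the
root-adjacent pendant role of the branch(es) just below the internal root
child, t̂₂+t̂_D = L̄_D′ − (2/3)(2 + 1/(1 − e^(−T̂₁)))Δ̄_D, averaging the two
candidates when both children of the root child are internal; T̂₁ inside the
divergent 1/(1−e^(−T₁)) factor is clamped to ≥ 10⁻⁶ (the paired Δ̄_D vanishes
with T₁, keeping the product stable).  With both root children internal, the
root path behaves exactly like an internal branch with total CU length
S = T₁ + T₂: conditioning on concordance routes shows E[L̄ᵢ′] = μ and
δ̄ = 3(S + e^(−S) − 1)/(3 − 2e^(−S)), so the internal machinery applied to
the root path returns μ̂·Ŝ, the root sum.  By default the sum is split
evenly between the two root edges (`--root-split even|left|right`); the
inferred sum itself is recorded on the result object.

**Balanced-root cherry terminals.**  A cherry hanging directly off a root
child (including the balanced 4-taxon tree) is not covered by the unbalanced
limits.  Its estimator is derived directly: conditioned on discordance, a
cherry pendant of the balanced quartet reaches expected CU depth T₁ + 2/3
above its species split (the 2/3 rather than 1/2 arises because a pendant
ends at the adjacent node of the *unrooted* induced quartet — a final
coalescence of degree 2 is suppressed and the pendant continues down the far
side, doubling the last waiting time).  The matching-bucket depth mixes the
three routes to concordance (own-side coalescence below the root; other side
only; neither, with a concordant first pair above the root).  Given μ̂ and
Ŝ, the observed pendant difference pins down the focal side's share T₁ by a
bracketed solve (the difference is strictly decreasing in T₁;
out-of-range observations clamp to the nearer end), and
t̂ = L̄′ − μ̂(T̂₁ + 2/3).

**Degenerate inputs.**  δ̄ < 0 (and any non-positive estimate) yields the
configured floor, 10⁻⁶ SU by default (`--min-len`).  A branch whose
non-matching bucket is empty — no observed discordance — falls back to the
matching-bucket mean of the corresponding role, logged as low confidence;
when all gene trees equal the species tree this fallback reproduces the
input lengths exactly (up to float summation).  A branch with no resolved
quartet observations at all raises an error naming the branch.

## Aggregation over all quartets

Each internal branch's quadripartition takes A, B from the focal node's
children, C from the sibling subtree and D from everything beyond the
parent; a root child with an internal sibling contributes the single
balanced-root quadripartition (C, D from the sibling's children), and a root
child with a leaf sibling contributes none (its sum comes from the D role
below, as above).  Observations are weighted uniformly over
(quartet × gene × individual-combination); quartets spanning a gene-tree
polytomy are unresolved and excluded; gene trees missing a species simply
contribute no quartets through it; all-zero-length gene trees are excluded
with a warning.

Two engines share this contract.  The brute force enumerates quartets and
reads each observation off patristic distances via the four-point
decomposition.  The fast engine anchors every resolved quartet at the unique
gene-tree node where the near pair's paths diverge: one O(m) bottom-up pass
per gene computes, per node and per far-pair class, pair counts and sums of
distances to the pair's junction; an O(m) rerooting pass extends these to
the "up" component; an O(m) anchor pass then combines near-side counts and
distance sums across component pairs.  Three passes (one per topology class)
per (gene, branch) give O(n²k) total.  Equivalence with the brute force to
10⁻⁹ is asserted on 50 randomized instances with missing leaves, polytomies
and multi-individual genes.

## Synthetic data

The simulator draws exponential coalescence times per species branch (exact,
not discretized), annotates SU lengths per traversed branch, and is
deterministic per seed.  It emulates true gene trees under the MSC with
per-branch rates and optional mean-one per-gene rate multipliers or
heterotachy.  It does **not** emulate gene-tree estimation error (noisy
branch lengths and topologies from finite alignments), missing data
correlated with rates, gene flow, or duplication/loss — so passing tests
demonstrate correctness under the model, not robustness to real-data
artifacts beyond the missing-leaf/polytomy perturbations used in the
equivalence tests.

Study conditions for the recovery tests were fixed once: an unbalanced
quartet with T₁ = 0.8 CU — average gene-tree discordance (2/3)e^(−0.8) ≈ 0.30,
a moderate ILS level — T₂ = 3 CU, strict clock (all μ = 1), terminals
0.5 SU, k = 10⁴ genes × 20 seeds; and 10-taxon random model trees
(uniform joins, branch CU lengths uniform on [0.3, 1.5], clock-like) with
k ∈ {10², 10³, 10⁴} for the error-scaling check.  The large T₂ keeps the
terminal estimators inside the regime of their defining limits; the
acceptance script re-runs exactly these conditions.

## Evaluation metrics

Branch-length error between two annotations of one topology: branches
correspond by the leaf set below them, the two root-incident branches are
compared as their sum, and per-branch errors e = est − true summarize as
MAE, signed bias, RMSE, and mean absolute log error with non-positive
lengths floored at 10⁻⁶ on both sides.  The ILS level of a gene-tree set is
the mean normalized Robinson–Foulds distance to the species tree on shared
taxa (genes sharing < 4 taxa are skipped), normalized by the total internal
edge count of both unrooted trees, so polytomous gene trees are not
penalized as full conflicts; on quartets this equals one minus the matching
fraction exactly.

## Known limitations

* Terminal estimators carry the finite-upper-path residual described above;
  internal branches are unbiased under the model (their single-rate form is
  exact for every T₂ under a local clock).
* All estimators assume a local clock around the focal branch; strong rate
  asymmetry between the two branches above a focal branch violates the
  μ₂ = μ₃ reduction and biases μ̂₁.
* The per-edge split of the root sum is a reporting convention, not an
  estimate.
* Gene trees are taken at face value; no weighting by gene informativeness
  and no handling of estimation error in input branch lengths.
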