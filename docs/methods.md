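# Methods

## Model

A similarity structure is a labeled dissimilarity matrix: square, symmetric,
nonnegative, zero diagonal, entries in arbitrary rating/distance units. Before
any comparison every matrix is normalized by its maximum entry so values lie
in [0, 1]; division by the global maximum is the minimal map achieving that
range while preserving zeros and rank order.

**Unsupervised alignment.** For structures D (n×n) and D′ (m×m) the
Gromov–Wasserstein distance is the minimum over couplings Γ (nonnegative,
row sums p, column sums q, here uniform 1/n and 1/m) of

GWD(Γ) = Σ_ijkl (D_ij − D′_kl)² Γ_ik Γ_jl .

Uniform marginals encode that every item carries equal weight. The entropic
problem adds −ε·H(Γ) with the Shannon entropy H(Γ) = −Σ Γ_ik (log Γ_ik − 1);
this convention makes the inner subproblem a classical Sinkhorn scaling. The
squared-difference loss is used exactly; no KL variant.

**Evaluation.** The matching rate grades a plan with external labels: source
item i matches when argmax_j Γ_ij carries the same label; the rate is the
percentage of matched source items, and chance for n distinct shared labels
is 100/n. Argmax ties (measure-zero for strictly positive entropic plans, but
possible for degenerate inputs) break toward the smallest index and are
flagged. Duplicate labels are allowed — matching is by label equality, not
index. The supervised contrast, RSA, is the Spearman correlation between
strict upper triangles under the assumed label correspondence, with
average-rank tie handling.

**Visualization.** Metric MDS (SMACOF, 8 restarts, best stress kept, seeded)
embeds each structure in 3-D by default. The target embedding Y is rotated
onto the source X by the orthogonal Q minimizing ‖X − Q·YΓ*‖²_F, where the
stored n×m plan is transposed at this boundary so it right-multiplies Y's
columns, and the barycentric projection YΓ* is rescaled by n (a uniform
coupling carries mass 1/n per item; Q itself is scale-invariant but plotted
points are not). Q = UVᵀ from the SVD of X(YΓ*)ᵀ; reflections are permitted
since only orthogonality is required.

**Color-space baselines.** Stimuli are HEX codes. The RGB model is Euclidean
distance on 8-bit sRGB triples. The LAB model converts sRGB→CIELAB (IEC
61966-2-1 inverse companding, sRGB primaries, D65 white, 2° observer) and
applies CIEDE2000 with parametric factors k_L = k_C = k_H = 1, including the
a*-axis rescaling, the S_L/S_C/S_H weights, the rotation term R_T, and the
published hue-angle discontinuity rules.

## Solver

Each trial is a projected-gradient iteration: at the current plan the
gradient 2·(constC − 2·D Γ D′) is used as the cost of an entropic linear
transport subproblem solved by log-domain Sinkhorn at temperature ε. Numerical
choices, in the order they matter:

- **Inexact inner solves.** At ε near 10⁻³–10⁻⁴ of the squared cost scale,
  Sinkhorn's linear convergence rate degrades so far that tight marginal
  accuracy (10⁻⁸) is unreachable in any practical iteration count (measured:
  >20 000 iterations on a 93-item gradient). Intermediate outer steps
  therefore run a fixed budget of 50 warm-started log-domain iterations
  (marginal tolerance 10⁻⁷).
- **Verified convergence.** The outer loop stops when the plain GWD changes
  by less than 10⁻⁹ between steps — but a truncated inner solve can stall the
  plan and fake such a plateau, so apparent convergence is verified: the test
  must hold on two consecutive steps run at an accurate budget (up to 2000
  inner iterations, tolerance 10⁻⁸) before `converged` is set. The outer cap
  is 3000 steps (inexact steps need more of them; ~400–800 observed at small
  ε).
- **Temperature annealing.** Trials warm up through a ladder of larger
  temperatures, from ~1% of the squared cost scale down to the target ε by
  factors of 4, each stage converged loosely (ΔGWD < 10⁻⁷, ≤200 steps) and
  warm-starting the next — graduated non-convexity. This both cuts total work
  several-fold and avoids many poor sharp local optima that trap cold random
  starts at small ε. `anneal=False` exposes the raw single-temperature
  iteration. The returned plan is in either case a local optimum of the
  entropic objective at the target ε.
- **Feasibility polish.** The returned plan receives a final accurate
  Sinkhorn pass, then a projection onto the coupling polytope (alternating
  rescaling; if underflowed support blocks exact feasibility, capped
  row/column scaling plus a rank-one correction), guaranteeing marginal error
  below the 10⁻⁶ invariant of the `TransportPlan` type.
- **Cost evaluation.** The quartic objective is always computed through the
  factored decomposition ⟨D²p, p⟩ + ⟨D′²q, q⟩ − 2⟨Γ, D Γ D′⟩, never the
  4-index sum (an explicit-loop implementation exists in the test suite as an
  oracle).

**Sweep protocol.** n_trials ε values log-spaced on [eps_min, eps_max]
(defaults 10⁻⁴ to 10⁻¹, 500 values), one fresh random initialization per ε.
Initializations are i.i.d. uniform-positive matrices Sinkhorn-projected onto
the coupling polytope; the per-trial seed derives from the master seed via a
splittable stream (`SeedSequence([master, trial])`), so sweeps are
reproducible and parallelizable. The reported optimum minimizes the plain GWD
over converged trials, ties broken toward smaller ε then earlier trial. A
single fixed temperature is unreliable even on easy instances (at n = 5, ten
random starts at ε = 10⁻³ all landed in local optima an order of magnitude
above the exact permutation minimum, while the ε sweep reached it to 10⁻¹³) —
the sweep is part of the method, not a tuning convenience.

## Synthetic data

The generator produces structure pairs with known ground truth, emulating
three aspects of group-level similarity data:

- **Geometric structures** (`sample_structure`): i.i.d. standard-normal
  points in 3-D, Euclidean distances — honest metrics with the smooth
  geometry typical of perceptual similarity matrices.
- **Noisy relabeled copies** (`make_pair`): additive Gaussian noise on
  off-diagonals (re-symmetrized by averaging the perturbed triangles, clipped
  at zero), then a random permutation of items with labels traveling along.
- **Category pairs** (`make_category_pair`): items around category centroids
  placed on randomly oriented orthogonal directions so every centroid pair
  sits at exactly `between_sep` (default 1.5); within-category offsets are
  isotropic normal with sd `within_scale` (default 0.25). With
  `resample_fine=True` the target's offsets are redrawn independently —
  category skeleton preserved, fine correspondence destroyed. Defaults
  (2 categories × 31 items, n = 62) put within-category chance (100/31 ≈
  3.2%) within a few points of global chance (1.6%), so a category-level-only
  alignment is still near-chance at the item level, and give Spearman ρ ≈
  0.72–0.75 between resampled pairs — the regime where correlation and
  matching dissociate.
- **Rating panels** (`simulate_rater_panel`): each rater's judgment of pair
  (i, j) is round(clip(scale·base_ij + N(0, σ), 0, scale)) on the discrete
  0–7 scale; `simulate_llm_trials` is the continuous analogue averaged over
  a small number of trials (default 5). The noise models target the
  statistical role of the group average, not individual psychophysics — per
  rater noise magnitudes are free parameters chosen to span the regimes the
  property tests need.

What passing tests on these data do **not** show: robustness to
non-metric or asymmetric judgments, rater heterogeneity or response biases,
item sets whose geometry is far from low-dimensional Euclidean, or unequal
item salience (non-uniform marginals). The generator validates the machinery
and the dissociation logic, not any empirical claim about a particular
dataset.

## Problem sizes and budgets

Validation suites run at n = 30 (permutation recovery: 5% relative noise,
50-trial sweeps, 10 seeds) and n = 62 (dissociation: 12-trial sweeps, 10
seeds per condition); Monte-Carlo chance calibration uses n = 93 with 10 000
random couplings. These sizes keep the full suite in the tens of minutes on
a single CPU while staying at the scale where the phenomena of interest are
unambiguous.

## Known limitations

- Balanced transport only: no unbalanced/partial variants, no fused term for
  item features, uniform marginals hard-coded in the sweep path.
- The solver returns local optima; the sweep mitigates but cannot guarantee
  global optimality, and annealing biases trials toward basins that are good
  at larger temperatures.
- MDS embeddings are for visualization; stress is reported but no confidence
  statement attaches to embedded coordinates.
- The CSV interchange format stores dense matrices; it is not intended for
  very large n.
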