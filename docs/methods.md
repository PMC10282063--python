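# Methods

## The model

The observable is the meso-dyad probability P_m ∈ [0, 1] of PLA produced
by a symmetric salen/salan Al complex (P_r = 1 − P_m). A ligand is a pair
(A_m, B_nC_p) of an arene and an amine-linker fragment; the design space
is the Cartesian product of the two fragment sets (16 × 36 = 576 with the
bundled registry). Each fragment carries a descriptor vector computed (or
ingested) once; a ligand's feature vector is the concatenation of its two
fragment vectors, arene block first, names prefixed `A:`/`BC:` so that
attribution can assign effects to a fragment.

The surrogate is a GP regression y(x) ~ GP(0, k) on preprocessed
features, with k a Matérn-5/2 kernel with automatic-relevance-
determination lengthscales, a signal-variance scale, and (by default) an
inferred observation-noise variance. Targets are standardized internally;
hyperparameters maximize the log marginal likelihood from multiple random
restarts (log-space bounds [1e−3, 1e3], diagonal jitter 1e−6). Bounded
outcomes are modeled directly on the probability scale: at n ≈ 50–90 the
GP's smoothness assumption matters far more than the boundedness
violation, and predictions stay in range in practice.

Acquisition is expected improvement for maximization. Batches of q = 3
are chosen by sequential fantasy (Kriging-believer) selection: after each
pick the GP is conditioned on its own posterior mean at that pick (with
hyperparameters frozen) and EI is re-scored, so the first pick always
equals the q = 1 argmax and later picks are pushed away from it. The
incumbent f* stays at the best *observed* value during a batch; fantasy
values never raise it. Plain top-q ranking is available
(`strategy="rank"`).

The synthetic-scale constraint — steps(A_m) + steps(B_nC_p) ≤ 3 by
default — is a hard pre-filter on proposals, not a penalty: a candidate
over budget is removed before scoring. An unknown step count is an
explicit error, never a silent zero. Random initial designs are not
filtered (retrospective data may include costly literature complexes).

## Campaign mechanics

One run = 3 uniformly random initial observations, then 12 iterations of
(fit surrogate → propose 3 → observe → append). Campaigns repeat for 10
independent runs from per-run substreams of a master seed; all seeds are
recorded in the trace. Two separate campaigns serve the two objectives
(maximize P_m, maximize P_r); they share code, never state. Convergence
of a repeated campaign is the first iteration at which every run's
best-so-far equals the global optimum, i.e. the cross-run sd of
best-so-far collapses to zero.

Feature preprocessing for campaigns is fitted once on the full candidate
library rather than per iteration: descriptors are known for the whole
design space before any outcome is observed, so no outcome information
leaks, and the transform is stable when only three points have been
observed. Candidate rows are always transformed with those stored
statistics.

GP fits inside the campaign loop use 2 hyperparameter restarts (the
standalone `fit` default is 8); with ≤ 60 training points and ~10
features the marginal-likelihood surface is benign and the cheaper
setting changed no campaign outcome we measured, while keeping a
10-run × 12-iteration × 2-objective experiment to a couple of minutes on
one CPU.

## Preprocessing

Zero-variance columns are dropped; the rest are z-scored with population
statistics. Decorrelation removes, for each pair with |Pearson r| above
0.95, the later column in scan (load) order — a deterministic tie-break.
The absolute value is used because anti-correlated features are equally
redundant. The kept/dropped ledger, means, and scales serialize to JSON
and replay exactly on new rows. The transform is idempotent.

## Cross-validation harness

The 5-fold encoding benchmark uses k repeated random splits with test
size ⌊n/k⌋ — at n = 56 that is 45 train / 11 test per fold, the split the
benchmark is defined by. Note 5 × 11 = 55 ≠ 56: disjoint 5-folds of 56
cannot all have 11 test points, so repeated random subsampling is the
construction that honors those sizes; fold assignments are deterministic
given the seed.

## Descriptor encodings

* **One-hot** — indicator over the fragment vocabulary; the
  chemistry-blind baseline.
* **E-state indices** — Kier–Hall intrinsic state
  I = ((2/L)² δᵛ + 1)/δ perturbed by Σ(I_i − I_j)/(d_ij + 1)²; the
  per-atom inputs are the principal quantum number and hydrogen-
  suppressed valence-electron count. Pairwise perturbations are
  antisymmetric, so ΣS = ΣI on every graph — a property the tests
  exploit.
* **Coulomb-matrix eigenvalues** — M_ii = 0.5 Z_i^2.4,
  M_ij = Z_iZ_j/|R_i − R_j| with distances in bohr (Å converted on
  ingestion); the descending, zero-padded spectrum is invariant to rigid
  motion and atom permutation.
* **Percent buried volume** — fraction of a probe sphere occluded by the
  atoms' van der Waals spheres, integrated on a regular grid. Defaults:
  sphere radius 3.5 Å centered on the metal-binding site (or the atom
  centroid for an isolated fragment), Bondi radii, hydrogens included,
  no radius scaling, grid spacing 0.05 Å. These are declared conventions
  of this package, chosen as the common %V_bur setup; halving the grid
  spacing moves results by well under 0.5 percentage points, and a
  Monte-Carlo rejection-sampling oracle agrees to the same tolerance.
* **Ingested tables** (Mordred, quantum-chemistry summaries) — flat
  per-fragment tables are validated and flattened; per-atom/per-mode
  arrays (buried volumes, Mulliken and polar-tensor charges, frequencies)
  reduce to min/max/mean with systematic names; electronegativity
  −(E_HOMO + E_LUMO)/2 and hardness (E_LUMO − E_HOMO)/2 are derived.
  Nothing beyond flat summary tables is parsed — running electronic-
  structure jobs, or parsing their raw logs, is out of scope.

Reaction-condition columns (temperature, concentration) can be appended
to the feature frame by the caller but are off by default: ligand
structure dominates stereoselectivity in this chemistry, and the
descriptor-only representation is the one the campaign mechanics assume.

## Attribution

Shapley values use the interventional value function: v(S) is the mean
model output with features in S taken from the explained record and the
complement from each background row. Exact mode enumerates all 2^d
subsets (refused above d = 15) and satisfies efficiency, symmetry, and
null-player axioms to numerical precision; sampled mode averages
marginal contributions over random permutations (efficiency holds per
permutation by telescoping). The background is the full training matrix —
at n ≤ ~90 there is nothing to summarize. Feature ranking is descending
mean |φ| with alphabetical tie-break; the reported sign is the Pearson
correlation sign between feature values and their φ across records.

The multivariate linear models are OLS on z-scored descriptors, reporting
coefficients, R² = 1 − SS_res/SS_tot, and in-sample MAE. Feature subsets
come from the Shapley ranking (top-k, default 8); the package never
claims mechanistic meaning for a subset — that judgment stays with the
user. Rank-deficient designs raise an error naming exactly collinear
columns.

## Synthetic landscape

`make_landscape()` defaults: 16 arenes × 36 linkers (a 576-ligand,
fully enumerable mirror of the design space), d = 4 i.i.d. standard-
normal descriptors per fragment (optional pairs with prescribed
correlation ρ), planted weights w_A = (1.5, 1.2, 0.15, 0.15) and
w_BC = (1.4, 0.12, 0.12, 0.12) — three dominant features at ≥ 5× the
background — interaction γ = 0.2, and latent noise sd τ = 0.05 frozen per
ligand by a hashed seed. γ is kept small so additive attribution
assumptions approximately hold; τ mimics, qualitatively only, the small
free-energy differences that make stereoselectivity noisy. Synthetic step
counts are uniform on {1, 2, 3}. With γ = τ = 0 the logit of P_m is
exactly linear in the concatenated descriptors, which gives the
weight-recovery oracle used in tests.

What the generator does *not* emulate: real DFT descriptor distributions
(correlated, heavy-tailed, unit-bearing), measurement error on NMR-derived
P_m, replicate structure, or condition dependence. Passing tests on these
landscapes therefore demonstrate correctness of the machinery and
sample-efficiency of the loop under a favorable, known signal — not
performance on laboratory data.

## Bundled stand-in dataset

The repository cannot ship the literature table it emulates, so
`src/ropbo/data/` contains a constructed stand-in (every filename says
`synthetic`): 56 records over re-keyed fragment ids with
fragment-additive logistic P_m rounded to two decimals, built to match
the published summary facts — exactly 9 records with P_r > 0.5, exactly
3 with P_r > 0.8, a unique isoselective optimum (A3C3B1, P_m 0.94) and
heteroselective optimum (A6C1B3, P_m 0.11), one A5 record (P_m 0.76),
and a high-performing but 5-step ligand (A15C3B1) that the cost filter
excludes. The per-fragment descriptor tables are synthetic DFT-style
aggregates whose informative columns (buried volume, frontier-orbital
energies) track each fragment's latent effect with small noise,
mirroring the informativeness that real DFT descriptors showed for this
chemistry; both campaign optima cost ≤ 3 steps, so the feasibility
filter never blocks convergence. `table1_complexes.csv` transcribes the
printed outcomes of eight representative complexes for worked examples.

## Numerical choices and edge cases

* Jitter 1e−6 on the kernel diagonal; noise-free mode uses α = 1e−10.
* EI at σ = 0 degenerates to max(μ − f*, 0); tiny negative values from
  floating-point cancellation are clamped to 0.
* A constant target collapses the standardized GP to its mean;
  predictions return the constant.
* Duplicate (ligand, conditions) rows are kept as replicates;
  aggregation is always explicit.
* A dataset file supplying only P_r fills P_m = 1 − P_r (and vice
  versa); the complement invariant is enforced to 1e−9 on every load.
* MW_cal uses a zero end-group mass by default
  ((conversion × feed ratio × 144.13)/1000 kDa), with the benzyl-alcohol
  end group (108.14 g/mol) available as an option; the zero-end-group
  form is the one the worked examples round-trip.
* Campaign problem sizes used by the acceptance script: 56-record
  retrospective space, 10 runs × 12 iterations × 5 master seeds per
  objective; 200-candidate synthetic subspaces, 1 run × 10 seeds, for
  the BO-vs-random comparison, with runs that never reach the optimum
  censored at 13 iterations.

## Known limitations

* The GP ignores the [0, 1] range of P_m; a warped or Beta likelihood
  would be more principled for extreme selectivities.
* Kriging-believer batches can under-explore when the surrogate is
  overconfident early; no local penalization alternative is provided.
* The decorrelation filter's scan-order tie-break means feature *order*
  can change which of two redundant descriptors survives.
* Exact Shapley is exponential in d; beyond 15 features only the sampled
  estimator is available.
* Retrospective campaigns observe by table lookup and therefore cannot
  model measurement noise between replicate experiments.
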