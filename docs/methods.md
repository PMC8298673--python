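# Methods

## Model

The package learns the map from a molecular bonding graph to the one
relaxed 3D structure associated with it. This presumes training data free
of conformational ambiguity: families of constitutional isomers (fixed sum
formula, varying connectivity) where each graph was relaxed once, in a
consistent way. Under that assumption graph → structure is a function and
supervised learning applies; with conformers in the data the labels would
be multivalued, so duplicate graphs are rejected at model construction.

Internally the target is not the coordinates (which carry arbitrary
rotation/translation and atom indexing) but the heavy-atom pairwise
distance matrix, canonically sorted. One kernel ridge regression machine
is trained per pair slot IJ of the padded n_max × n_max matrix —
n_max(n_max−1)/2 targets — but all machines share a single kernel, so
training reduces to one Cholesky factorization of K + λI applied to the
whole label matrix. Hydrogens are handled separately by four machines
predicting each hydrogen's distances to four anchor heavy atoms.
Coordinates are recovered from the predicted distances by a native
distance-geometry solver, and hydrogens are completed geometrically.

Assumptions worth keeping in mind:

- One structure per graph (no conformers) in training and at query time.
- Query molecules must fit the padding (≤ n_max heavy atoms) and use only
  elements seen in training (enforced, with a clean error).
- Distances cannot encode chirality: every reconstruction is defined up to
  a mirror image. Evaluation minimizes RMSD over both hands and reports
  how often the mirror won.

## Representations

All molecular schemes build an n×n heavy-atom matrix, sort it canonically,
zero-pad and flatten the upper triangle (the diagonal is kept only for
`graph_cm`, where it is informative). `bond_length` defines the
through-bond length l_ij as the minimum over connecting paths of the
summed per-edge lengths r_cov(a)+r_cov(b); minimizing total weight rather
than hop count makes l a true metric. The covalent radii are pinned to the
Cordero 2008 single-bond table, shipped as a versioned JSON file — several
published tables disagree at the 0.01–0.05 Å level, and pinning one makes
every derived feature reproducible bit for bit.

Canonical sorting orders atoms by non-decreasing Euclidean row norm of the
representation matrix. Row-norm ties are endemic (bond-order matrices of
isomer families tie constantly), and naive tie-breaking is not invariant
to the input atom order. The implementation therefore refines ties
Weisfeiler–Lehman style — the key (norm, descending-sorted row, nuclear
charge) is sharpened with sorted (entry, neighbor-rank) multisets until
the partition stabilizes — and, where correlated tie classes survive
(they do: two tied classes can be individually unsplittable yet jointly
constrained), falls back to an exact individualization–refinement search
over the tied branches, keeping the lexicographically smallest sorted
matrix. For ≤ 9 heavy atoms this costs microseconds-to-milliseconds per
molecule. Residual ties are automorphic: any choice yields the same
matrix, and the stable original-index order makes the choice
deterministic. Path-length matrices are rounded to 1e-10 before sorting
so that float summation-order noise cannot flip tie decisions; this is
what makes representation vectors bit-identical under input permutations.

`graph_bob` groups graph-CM entries into element (pair) bags, sorts each
descending and pads to the largest size seen in training; bag sizes are
fitted model state, persisted with the model. Queries with unseen element
pairs raise an out-of-vocabulary error; overflowing bags are truncated
(smallest entries dropped) with a logged warning. The distance labels for
`graph_bob` follow the graph-CM canonical permutation, which carries the
same through-bond ordering in matrix form.

The crystal representation is the stoichiometry 8-tuple (period,
valence-electron count) per ABC₂D₆ site in fixed Wyckoff order; "column"
means the s+p valence count (1–8), not the 18-column table index.

Disconnected graphs (transition-state-like inputs with detached
attacking/leaving fragments) are supported by adding order-1 pseudo-edges
between every heavy atom of a detached fragment and the user-supplied
reaction-center atoms; there is no automatic reaction-center detection.

## Kernel ridge regression

Laplacian `exp(−‖Δx‖₁/σ)` and Gaussian `exp(−‖Δx‖₂²/2σ²)` kernels are
supported. The solve uses a Cholesky factorization with jitter escalation
(0 → 1e-10 → 1e-8 → 1e-6) before failing hard. One (kernel, σ, λ) is
shared by all targets — selected to minimize the mean MAE over all
distance targets — rather than tuned per target; per-target
hyperparameters are deliberately not implemented.

Default search grid: σ log-spaced over [0.05, 20] × the median nonzero
pairwise feature distance (13 points; the median anchors the grid to the
feature scale, so the same grid works for bond counts and Coulomb-matrix
magnitudes alike), λ over the decades 1e-10 … 1e-3, both kernel families.
Model selection is nested fivefold cross-validation: inner folds pick the
grid point, outer folds report an unbiased MAE, and the final model is
refit on all data with hyperparameters selected by an inner-style search
on the full set. All fold shuffling and subset draws derive from a single
user seed; identical seeds give bit-identical tables.

## Hydrogen machines

Four targets per hydrogen: the distances to its bonded heavy atom and
three further anchors. Two choices here are implementation-defined because
neither the anchor-to-label correspondence at prediction time nor the
featurization of individual hydrogens follows from the method description:

- **Anchors** are chosen by through-bond proximity to the bonded heavy
  atom (ties broken by canonical index), with a geometric veto that skips
  candidates leaving the four anchors coplanar (tetrahedron volume
  < 0.1 Å³). A pure-graph criterion is used instead of Euclidean
  nearest-neighbors because idealized geometries contain exactly tied
  distances, and a tie that resolves differently in the reference and the
  embedded frame silently mispairs predicted distances with anchors
  (observed as ~1 Å hydrogen errors before the change). A separate
  routine, `select_hydrogen_anchors`, implements the classic
  reference-geometry rule (four nearest heavy atoms to the hydrogen, with
  a coplanarity swap) for training-time analysis.
- **Features** are the whole-molecule representation vector tagged with
  the bonded atom's nuclear charge, its canonical position, and a sibling
  slot index. Geminal hydrogens are graph-identical; without the slot
  their kernel rows coincide, the kernel matrix is singular at λ → 0, and
  the model can only learn their average. The slot assignment is
  deterministic but arbitrary between geminal partners — exactly as their
  labels are.

Placement scans a deterministic generalized-spiral grid (default 4096
points) on the sphere of the predicted bond radius: quadrature-grade
nodes are unnecessary because the grid is only an argmin domain, and the
spiral is uniform to ~0.06 Å at bond radius. A soft quadratic clash
penalty (cutoff 1.2 Å, weight 10) against already-placed hydrogens breaks
mirror-symmetric ties; remaining ties fall to the lowest grid index. The
bond radius itself is honored exactly.

## Distance-geometry solver

Two stages: (1) classical metric embedding — double-center −½D², take the
top-3 spectral components; (2) L-BFGS minimization of the raw stress
Σ(‖r_i−r_j‖ − D_ij)² with analytic gradients (ftol 1e-18, gtol 1e-14,
default cap 500 iterations; line search guarantees a monotone stress
history, which is recorded). For exact Euclidean inputs stage 1 is already
machine-precision and exact matrices from random point sets are recovered
below 1e-14 Å RMSD; stage 2 is what absorbs regression noise. Full dense
matrices are always embedded — the model predicts all pairs — so no
sparse-completion machinery exists. A consequence of using a smooth local
minimizer seeded by the spectral solution is that solver noise is
essentially absent; performance-curve kinks attributable to a stochastic
external solver will not appear here.

Crystals embed in fractional-coordinate space, are aligned onto the ideal
site template (mirror allowed), wrapped into [0,1), and scaled by the
separately predicted lattice constant.

## Synthetic data generator

The molecular generator emulates a family of constitutional isomers:
distinct connectivities (uniform-random trees via Prüfer sequences, or
single-ring variants) over a fixed heavy-atom stoichiometry, deduplicated
by an element-colored graph hash, with hydrogens completing standard
valences. For ≤ 7 heavy atoms trees are enumerated exhaustively, so
over-requests report the exact maximum; for 8–9 atoms sampling with a
stall limit is used. Each family fixes its unsaturation (all trees or all
single-ring) because mixing would change the hydrogen count and break the
fixed-sum-formula premise.

Each graph maps to exactly one geometry built from idealized internal
coordinates: bond lengths are covalent-radius sums, angles tetrahedral,
sibling torsions follow a canonical anti/gauche pattern (with a
deterministic global torsion offset retried if atoms clash), rings are
regular polygons with substituents alternating above/below the plane.
The map is seed-independent and bit-reproducible; the seed only selects
which connectivities are drawn.

What this emulates — and what it does not: the generator reproduces the
structural premises of the learning problem (one minimum per graph,
consistent generation, distances determined by connectivity) but its
geometries are exactly ideal, with none of the angle/length relaxation,
conjugation effects or steric distortion of quantum-chemistry data, and
no label noise. Passing tests therefore demonstrate the pipeline's
correctness and its qualitative learning behaviour (monotone learning
curves with log–log slope ≈ −0.16; bonded distances learned to ~0.07 Å
while pairs ≥ 4 bonds apart carry ~10× the error, mirroring the
long-range-flexibility effect in real data), not the absolute accuracy
attainable on quantum-chemical datasets — for that, the `benchmark`
command runs the published protocol on downloaded data. Held-out distance
MAE on the 9-heavy-atom fixture family is ~0.37 Å at 256 training
molecules and still falling; useful as a regression baseline, not as a
chemistry claim.

The crystal generator emits distinct ABC₂D₆ stoichiometries from p-block/
alkali element pools (720 possible combinations). The lattice constant is
a smooth closed form in per-element size proxies — themselves a linear
closed form in (period, valence count), increasing with period and
decreasing with valence — plus Gaussian noise of standard deviation
0.1 Å, a noise level chosen to resemble the scatter of DFT-relaxed cell
constants around smooth chemical trends. Fractional sites are the ideal
elpasolite positions with the anion parameter set deterministically from
the A/D size proxies. Because the noise-free part is an exact function of
the representation, held-out lattice-constant MAE approaching the noise
floor (≈ 0.08 Å ≲ σ = 0.1 Å) is the correct parameter-recovery outcome.

## Numerical choices and degenerate inputs

- Jitter escalation for kernel solves as above; λ = 0 is allowed and
  interpolates when the kernel is nonsingular.
- Distance-target invariants enforced at construction: molecular
  heavy-atom distances > 0.5 Å, padded entries exactly zero.
- Embedding rejects n < 3, asymmetric or non-positive inputs.
- Fewer than four heavy atoms: hydrogen machines fall back to the
  available anchors (targets zero-padded).
- Molecules exceeding n_max, unseen elements, unseen element-pair bags:
  explicit errors, never silent degradation.
- Non-converged embeddings are returned with `converged=False` and logged,
  never hidden.

## Problem sizes used in tests and the acceptance script

The shipped study conditions are a 320-molecule nine-heavy-atom family
(256 train / 64 test, the size at which the learning-curve and anisotropy
behaviour is already unambiguous), 100 random distance-geometry recovery
problems at n = 4…9, and 500 crystals (400/100). These run the full
pipeline — featurization, nested or plain fivefold grid search, Cholesky
solves, embedding, hydrogen placement — at sizes a laptop handles in
seconds while leaving every algorithmic path exercised.

## Known limitations

- Chirality and diastereomer selection are fundamentally outside a
  distance-only formulation.
- Hydrogen placement inherits the geminal ambiguity discussed above;
  heavy-atom metrics are unaffected (and all reported MAE/RMSD are
  heavy-atom quantities).
- The padded-slot distance targets are trained as zeros and discarded at
  query time; models are specific to their n_max.
- Crystal support covers the cubic elpasolite template only (no periodic
  images in the distance labels, no non-cubic cells).
- The `benchmark` protocol uses a seeded random split at the published
  train/test sizes; the original molecule-level split is unpublished, so
  published error values can only be matched up to split noise.
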