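# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Phase-noise model

Complex MR data carries i.i.d. Gaussian noise of sd &sigma; on the real and
imaginary channels. The reconstructed phase error is therefore
non-Gaussian in general: uniform on (−&pi;, &pi;] where there is no signal
(A = 0), and approximately N(0, (&sigma;/A)²) when A &Gt; &sigma;. The
generator offers both the exact complex-channel mechanism
(`NoiseSpec(mode="complex_channel")`) and a direct Gaussian-on-phase mode
used by the validation experiments, which add i.i.d. N(0, variance) to the
true unwrapped phase before wrapping. The per-voxel i.i.d. assumption is a
modelling choice; scanner noise can be spatially correlated by
reconstruction filters.

## Unwrapping as MAP inference

The wrap-count field k minimises a pairwise MRF energy with the convex
squared-difference potential over 6-neighbour pairs (see README for the
formula). Properties that the implementation relies on and the tests
assert:

* **Submodularity of every move.** For V(x) = x², V(t+2&pi;) + V(t−2&pi;)
  − 2V(t) = 8&pi;² > 0 regardless of t, so every binary +1-move problem is
  representable as a cut and solved exactly.
* **Gauge freedom.** The energy depends only on count differences, so all
  results are defined up to a global integer offset per connected
  component; the misclassification ratio removes the modal offset before
  counting, and the pipeline re-references the counts to the modal in-mask
  value before computing the fieldmap.
* **Exactness without noise.** If no true adjacent phase difference
  reaches &pi; inside the mask, wrapping is the only discontinuity and the
  MAP solution equals the truth exactly; the phantom is constructed to
  satisfy this precondition, and the noise-free test demands MCR = 0.

Iteration starts at k = 0 and applies optimal +1 binary moves until no
move lowers the energy (negative relative wraps are reachable because only
differences matter). Termination tolerance is a relative 1e-9 on the
energy; `max_iterations` = 100 is a safety cap — the default phantom
converges in 2–4 moves.

**Quality weighting.** The per-edge weight is the geometric mean of the
two voxels' magnitudes, each normalised by the 95th magnitude percentile
and clipped to [0, 1]; voxels below `mask_threshold` = 0.05 (of the
normalised magnitude) are excluded from the graph and from all scores.
This specific formula is a package choice: it is bounded, symmetric and
monotone in both magnitudes, which is all the method requires.

## The flow engine

The max-flow solver is a Dinic implementation over CSR arrays (numba-
compiled) with implicit terminals. Float capacities are scaled to int64
(scale 2³², reduced automatically for very large totals) so flow
arithmetic is exact; "infinite" capacity is one unit above the sum of all
finite capacities. Tie-breaking: nodes reachable from the source in the
residual graph take label 0, so per-node labels on exact ties are
implementation-defined while energies are not.

Constrained re-solves (min-marginals) reuse the residual state: pinning a
node to a label only adds terminal capacity, so the energy increase equals
the maximum extra flow between the node and the opposite terminal through
the residual graph — found by repeated BFS augmentation with an undo log,
which restores the residual before the next node. A cold re-solve path
exists as the reference implementation and both are tested to be
value-identical; enumeration on ≤12-node problems confirms exactness.

## Confidence and the gauge anchor

At convergence the MAP move is "no change", and the confidence of voxel v
is the softmax of its two min-marginals. One subtlety is inherent to the
translation-invariant energy: incrementing *every* voxel of a component is
free, so the unconstrained min-marginals of the converged move problem are
degenerate (every &omega; would be 0.5). That freedom is pure gauge — it
does not alter any phase difference. The confidence problem therefore pins
one anchor voxel per connected component (the highest-magnitude voxel) to
"no move", and &omega;_v measures the energy cost of flipping v *relative
to its component*. Consequences: the anchor itself reports &omega; = 1,
and values are meaningful as relative stability, not calibrated
probabilities (min-marginals are not exact marginals in loopy MRFs).

Because the squared potential produces large flip costs wherever edge
weights are appreciable, &omega; saturates near 1 in high-signal regions;
informative low values appear exactly where they should — voxels whose
noisy phase sits near &pi; away from their neighbours (genuine wrap
ambiguity) and low-magnitude voxels such as the perilesional band around a
resection. Exact per-voxel confidence costs one constrained re-solve per
voxel; for large volumes a `stride` option evaluates a subsample and fills
the mask by nearest neighbour (off by default).

Confidence is computed from the *final* move problem only: at convergence
it measures the stability of the delivered wrap counts, which is what the
downstream registration consumes.

## Fieldmap and distortion correction

Fieldmaps are carried in Hz (f = &gamma;&Delta;B0/2&pi;), which removes the
gyromagnetic-ratio constant: f = &Delta;&Theta;/(2&pi;&Delta;TE) and
&delta;_PE = pe_sign·f·T_acq voxels, with T_acq the user-supplied
*effective* readout time (any parallel-imaging acceleration already
divided out). The wrapped *difference* of the two echoes is unwrapped, not
each echo separately — differencing removes echo-common phase and the
difference field is the smooth quantity the prior describes.

The distortion forward model places signal from true PE coordinate y at
y' = y + &delta;(y). The simulator inverts this map per line (monotone
interpolation; folded lines fall back to clamped inversion with a warning)
and multiplies by dy/dy'; correction samples the distorted image at
y + &delta;(y) with 1D cubic interpolation and multiplies by
1 + &part;&delta;/&part;y, clamped at 0.01 with a logged warning where the
geometry folds. With modulation on, total intensity of compactly supported
images is conserved to well under 1%.

## Registration refinement

PE-only cubic B-spline free-form deformation; the control grid carries a
one-spacing margin so the basis sums to one over the whole image (constant
coefficients reproduce that constant to machine precision). The data term
per control point is SEMI: a joint histogram over the Gaussian support
(&Gamma; sd = control spacing, truncated at 3 sd) with cubic B-spline
Parzen windows on 32 bins spanning the 1st–99th intensity percentiles,
scored by Studholme NMI (H(R)+H(F))/H(R,F) with natural logs; a
degenerate single-bin histogram scores 2 with a warning.

The pairwise term is the absolute difference of the *accumulated
registration update* at neighbouring control points — the projection R of
all refinement applied so far plus the candidate label. This regularises
the registration over its full time course (updates compound correctly
across sweeps and levels) without smoothing away the fieldmap
initialisation, which is a trusted measurement rather than a quantity the
registration invented. Per-control-point confidence &sigma; (basis-weighted
average of the voxel confidences, clamped so the data weight 1 − &sigma;&lambda;
stays nonnegative) modulates the balance; &lambda; defaults to 0.5 as a
neutral setting of a scale the method leaves free. At &sigma;&lambda; = 1
the refinement is exactly zero.

Optimisation is &alpha;-expansion: labels are visited in a fixed order
(default range ±10 voxels, step 1.0 at the coarse level and 0.5 at the
fine level; two levels with grid spacing 10 → 5 voxels and field
composition between levels); each sweep solves the binary keep-or-&alpha;
choice by graph cut, zeroing any pairwise edge that violates
submodularity for that particular move. The candidate data term is
evaluated with only the considered control point moved (a standard local
approximation), so every accepted expansion is verified against the
exactly recomputed total energy and rolled back if it does not decrease it
— the cost trace is non-increasing by construction. The floating image is
re-resampled from the original data at each evaluation with the full
current field and 1D Jacobian modulation; the optimiser uses linear
interpolation for speed (the fieldmap-correction path keeps cubic).

## The phantom

The generator emulates the statistical structure the method depends on —
smoothness, dynamic range, SNR structure — not MR physics: a low-order 3D
polynomial background spanning ~11 rad across the head, three Gaussian
field bumps, an ellipsoidal head mask with a smooth magnitude edge, and an
optional resection whose rim carries a steep radial field ridge
(amplitude 2.5 rad, width 2.5 voxels — a worst-case slope of
~0.7 rad/voxel, documented bound rim_amplitude <
&pi;·width·&radic;e·r_min/r_mean) over a near-zero-magnitude core. Default
grid 64×64×32 at 2.5×2.5×2.7 mm keeps every default run under a minute.
All stochastic outputs are bit-reproducible for a fixed seed.

What passing tests therefore show: correct energies, exact optimisation,
correct unit conversions, noise-model fidelity, and graceful degradation
with noise. What they do not show: performance on real k-space artefacts
(ghosting, chemical shift), spatially correlated noise, motion, or
anatomies whose true field violates the sub-&pi; smoothness precondition —
on such data the MAP solution is still the energy optimum but need not be
the physical truth.

## Problem sizes and determinism

The test suite exercises the full 64×64×32 study phantom for the noise
sweep and exactness checks, 24–32-voxel grids where exact per-voxel
confidence is computed, and 30×30×12 image pairs for registration
recovery — sizes chosen so each module's suite completes in seconds to a
couple of minutes. Simulation studies average five seeds per condition.
Every RNG is a seeded `numpy` Generator; reruns are bitwise identical.

## Known limitations

* Min-marginal confidence is relative (gauge-anchored) and uncalibrated.
* Exact full-volume confidence is O(voxels × local re-solve) and becomes
  the dominant cost on large volumes; use `stride` or compute on a mask.
* Anisotropic voxel sizes do not rescale the unwrapping potential (the
  six-neighbour prior treats all axes equally); an extension point, off by
  default.
* The registration's label set is discrete; sub-step accuracy comes only
  from the B-spline interpolation between control points.
* No eddy-current, motion or gradient-nonlinearity correction; the EPI and
  structural images are assumed affinely aligned upstream.
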