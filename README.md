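# epiunwarp

Correction of susceptibility artefacts in echo-planar MRI (EPI), built for
the interventional setting where a resection cavity creates severe, local
B0 inhomogeneity: **graph-cut phase unwrapping** of a dual-echo fieldmap
acquisition, **per-voxel confidence** of the unwrapping from min-marginal
energies, conversion to a **phase-encode displacement field** with Jacobian
intensity modulation, and a **confidence-modulated discrete B-spline
registration** that refines the correction exactly where the fieldmap is
unreliable. A synthetic phantom generator reproduces the statistical
structure of the validation experiments, so the whole chain is testable
without scanner data.

## Who this is for

Researchers working on EPI distortion correction (diffusion/functional MRI,
image-guided neurosurgery) who need a fieldmap pipeline that (a) unwraps
phase robustly at low SNR, (b) quantifies *where* the unwrapped fieldmap can
be trusted, and (c) falls back to image registration only in the
low-confidence regions.

## The model

Measured MR phase is known only modulo 2&pi;: &phi;_t(i) = &phi;_w(i) +
2&pi;k_i with unknown integer wrap counts k. Under a hard congruence
likelihood and a Gaussian smoothness prior, the MAP estimate of k minimises
a six-neighbourhood pairwise MRF energy

E(k | &phi;_w) = &Sigma;_&lt;i,j&gt; w_ij (2&pi;(k_i − k_j) + (&phi;_w,i − &phi;_w,j))²,

with edge weights w_ij from the signal magnitude (low-signal voxels are
down-weighted or masked). The squared potential is convex, so each binary
"add one wrap" move problem is submodular and solved *exactly* by one
max-flow/min-cut computation; iterating moves reaches the global minimum up
to an irrelevant global offset.

Confidence comes from **min-marginals**: &psi;_{v;j} is the minimum energy
with voxel v pinned to move-label j, obtained by adding an infinite
terminal arc and re-solving on the residual flow (cheap, local). The
confidence of the MAP label is the softmax

&omega;_{v;j} = exp(−&psi;_{v;j}) / &Sigma;_l exp(−&psi;_{v;l}),

in which the partition function cancels — no probabilistic normalisation is
ever computed.

The fieldmap is f = &Delta;&Theta; / (2&pi;&Delta;TE) Hz from the unwrapped
echo difference, and off-resonance displaces signal along the phase-encode
axis by &delta; = f·T_acq voxels. Correction resamples each PE line at
y + &delta;(y) and multiplies by the 1D Jacobian 1 + &part;&delta;/&part;y.
The registration stage then refines &delta; with PE-only cubic B-spline
control points, a spatially-encoded normalised-mutual-information data term
per control point, an |&Delta;deformation| pairwise penalty, and
&alpha;-expansion graph cuts — weighted per control point by the projected
unwrapping confidence &sigma;: energy −&Sigma;(1−&sigma;&lambda;)·SEMI +
&Sigma;&sigma;&lambda;·|&Delta;d|, so full confidence freezes the fieldmap
solution and zero confidence hands control to the image data.

## Worked example

Simulate a dual-echo acquisition of the built-in resection phantom at the
clinically measured phase-noise level (variance 0.71 rad), unwrap the echo
difference, and convert to a fieldmap:

```python
import numpy as np
from epiunwarp import (
    AcquisitionParams, NoiseSpec, add_phase_noise, default_spec,
    displacement_from_fieldmap, fieldmap_from_unwrapped_difference,
    generate_magnitude, generate_true_phase, mcr, phase_difference,
    simulate_echo_pair, true_wrap_counts, unwrap, unwrap_confidence,
    wrap_phase, PhaseVolume,
)

spec = default_spec(grid_shape=(32, 32, 16))       # resection phantom
truth = generate_true_phase(spec)
magnitude = generate_magnitude(spec)
params = AcquisitionParams(te1=0.008, te2=0.010, tacq=0.012, pe_axis=1)

fmap_true = truth.data / (2 * np.pi * params.delta_te)
noisy = add_phase_noise(truth, NoiseSpec("phase_gaussian", variance=0.71, seed=0))
e1, e2 = simulate_echo_pair(
    fmap_true + (noisy.data - truth.data) / (2 * np.pi * params.delta_te),
    params.te1, params.te2)

dphi = phase_difference(e1, e2)
result = unwrap(dphi, magnitude)
report = mcr(result.counts.k, true_wrap_counts(noisy), result.weights.mask)
print(f"converged: {result.converged} after {len(result.energy_trace)-1} moves")
print(f"misclassification ratio: {report.mcr:.5f} over {report.n_masked} voxels")

conf = unwrap_confidence(result)
print(f"median confidence in mask: {np.median(conf.omega[result.weights.mask]):.4f}")

unwrapped = PhaseVolume(dphi.data + 2*np.pi*(result.counts.k - report.global_offset),
                        wrapped=False)
fmap = fieldmap_from_unwrapped_difference(unwrapped, params)
disp = displacement_from_fieldmap(fmap, params)
err = np.abs(fmap.data - fmap_true)[result.weights.mask]
floor = (0.71 ** 0.5) / (2 * np.pi * params.delta_te)
print(f"fieldmap error: mean {err.mean():.2f} Hz (phase-noise floor ~{0.7979*floor:.0f} Hz)")
print(f"peak PE displacement: {np.abs(disp.data[result.weights.mask]).max():.2f} voxels")
```

Output:

```
converged: True after 2 moves
misclassification ratio: 0.00076 over 5258 voxels
median confidence in mask: 1.0000
fieldmap error: mean 53.20 Hz (phase-noise floor ~54 Hz)
peak PE displacement: 6.47 voxels
```

Even at clinical noise, fewer than 0.1% of voxels take a wrong wrap count,
and the residual fieldmap error is fully explained by the per-voxel phase
noise (sd &radic;0.71 / (2&pi;&Delta;TE) &asymp; 67 Hz at &Delta;TE = 2 ms)
— the unwrapping itself adds essentially nothing.

## Command line

`epiunwarp` exposes `simulate`, `unwrap`, `fieldmap`, `correct`,
`register`, `evaluate-mcr` and `pipeline` (the full workflow from a YAML
config; `--dump-defaults` prints every default). Times are in seconds,
fieldmaps in Hz, displacements in voxels along the stated PE axis (recorded
in a JSON sidecar).

```sh
epiunwarp simulate --outdir sim --seed 0
epiunwarp pipeline --config pipeline.yaml
```

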