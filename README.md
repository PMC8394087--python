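# ivusreg

Two-stage registration of temporal intravascular ultrasound (IVUS)
pullbacks: longitudinal frame matching by dynamic time warping (DTW),
followed by in-plane rigid registration of each matched frame pair by
mutual-information maximization with a Harmony Search optimizer.

## The problem

An IVUS pullback is the ordered stack of cross-sectional vessel images
recorded while the transducer is withdrawn through a coronary artery.
Comparing two pullbacks of the same vessel — before and after stent
deployment, or baseline and follow-up — lets clinicians quantify plaque
progression and the effect of an intervention, but the two acquisitions
never line up: they start and end at different positions (partial
overlap), the catheter's longitudinal oscillation samples some
cross-sections several times (frame repetition), and the freely rotating
catheter introduces per-frame in-plane rotation and translation.

`ivusreg` registers a pair of gated (end-diastolic) pullbacks in two
stages, using only global image measurements — no lumen segmentation or
morphological feature extraction:

1. **Longitudinal stage.**  Every frame pair gets the dissimilarity

   d(i, j) = 1 − |CC(i, j)|,

   where CC is the Pearson cross-correlation of the two frames' pixel
   vectors.  A regularized DTW recurrence

   D(i, j) = d(i, j) + min( D(i, j−1) + C, D(i−1, j) + C, D(i−1, j−1) )

   accumulates these costs — the penalty C favours diagonal steps — and
   backtracking yields a monotone warping path that may map one frame to
   several (repeated) frames of the other pullback.  Open boundaries
   (subsequence alignment, both orientations tried) handle partial
   overlap.

2. **Axial stage.**  Each matched pair is aligned by the rigid transform
   T = (θ, tx, ty) (rotation about the frame centre, then translation)
   that maximizes the mutual information

   MI(T(F), R) = Σ_{f,r} p_FR(f, r) log [ p_FR(f, r) / (p_F(f) p_R(r)) ]

   of the binned intensities of the transformed floating frame F and
   reference frame R.  The optimizer is a Harmony Search variant: new
   candidates are assembled element-wise from a memory of previous
   solutions, pitch-adjusted by an ALOPEX-style step (sign biased toward
   the most recent objective improvement, magnitude annealed), or drawn
   uniformly from the bounds; the memory-use and pitch-adjust rates grow
   linearly over the run.

Frames are preprocessed first: intensities below the 90th percentile of
the frame's cumulative distribution are zeroed and Perona–Malik
anisotropic diffusion suppresses speckle while preserving edges.

Because clinical pullbacks are not redistributable, the package ships a
first-class simulator: phantom pullbacks of drifting vessel-like
cross-sections, plus the four-distortion protocol (Gaussian amplitude
noise; 60–80 % partial overlap; 10 % frame repetition, 1–4 extra copies;
rigid perturbation with rotation in [−15°, 15°] and translation in
[−5, 5] px) with full ground truth, and the matching error metrics.

## Worked example

```python
from ivusreg import (DistortionSpec, generate_phantom_pullback,
                     make_synthetic_pair, preprocess_pullback,
                     register_longitudinal, register_axial,
                     alignment_error, rigid_error)

base = generate_phantom_pullback(40, (128, 128), seed=1)
reference, distorted, truth = make_synthetic_pair(base, DistortionSpec(seed=3))

pre_a = preprocess_pullback(reference)
pre_b = preprocess_pullback(distorted)
result, matches = register_longitudinal(pre_a, pre_b)
print("alignment error:",
      round(alignment_error(truth.correspondence, result.path), 3), "frames")

matches = register_axial(matches, pre_a, pre_b, global_seed=0)
rot, trans, _ = rigid_error(
    [truth.per_frame_transform[m.index_b] for m in matches],
    [m.transform for m in matches])
print("rotation error: %.2f deg, translation error: %.2f px" % (rot[0], trans[0]))
```

prints

```
alignment error: 0.037 frames
rotation error: 0.23 deg, translation error: 0.15 px
```

i.e. the warping path deviates from the ground-truth correspondence by
well under a tenth of a frame on average, and the axial stage recovers
the hidden per-frame rotations and translations to about a quarter of a
degree and a sixth of a pixel.

The same pipeline is scriptable from the shell:

```bash
ivusreg simulate --n-frames 118 --seed 1 --out sim/
ivusreg register sim/reference.tif sim/distorted.tif --out reg/
ivusreg evaluate --ground-truth sim/ground_truth.json --matches reg/matches.csv --out metrics.json
ivusreg experiment --n-pairs 10 --distortions 1,2,3 --seed 0 --out exp/
```

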