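# Methods

## Scope and model

`ivusreg` aligns two end-diastolic (gated) IVUS pullbacks of the same
vessel.  Gating is assumed done upstream; within a gated pullback the
remaining misalignments are (i) longitudinal — different start/end
positions and repeated sampling of cross-sections due to catheter
oscillation — and (ii) axial — per-frame in-plane rotation and
translation from catheter motion.  Cardiac-phase deformation is assumed
removed by gating, so the axial model is strictly rigid; affine or
non-rigid deformation is out of scope by design.

## Preprocessing

Each frame is thresholded at the 90th percentile of its empirical
intensity CDF (percentile by linear interpolation on the sorted pixel
vector; sub-threshold pixels set to 0, eliminating blood speckle and
catheter artifacts) and then filtered with explicit 4-neighbour
Perona–Malik anisotropic diffusion, conductance g(∇I) = exp(−(∇I/κ)²),
reflective boundaries.  Defaults: κ = 30 (intensity units of
8-bit-scaled data), time step λ = 0.15 (stable for λ ≤ 0.25), 10
iterations.  The pipeline first rescales each pullback linearly to
[0, 255] float (`normalize_pullback`) so κ has a fixed meaning across
acquisitions; a constant stack is left untouched.  The scheme conserves
the image mean exactly (antisymmetric fluxes, zero boundary flux).

## Longitudinal stage

The frame-pair cost is d(i,j) = 1 − |CC(i,j)| with CC the Pearson
correlation of the flattened pixel vectors; a constant frame is
assigned CC = 0 (it carries no alignment information).  The accumulated
cost follows

    D(i,j) = d(i,j) + min(D(i,j−1) + C, D(i−1,j) + C, D(i−1,j−1)),

with C ≥ 0 charged to vertical/horizontal steps (default C = 0.05 on
the [0,1] cost scale).  Ties in the minimum are broken diagonal ≻
vertical ≻ horizontal, pinned for determinism.

**Boundary handling.**  Closed boundaries run corner to corner.  For
partially overlapping pullbacks the open mode is a *subsequence*
alignment: the path starts and ends anywhere along one pullback while
covering every frame of the other; both orientations are computed and
the one with the lower per-step average cost is kept.  We deliberately
do not free the start on both sequences simultaneously: with the
unnormalized recurrence, every extra step adds a non-negative cost, so
a fully-open formulation systematically prefers arbitrarily short
near-corner paths (we observed three-cell "alignments" beating the true
forty-cell corridor) and no end-cell normalization can repair the
interior of the table.  The two-orientation subsequence form covers the
overlap geometries that occur in practice and is degenerate-free.

An optional Sakoe–Chiba band (off by default) restricts the path to a
corridor around the scaled diagonal.

## Axial stage

Mutual information is computed on a joint histogram with 32 bins per
image over the pair's min–max intensity range (frozen per pair, so all
candidate transforms share one binning), natural logarithm, with
0·log 0 ≡ 0.  MI is estimated on the preprocessed frames, consistent
with the rest of the pipeline.  The rigid transform rotates
counter-clockwise (on x–y axes, x = columns) about the frame centre
((H−1)/2, (W−1)/2) and then translates; resampling is bilinear with
zero fill, and the evaluation module uses the matching inverse
convention throughout.

The optimizer is Harmony Search over (θ, tx, ty), bounds θ ∈ [−20°, 20°]
and t ∈ [−8, 8] px — slightly wider than the simulated perturbation
ranges so the inverse of any perturbation is interior.  Memory size 20;
memory-consideration rate h: 0.7 → 0.95 and pitch-adjustment rate
p: 0.1 → 0.5, both linear over 500 iterations (explore early, refine
late); the identity transform is always seeded into the initial memory,
so the reported MI never drops below the unregistered MI.  The pitch
step is ALOPEX-style: its sign is biased (probability 0.75) toward
sign(Δx_i·ΔJ) of the last two evaluations — the direction that most
recently improved the objective — and its magnitude is half-normal,
scaled by 0.1 × the bound range and an annealing temperature that
decays by 0.99 per iteration (≈ 0.007 after 500 iterations, giving
sub-0.05° final steps).  With no history the step is uniform within
±1 % of the bound range.  A candidate whose objective is non-finite is
rejected with a warning.  Every matched pair gets an RNG stream derived
from (global seed, index_a, index_b), so results do not depend on the
order in which pairs are processed.

## Synthetic data

The phantom generator emulates a gated pullback of a diseased coronary
segment at 128×128 px.  Each frame contains a dark eccentric lumen
(elliptical perturbation), a bright wall annulus with an angularly
localised plaque thickening, a calcification arc with an acoustic
shadow cast radially outward, a second echogenic nodule, a
pericardium-like outer arc and, over one or two contiguous frame
windows, a side-branch opening through the wall.  All anatomical
parameters follow unit-variance Gaussian-filtered random walks with a
correlation length of ~3 frames — gated frames are roughly 0.5–1 mm of
vessel apart, so consecutive frames are similar but measurably
different.  Circumferential feature positions drift only a few degrees
over the pullback (slow catheter twist): plaque and calcium sit at
essentially fixed angles in a real gated acquisition, and this is what
keeps in-plane rotation from masquerading as longitudinal motion.
Multiplicative speckle has total contrast (std/mean) 0.5 — the
fully-developed-speckle value (speckle SNR ≈ 1.91) — split into a
persistent scatterer grain that evolves smoothly along the pullback
(adjacent real cross-sections share correlated texture) and a smaller
per-frame independent grain.

The distortion protocol applies, in order: partial overlap (keep a
contiguous uniform 60–80 % of the frames, discard split randomly
between head and tail), frame repetition (each frame independently with
probability 0.10 gets 1–4 extra consecutive copies, uniform),
per-frame rigid perturbation (rotation U[−15°, 15°], translation
U[−5, 5] px per axis, independent per frame — repeated copies get
independent draws, emulating re-sampling the same cross-section at
different catheter poses), and additive zero-mean Gaussian noise
(σ = 5 on the 0–255 scale), clipped to [0, 255].  Every step records
ground truth: the monotone original↔distorted correspondence, the kept
range and the per-frame transforms.

**What the phantoms do not capture.**  Real IVUS has vendor-specific
ring-down and catheter artifacts, non-rigid wall deformation residue,
guidewire shadows, and — crucially for a registration benchmark —
between-visit anatomical change (stents, plaque progression).  A
synthetic pair is built from a *single* pullback, so both frames of a
matched pair share the same underlying anatomy and speckle realization;
passing tests demonstrate that the pipeline inverts the simulated
distortions, not that it handles longitudinal biological change.

## Error metrics

Longitudinal accuracy is the alignment error: the mean, over
ground-truth pairs (i, j), of min |j′ − j| over computed pairs with
i′ = i, falling back to the Chebyshev distance to the whole path when i
never appears (this reduces to the intuitive frame offset for
one-to-one paths and handles one-to-many matches).  The normalized
error divides the mean error by the number of registered frames.  Axial
accuracy composes the estimated transform with the true perturbation —
a perfect estimate is the exact inverse — and reports |wrapped residual
angle| and the Euclidean residual translation, in mm as well when a
pixel spacing is supplied; no spacing is ever assumed.  A three-setting
MI summary (unregistered index-by-index / after DTW / after axial) is
available for real pairs without ground truth.

## Problem sizes and numerics

The shipped experiments use ten 118-frame pairs for the
longitudinal-only protocol and five 40-frame pairs for the full
two-stage protocol (the axial stage evaluates ~500 MI objectives per
matched pair; the scaled sizes keep a full run in the minutes range on
one core).  All experiments derive every stream (phantom, distortions,
optimizer) deterministically from one global seed; fixed seeds give
bit-identical outputs.  Degenerate inputs are defined explicitly:
constant frames give CC = 0 and MI = 0; a constant stack skips
normalization; 0·log 0 ≡ 0 in MI; DTW ties break toward the diagonal;
angles wrap to (−180°, 180°] before error statistics.

## Known limitations

The |CC| cost uses no structural information, by design; on pullbacks
whose frames are locally very similar, ±1-frame slips around repeated
frames remain the dominant longitudinal error, because a repeated copy
under an independent ±15° / ±5 px perturbation is only marginally more
similar to its own original than to an adjacent frame.  The axial
search is bounded to ±20° / ±8 px and will not recover larger motions.
MI is computed on preprocessed (thresholded) frames; heavily
thresholded frames concentrate the histogram mass, which is robust for
the phantoms but untested on raw clinical dynamic ranges.
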