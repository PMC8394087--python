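"""Phantom IVUS-like pullbacks and the four-distortion simulation protocol.

Pairs of sequences are built by modifying a single pullback: the
unmodified base acts as the reference, and the distorted copy is
produced by (1) partial overlap — discarding frames at the head and
tail so 60-80% of the original remains, (2) frame repetition — each
frame has a 10% probability of being repeated 1-4 extra times,
emulating longitudinal oscillation of the catheter, (3) per-frame rigid
perturbation — rotation uniform in [-15, 15] degrees and translation
uniform in [-5, 5] pixels, emulating circumferential probe motion, and
(4) additive zero-mean Gaussian amplitude noise.  Every step records
ground truth (frame correspondences and per-frame transforms), so the
whole registration pipeline can be scored without clinical data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .axial import apply_rigid
from .io_core import Pullback, RigidTransform

__all__ = [
    "DistortionSpec",
    "DistortionRecord",
    "generate_phantom_pullback",
    "distort_amplitude",
    "distort_overlap",
    "distort_repeat",
    "distort_rigid",
    "make_synthetic_pair",
]

INTENSITY_RANGE = (0.0, 255.0)


@dataclasses.dataclass(frozen=True)
class DistortionSpec:
    """Parameters of the four distortions plus per-distortion switches."""

    noise_sigma: float = 5.0
    overlap_range: tuple[float, float] = (0.6, 0.8)
    repeat_probability: float = 0.10
    repeat_count_range: tuple[int, int] = (1, 4)
    rotation_range_deg: tuple[float, float] = (-15.0, 15.0)
    translation_range_px: tuple[float, float] = (-5.0, 5.0)
    enable_noise: bool = True
    enable_overlap: bool = True
    enable_repeat: bool = True
    enable_rigid: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.repeat_probability <= 1.0:
            raise ValueError("repeat_probability must lie in [0, 1]")
        for name, (lo, hi) in (
            ("overlap_range", self.overlap_range),
            ("repeat_count_range", self.repeat_count_range),
            ("rotation_range_deg", self.rotation_range_deg),
            ("translation_range_px", self.translation_range_px),
        ):
            if hi < lo:
                raise ValueError(f"{name} must be ordered (min, max)")
        if not 0.0 < self.overlap_range[0] <= self.overlap_range[1] <= 1.0:
            raise ValueError("overlap_range must lie in (0, 1]")
        if self.repeat_count_range[0] < 1:
            raise ValueError("repeat counts must be >= 1")


@dataclasses.dataclass
class DistortionRecord:
    """Ground truth of one synthetic pair.

    correspondence
        ``(original_index, distorted_index)`` for every distorted frame,
        non-decreasing in both components.
    per_frame_transform
        Rigid perturbation applied to each distorted frame (identity
        when the rigid distortion is disabled).
    kept_range
        ``(first_kept, last_kept)`` original indices surviving the
        overlap distortion.
    """

    correspondence: list[tuple[int, int]]
    per_frame_transform: list[RigidTransform]
    kept_range: tuple[int, int]

    def __post_init__(self) -> None:
        orig = [i for i, _ in self.correspondence]
        dist = [j for _, j in self.correspondence]
        if sorted(orig) != orig or dist != list(range(len(dist))):
            raise ValueError(
                "correspondence must be monotone in original index and cover "
                "every distorted frame exactly once"
            )
        if len(self.per_frame_transform) != len(self.correspondence):
            raise ValueError("one transform per distorted frame required")

    def to_dict(self) -> dict:
        return {
            "correspondence": [list(p) for p in self.correspondence],
            "per_frame_transform": [
                [t.angle_deg, t.tx_px, t.ty_px] for t in self.per_frame_transform
            ],
            "kept_range": list(self.kept_range),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DistortionRecord":
        return cls(
            correspondence=[tuple(p) for p in data["correspondence"]],
            per_frame_transform=[
                RigidTransform(*t) for t in data["per_frame_transform"]
            ],
            kept_range=tuple(data["kept_range"]),
        )


def _smooth_series(rng: np.random.Generator, n: int, sigma: float = 3.0) -> np.ndarray:
    """Unit-variance smooth random series: Gaussian-filtered white noise.

    Smoothing over ~3 frames makes neighbouring frames similar but
    distinct, emulating the change of vessel morphology between consecutive
    gated frames (roughly 0.5-1 mm of vessel apart).
    """
    x = rng.standard_normal(n)
    if n < 3:
        return np.zeros(n)
    y = ndimage.gaussian_filter1d(x, sigma, mode="reflect")
    sd = y.std()
    return (y - y.mean()) / sd if sd > 0 else np.zeros(n)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def generate_phantom_pullback(
    n_frames: int,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    speckle_contrast: float = 0.5,
) -> Pullback:
    """Phantom pullback of vessel-like cross-sections.

    Each frame shows a dark eccentric lumen inside a bright wall
    annulus with an angularly localised plaque thickening, a bright
    calcification arc casting an acoustic shadow, a second echogenic
    nodule, a pericardium-like echogenic outer arc and, over a window
    of frames, a side-branch opening through the wall.  Longitudinal
    variation is dominated by
    rotation-invariant anatomy — lumen caliber and ellipticity, wall
    thickness, plaque burden, branch presence — which all drift
    smoothly along the pullback, while the circumferential positions of
    plaque and calcification stay nearly fixed (only a slow catheter
    twist of a few degrees), as in a gated acquisition.

    Multiplicative speckle has two parts: a persistent grain tied to the
    tissue's scatterer configuration, which evolves smoothly along the
    pullback (adjacent cross-sections of a real vessel share correlated
    speckle texture), and a smaller per-frame independent grain.  Their
    combined std/mean ratio is ``speckle_contrast``, defaulting to 0.5,
    the fully-developed-speckle value (speckle SNR about 1.91).
    Deterministic given the seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    H, W = size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    ex = 4.0 * _smooth_series(rng, n_frames)
    ey = 4.0 * _smooth_series(rng, n_frames)
    r_lumen = 15.0 + 4.5 * _smooth_series(rng, n_frames)
    ecc = 0.12 + 0.08 * _smooth_series(rng, n_frames)  # lumen ellipticity
    ecc_ang = np.deg2rad(rng.uniform(0, 360) + 8.0 * _smooth_series(rng, n_frames))
    wall_th = 9.0 + 2.5 * _smooth_series(rng, n_frames)
    plaque_amp = np.clip(6.0 + 4.0 * _smooth_series(rng, n_frames), 0.0, None)
    plaque_ang = np.deg2rad(rng.uniform(0, 360) + 8.0 * _smooth_series(rng, n_frames))
    plaque_width = 0.9 + 0.2 * _smooth_series(rng, n_frames)
    calc_ang = np.deg2rad(rng.uniform(0, 360) + 6.0 * _smooth_series(rng, n_frames))
    calc_amp = np.clip(70.0 + 45.0 * _smooth_series(rng, n_frames), 0.0, None)
    nodule_ang = np.deg2rad(rng.uniform(0, 360) + 8.0 * _smooth_series(rng, n_frames))
    nodule_amp = np.clip(40.0 + 30.0 * _smooth_series(rng, n_frames), 0.0, None)
    peri_r = 45.0 + 6.0 * _smooth_series(rng, n_frames)
    peri_ang = np.deg2rad(rng.uniform(0, 360) + 8.0 * _smooth_series(rng, n_frames))
    peri_amp = np.clip(55.0 + 30.0 * _smooth_series(rng, n_frames), 0.0, None)
    # Side branch: open only where the gating series exceeds a threshold,
    # i.e. over one or two contiguous frame windows.
    branch_amp = np.clip(_smooth_series(rng, n_frames) - 0.7, 0.0, None) / 0.3
    branch_ang = np.deg2rad(rng.uniform(0, 360) + 6.0 * _smooth_series(rng, n_frames))

    # Persistent scatterer grain: smooth over ~2.5 frames along the pullback
    # and ~1 px in-plane; plus an independent per-frame grain.  Contrasts
    # add in quadrature to speckle_contrast (4:3 persistent:independent).
    persist_c = 0.8 * speckle_contrast
    indep_c = 0.6 * speckle_contrast
    grain3d = ndimage.gaussian_filter(
        rng.standard_normal((n_frames, H, W)), (2.5, 1.0, 1.0), mode="reflect"
    )
    grain3d /= max(grain3d.std(), 1e-12)

    frames = np.empty((n_frames, H, W))
    for k in range(n_frames):
        cy = (H - 1) / 2.0 + ey[k]
        cx = (W - 1) / 2.0 + ex[k]
        r = np.hypot(xx - cx, yy - cy)
        th = np.arctan2(yy - cy, xx - cx)
        rl = r_lumen[k] * (1.0 + ecc[k] * np.cos(2.0 * (th - ecc_ang[k])))
        bump = np.exp(-(_wrap_angle(th - plaque_ang[k]) / plaque_width[k]) ** 2)
        rw = rl + wall_th[k] + plaque_amp[k] * bump
        s_lumen = 1.0 / (1.0 + np.exp(-(r - rl) / 0.8))
        s_wall = 1.0 / (1.0 + np.exp(-(r - rw) / 0.8))
        adventitia = 25.0 + 55.0 * np.exp(-np.clip(r - rw, 0.0, None) / 18.0)
        img = 15.0 * (1 - s_lumen) + 150.0 * s_lumen * (1 - s_wall) + adventitia * s_wall
        rc = rl + 0.5 * wall_th[k]
        img += calc_amp[k] * np.exp(
            -(_wrap_angle(th - calc_ang[k]) / 0.18) ** 2 - ((r - rc) / 3.0) ** 2
        )
        # Acoustic shadow cast radially outward behind the calcification.
        shadow = np.exp(-(_wrap_angle(th - calc_ang[k]) / 0.20) ** 2) * (
            1.0 / (1.0 + np.exp(-(r - (rc + 3.0)) / 1.5))
        )
        img *= 1.0 - 0.7 * (calc_amp[k] / 115.0) * shadow
        img += nodule_amp[k] * np.exp(
            -(_wrap_angle(th - nodule_ang[k]) / 0.30) ** 2
            - ((r - (rl + wall_th[k])) / 4.0) ** 2
        )
        # Pericardium-like echogenic arc outside the vessel.
        img += peri_amp[k] * np.exp(
            -(_wrap_angle(th - peri_ang[k]) / 0.55) ** 2
            - ((r - peri_r[k]) / 3.0) ** 2
        )
        if branch_amp[k] > 0:
            # The branch darkens a wedge of the wall down to lumen level.
            wedge = np.exp(-(_wrap_angle(th - branch_ang[k]) / 0.35) ** 2)
            img -= branch_amp[k] * wedge * (img - 15.0) * s_lumen * (1 - s_wall)
        grain = ndimage.gaussian_filter(rng.standard_normal((H, W)), 1.0)
        grain /= max(grain.std(), 1e-12)
        speckle = np.clip(
            1.0 + persist_c * grain3d[k] + indep_c * grain, 0.05, None
        )
        frames[k] = np.clip(img * speckle, *INTENSITY_RANGE)
    return Pullback(frames=frames, identifier=f"phantom-{seed}")


def distort_amplitude(
    pullback: Pullback, sigma: float, rng: np.random.Generator
) -> Pullback:
    """Add i.i.d. zero-mean Gaussian noise of std ``sigma`` per pixel,
    clipped to the valid intensity range."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return pullback.with_frames(pullback.frames.copy())
    noisy = pullback.frames + rng.normal(0.0, sigma, size=pullback.frames.shape)
    return pullback.with_frames(np.clip(noisy, *INTENSITY_RANGE))


def distort_overlap(
    pullback: Pullback,
    overlap_range: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[Pullback, tuple[int, int]]:
    """Keep a contiguous run of ``round(L * u)`` frames, u ~ U(overlap_range),
    splitting the discarded frames randomly between head and tail."""
    n = len(pullback)
    if n < 5:
        raise ValueError("overlap distortion needs at least 5 frames")
    u = rng.uniform(*overlap_range)
    kept = int(round(n * u))
    if kept < 1:
        raise ValueError("overlap_range implies zero kept frames")
    head = int(rng.integers(0, n - kept + 1))
    kept_range = (head, head + kept - 1)
    return (
        pullback.with_frames(pullback.frames[head : head + kept].copy()),
        kept_range,
    )


def distort_repeat(
    pullback: Pullback,
    repeat_probability: float,
    repeat_count_range: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[Pullback, list[tuple[int, int]]]:
    """Independently repeat each frame with the given probability,
    inserting 1-4 (uniform) extra consecutive copies.

    Returns the lengthened pullback and the correspondence mapping each
    output frame to its originating input index.
    """
    frames: list[np.ndarray] = []
    correspondence: list[tuple[int, int]] = []
    c_lo, c_hi = repeat_count_range
    for i, frame in enumerate(pullback.frames):
        copies = 1
        if rng.random() < repeat_probability:
            copies += int(rng.integers(c_lo, c_hi + 1))
        for _ in range(copies):
            correspondence.append((i, len(frames)))
            frames.append(frame.copy())
    return pullback.with_frames(np.stack(frames)), correspondence


def distort_rigid(
    pullback: Pullback,
    rotation_range_deg: tuple[float, float],
    translation_range_px: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[Pullback, list[RigidTransform]]:
    """Apply an independent uniform rigid perturbation to every frame."""
    transforms = []
    frames = np.empty_like(pullback.frames, dtype=float)
    for k, frame in enumerate(pullback.frames):
        t = RigidTransform(
            angle_deg=float(rng.uniform(*rotation_range_deg)),
            tx_px=float(rng.uniform(*translation_range_px)),
            ty_px=float(rng.uniform(*translation_range_px)),
        )
        frames[k] = apply_rigid(frame, t)
        transforms.append(t)
    return pullback.with_frames(frames), transforms


def make_synthetic_pair(
    base: Pullback, spec: DistortionSpec
) -> tuple[Pullback, Pullback, DistortionRecord]:
    """Build a (reference, distorted) pair with full ground truth.

    Distortions are applied in the order overlap -> repeat -> rigid ->
    amplitude: repeated copies receive independent rigid and noise
    draws, emulating re-sampling of the same cross-section at different
    catheter poses, and the additive noise is the last step on each
    emitted frame.
    """
    if len(base) < 5:
        raise ValueError("base pullback must have at least 5 frames")
    rng = np.random.default_rng(spec.seed)
    current = base.with_frames(base.frames.astype(float), suffix="-distorted")

    kept_range = (0, len(base) - 1)
    if spec.enable_overlap:
        current, kept_range = distort_overlap(current, spec.overlap_range, rng)

    correspondence = [(i, i) for i in range(len(current))]
    if spec.enable_repeat:
        current, correspondence = distort_repeat(
            current, spec.repeat_probability, spec.repeat_count_range, rng
        )

    if spec.enable_rigid:
        current, transforms = distort_rigid(
            current, spec.rotation_range_deg, spec.translation_range_px, rng
        )
    else:
        transforms = [RigidTransform() for _ in range(len(current))]

    if spec.enable_noise and spec.noise_sigma > 0:
        current = distort_amplitude(current, spec.noise_sigma, rng)

    record = DistortionRecord(
        correspondence=[(kept_range[0] + i, j) for i, j in correspondence],
        per_frame_transform=transforms,
        kept_range=kept_range,
    )
    return base, current, record
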