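"""Axial (in-plane rigid) registration of matched frame pairs.

Each matched pair is aligned by maximizing the mutual information

    MI(T(F), R) = sum_{f, r} p_FR(f, r) * log(p_FR(f, r) / (p_F(f) p_R(r)))

over rigid transforms T (rotation about the frame centre followed by a
translation), where the joint distribution p_FR is the normalized 2-D
histogram of the binned intensities of the transformed floating frame F
and the reference frame R.  The optimizer is a Harmony Search variant:
new candidates are assembled element-wise from a memory of previous
solutions, optionally pitch-adjusted by an ALOPEX-style step whose sign
is biased toward the most recent objective improvement, or drawn
uniformly from the search bounds; the memory-consideration and
pitch-adjustment rates increase linearly over the run.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .io_core import FramePairMatch, Pullback, RigidTransform

__all__ = [
    "MiConfig",
    "HarmonyConfig",
    "HarmonyState",
    "apply_rigid",
    "mutual_information",
    "alopex_perturbation",
    "harmony_init",
    "harmony_step",
    "register_axial_pair",
    "register_axial",
]


@dataclasses.dataclass(frozen=True)
class MiConfig:
    """Mutual-information estimator settings.

    n_bins
        Histogram bins per image (default 32, robust for 8-bit data).
    intensity_range
        (min, max) used for binning both images; ``None`` uses the joint
        min-max of the pair.  During optimization the range is frozen
        from the untransformed pair so all candidates share one binning.
    """

    n_bins: int = 32
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.intensity_range is not None:
            lo, hi = self.intensity_range
            if not (math.isfinite(lo) and math.isfinite(hi) and hi >= lo):
                raise ValueError("intensity_range must be an ordered finite pair")


def apply_rigid(frame: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Resample a frame under a rigid transform (rotate about centre,
    then translate), bilinear interpolation, zero fill outside.

    The identity transform returns a bit-exact copy.
    """
    frame = np.asarray(frame, dtype=float)
    if transform.is_identity:
        return frame.copy()
    H, W = frame.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    th = math.radians(transform.angle_deg)
    c, s = math.cos(th), math.sin(th)
    # Inverse map: p_in = R(-theta) @ (p_out - centre - t) + centre,
    # written in (row, col) = (y, x) order for affine_transform.
    matrix = np.array([[c, -s], [s, c]])  # rows (y_in, x_in), cols (y_out, x_out)
    tx, ty = transform.tx_px, transform.ty_px
    offset = np.array(
        [
            cy - c * (cy + ty) + s * (cx + tx),
            cx - s * (cy + ty) - c * (cx + tx),
        ]
    )
    return ndimage.affine_transform(
        frame, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )


def _bin_indices(values: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Uniform bin index per pixel, clipped into [0, n_bins - 1]."""
    if hi <= lo:
        return np.zeros(values.size, dtype=np.intp)
    idx = ((values.ravel() - lo) * (n_bins / (hi - lo))).astype(np.intp)
    return np.clip(idx, 0, n_bins - 1)


def _mi_from_joint(joint: np.ndarray) -> float:
    """MI (natural log) of a joint count/probability table; 0*log 0 = 0."""
    p = joint / joint.sum()
    pf = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (pf @ pr)[mask])))


def mutual_information(
    floating: np.ndarray,
    reference: np.ndarray,
    config: MiConfig = MiConfig(),
) -> float:
    """Mutual information of the binned intensities of two images."""
    f = np.asarray(floating, dtype=float)
    r = np.asarray(reference, dtype=float)
    if f.shape != r.shape:
        raise ValueError(f"image shapes differ: {f.shape} vs {r.shape}")
    if config.intensity_range is not None:
        lo, hi = config.intensity_range
    else:
        lo = min(f.min(), r.min())
        hi = max(f.max(), r.max())
    if hi <= lo:  # both images constant at the same value
        return 0.0
    nb = config.n_bins
    fi = _bin_indices(f, lo, hi, nb)
    ri = _bin_indices(r, lo, hi, nb)
    joint = np.bincount(fi * nb + ri, minlength=nb * nb).reshape(nb, nb).astype(float)
    return _mi_from_joint(joint)


@dataclasses.dataclass(frozen=True)
class HarmonyConfig:
    """Harmony Search settings.

    ``h`` (memory consideration) and ``p`` (pitch adjustment) advance
    linearly from their initial to their maximal values over
    ``max_iterations``; larger early randomness favours exploration,
    larger late ``h``/``p`` favours refinement of remembered solutions.
    """

    memory_size: int = 20
    h_init: float = 0.7
    h_max: float = 0.95
    p_init: float = 0.1
    p_max: float = 0.5
    max_iterations: int = 500
    bounds: tuple[tuple[float, float], ...] = ((-20.0, 20.0), (-8.0, 8.0), (-8.0, 8.0))
    seed: int = 0
    step_scale: float = 0.1
    sign_bias: float = 0.75
    temperature_decay: float = 0.99

    def __post_init__(self) -> None:
        if self.memory_size < 1:
            raise ValueError("memory_size must be >= 1")
        for name, lo, hi in (("h", self.h_init, self.h_max), ("p", self.p_init, self.p_max)):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name}_init <= {name}_max must hold within [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for lo, hi in self.bounds:
            if hi < lo:
                raise ValueError("each bound must satisfy min <= max")
        if not 0.0 <= self.sign_bias <= 1.0:
            raise ValueError("sign_bias must lie in [0, 1]")


@dataclasses.dataclass
class HarmonyState:
    """Mutable optimizer state: solution memory, iteration counter,
    annealing temperature and the last two evaluated (x, J) pairs used
    by the ALOPEX step."""

    memory: list[tuple[np.ndarray, float]]
    iteration: int
    rng: np.random.Generator
    temperature: float = 1.0
    history: list[tuple[np.ndarray, float]] = dataclasses.field(default_factory=list)

    @property
    def best(self) -> tuple[np.ndarray, float]:
        return self.memory[0]

    @property
    def worst_value(self) -> float:
        return self.memory[-1][1]

    def _record(self, solution: np.ndarray, value: float) -> None:
        self.history.append((solution, value))
        del self.history[:-2]


def alopex_perturbation(
    history: Sequence[tuple[np.ndarray, float]],
    temperature: float,
    rng: np.random.Generator,
    ranges: np.ndarray,
    step_scale: float = 0.1,
    sign_bias: float = 0.75,
) -> np.ndarray:
    """Per-dimension pitch-adjustment step.

    With at least two evaluated solutions the sign of each component is
    biased (probability ``sign_bias``) toward ``sign(dx_i * dJ)`` — the
    direction that most recently improved the objective (maximization);
    the magnitude is half-normal, scaled by ``step_scale * range_i`` and
    by the annealing temperature.  Without history the step is uniform
    within +-1% of each bound range.
    """
    ranges = np.asarray(ranges, dtype=float)
    ndim = ranges.size
    if len(history) < 2:
        return rng.uniform(-0.01, 0.01, size=ndim) * ranges
    (x0, j0), (x1, j1) = history[-2], history[-1]
    bias = np.sign((x1 - x0) * (j1 - j0))
    rand_sign = rng.choice([-1.0, 1.0], size=ndim)
    take_bias = (rng.random(ndim) < sign_bias) & (bias != 0)
    sign = np.where(take_bias, bias, rand_sign)
    magnitude = np.abs(rng.standard_normal(ndim)) * step_scale * ranges * temperature
    return sign * magnitude


def _rates(iteration: int, config: HarmonyConfig) -> tuple[float, float]:
    frac = min(1.0, iteration / config.max_iterations)
    h = config.h_init + (config.h_max - config.h_init) * frac
    p = config.p_init + (config.p_max - config.p_init) * frac
    return h, p


def harmony_init(
    config: HarmonyConfig,
    objective: Callable[[np.ndarray], float],
    seeds: Sequence[np.ndarray] = (),
) -> HarmonyState:
    """Build the initial memory: supplied seed solutions first, then
    uniform draws from the bounds up to ``memory_size``."""
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    solutions = [np.asarray(s, dtype=float) for s in seeds[: config.memory_size]]
    while len(solutions) < config.memory_size:
        solutions.append(rng.uniform(lo, hi))
    memory = [(s, float(objective(s))) for s in solutions]
    memory.sort(key=lambda sv: -sv[1])
    return HarmonyState(memory=memory, iteration=0, rng=rng)


def harmony_step(
    state: HarmonyState,
    config: HarmonyConfig,
    objective: Callable[[np.ndarray], float],
) -> HarmonyState:
    """One Harmony Search iteration (maximization).

    Element-wise: with probability ``h (1 - p)`` copy element i from a
    uniformly chosen memory solution; with probability ``h p`` copy and
    perturb it by the ALOPEX step; with probability ``1 - h`` draw it
    uniformly from the bounds.  A candidate that beats the worst memory
    entry replaces it; the rates and temperature then advance.
    """
    rng = state.rng
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    ranges = hi - lo
    ndim = lo.size
    h, p = _rates(state.iteration, config)
    step = alopex_perturbation(
        state.history, state.temperature, rng, ranges,
        config.step_scale, config.sign_bias,
    )
    candidate = np.empty(ndim)
    for i in range(ndim):
        if rng.random() < h:
            k = state.memory[rng.integers(len(state.memory))][0]
            candidate[i] = k[i]
            if rng.random() < p:
                candidate[i] += step[i]
        else:
            candidate[i] = rng.uniform(lo[i], hi[i])
    candidate = np.clip(candidate, lo, hi)
    value = float(objective(candidate))
    if not math.isfinite(value):
        warnings.warn("objective returned a non-finite value; candidate rejected",
                      stacklevel=2)
    else:
        state._record(candidate, value)
        if value > state.worst_value:
            state.memory[-1] = (candidate, value)
            state.memory.sort(key=lambda sv: -sv[1])
    state.iteration += 1
    state.temperature *= config.temperature_decay
    return state


class _MiObjective:
    """MI of (transformed floating, reference) with frozen binning.

    The reference bin indices and the intensity range are precomputed
    once per pair so every candidate shares the identical estimator as
    :func:`mutual_information`.
    """

    def __init__(self, floating: np.ndarray, reference: np.ndarray, config: MiConfig):
        self.floating = np.asarray(floating, dtype=float)
        reference = np.asarray(reference, dtype=float)
        if self.floating.shape != reference.shape:
            raise ValueError("floating and reference shapes differ")
        if config.intensity_range is not None:
            lo, hi = config.intensity_range
        else:
            lo = min(self.floating.min(), reference.min())
            hi = max(self.floating.max(), reference.max())
        self.config = MiConfig(n_bins=config.n_bins, intensity_range=(lo, hi))
        self.lo, self.hi = lo, hi
        nb = config.n_bins
        self._ref_idx = _bin_indices(reference, lo, hi, nb) * nb

    def __call__(self, params: np.ndarray) -> float:
        nb = self.config.n_bins
        if self.hi <= self.lo:
            return 0.0
        moved = apply_rigid(self.floating, RigidTransform.from_params(params))
        fi = _bin_indices(moved, self.lo, self.hi, nb)
        joint = (
            np.bincount(self._ref_idx + fi, minlength=nb * nb)
            .reshape(nb, nb)
            .astype(float)
        )
        return _mi_from_joint(joint)


def register_axial_pair(
    floating: np.ndarray,
    reference: np.ndarray,
    mi_config: MiConfig = MiConfig(),
    hs_config: HarmonyConfig = HarmonyConfig(),
) -> tuple[RigidTransform, float, float]:
    """Rigid registration of one frame pair by Harmony Search over
    (angle_deg, tx_px, ty_px).

    The identity transform is always seeded into the initial memory, so
    the returned MI never falls below the unregistered MI.  Returns the
    best transform plus the MI before and after registration.
    """
    objective = _MiObjective(floating, reference, mi_config)
    identity = np.zeros(len(hs_config.bounds))
    state = harmony_init(hs_config, objective, seeds=[identity])
    mi_before = float(objective(identity))
    for _ in range(hs_config.max_iterations):
        harmony_step(state, hs_config, objective)
    best, mi_after = state.best
    return RigidTransform.from_params(best), mi_before, float(mi_after)


def register_axial(
    matches: Sequence[FramePairMatch],
    pullback_a: Pullback,
    pullback_b: Pullback,
    mi_config: MiConfig = MiConfig(),
    hs_config: HarmonyConfig = HarmonyConfig(),
    global_seed: int = 0,
) -> list[FramePairMatch]:
    """Axially register every matched pair (frame of B onto frame of A).

    Each pair gets its own RNG stream derived from
    ``(global_seed, index_a, index_b)``, so results are identical
    regardless of processing order.
    """
    out: list[FramePairMatch] = []
    for m in matches:
        seed = np.random.SeedSequence([global_seed, m.index_a, m.index_b])
        pair_cfg = dataclasses.replace(
            hs_config, seed=int(seed.generate_state(1)[0] % (2**31))
        )
        transform, mi_before, mi_after = register_axial_pair(
            pullback_b[m.index_b], pullback_a[m.index_a], mi_config, pair_cfg
        )
        out.append(
            dataclasses.replace(
                m, transform=transform, mi_before=mi_before, mi_after=mi_after
            )
        )
    return out
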