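"""Registration error metrics and the three-setting MI comparison.

Longitudinal accuracy is the alignment error: the average, over
reference correspondences (i, j), of the distance from (i, j) to the
computed warping path — the minimum |j' - j| over computed pairs with
i' = i, falling back to the Chebyshev distance to the whole path when
index i never appears in it.  Axial accuracy is the per-pair residual
of the estimated transform composed with the true perturbation:
absolute (wrapped) residual rotation, and the Euclidean norm of the
residual translation, optionally converted to millimetres when a pixel
spacing is known.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .axial import MiConfig, apply_rigid, mutual_information
from .io_core import FramePairMatch, Pullback, RigidTransform, WarpingPath

__all__ = [
    "RegistrationEvaluation",
    "alignment_error",
    "normalized_alignment_error",
    "rigid_error",
    "mi_three_settings",
]


@dataclasses.dataclass
class RegistrationEvaluation:
    """Aggregated metrics of one registered pullback pair."""

    alignment_error_frames: float
    normalized_error: float
    rotation_error_deg: tuple[float, float] | None = None
    translation_error_px: tuple[float, float] | None = None
    translation_error_mm: tuple[float, float] | None = None
    mi_unregistered: float | None = None
    mi_longitudinal: float | None = None
    mi_axial: float | None = None


def _as_pairs(path) -> np.ndarray:
    if isinstance(path, WarpingPath):
        return path.pairs
    pairs = np.asarray(list(path), dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected an (L, 2) list of index pairs")
    return pairs


def alignment_error(reference_path, computed_path) -> float:
    """Mean distance (frames) from reference correspondences to the
    computed warping path."""
    ref = _as_pairs(reference_path)
    comp = _as_pairs(computed_path)
    if ref.shape[0] == 0:
        raise ValueError("reference path must be non-empty")
    distances = np.empty(ref.shape[0])
    for k, (i, j) in enumerate(ref):
        same_i = comp[comp[:, 0] == i, 1]
        if same_i.size:
            distances[k] = np.abs(same_i - j).min()
        else:
            distances[k] = np.maximum(
                np.abs(comp[:, 0] - i), np.abs(comp[:, 1] - j)
            ).min()
    return float(distances.mean())


def normalized_alignment_error(mean_error: float, registered_length: int) -> float:
    """Mean alignment error divided by the number of registered frames."""
    if registered_length < 1:
        raise ValueError("registered_length must be >= 1")
    return float(mean_error) / registered_length


def _wrap_deg(a: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def rigid_error(
    true_transforms: Sequence[RigidTransform],
    estimated: Sequence[RigidTransform],
    spacing_mm: float | None = None,
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float] | None]:
    """Residual rotation / translation statistics of estimated vs. true.

    A perfect estimate is the inverse of the applied perturbation, so
    the residual is ``estimated o true``; per pair the rotation error is
    the absolute wrapped residual angle and the translation error the
    Euclidean norm of the residual translation.  Returns (mean, std)
    for rotation (deg), translation (px) and, when ``spacing_mm`` is
    given, translation in millimetres.
    """
    if len(true_transforms) != len(estimated):
        raise ValueError("transform lists must have equal length")
    if not true_transforms:
        raise ValueError("no transforms to compare")
    rot = np.empty(len(estimated))
    trans = np.empty(len(estimated))
    for k, (t, e) in enumerate(zip(true_transforms, estimated)):
        residual = e.compose(t)
        rot[k] = abs(_wrap_deg(residual.angle_deg))
        trans[k] = float(np.hypot(residual.tx_px, residual.ty_px))
    rot_stats = (float(rot.mean()), float(rot.std()))
    trans_stats = (float(trans.mean()), float(trans.std()))
    mm_stats = None
    if spacing_mm is not None:
        mm_stats = (trans_stats[0] * spacing_mm, trans_stats[1] * spacing_mm)
    return rot_stats, trans_stats, mm_stats


def mi_three_settings(
    pullback_a: Pullback,
    pullback_b: Pullback,
    matches_longitudinal: Sequence[FramePairMatch],
    matches_axial: Sequence[FramePairMatch],
    mi_config: MiConfig = MiConfig(),
) -> tuple[float, float, float]:
    """Mean MI under three settings: unregistered (index-by-index over
    the common length from the first frames), after longitudinal
    matching, and after axial registration (transformed floating frames).
    """
    overlap = min(len(pullback_a), len(pullback_b))
    if overlap == 0 or not matches_longitudinal or not matches_axial:
        raise ValueError("empty overlap or empty match list")
    mi_unreg = float(
        np.mean(
            [
                mutual_information(pullback_b[k], pullback_a[k], mi_config)
                for k in range(overlap)
            ]
        )
    )
    mi_long = float(
        np.mean(
            [
                mutual_information(pullback_b[m.index_b], pullback_a[m.index_a], mi_config)
                for m in matches_longitudinal
            ]
        )
    )
    mi_ax = []
    for m in matches_axial:
        if m.transform is None:
            raise ValueError("axial matches must carry transforms")
        moved = apply_rigid(pullback_b[m.index_b], m.transform)
        mi_ax.append(mutual_information(moved, pullback_a[m.index_a], mi_config))
    return mi_unreg, mi_long, float(np.mean(mi_ax))
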