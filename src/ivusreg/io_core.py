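"""Shared domain types and pullback / result I/O.

Conventions used throughout the package
---------------------------------------
Frames are 2-D ``numpy`` arrays in row-major order with ``(row, col) =
(y, x)`` and the origin at the top-left pixel.  The rotation centre of a
frame of shape ``(H, W)`` is ``((H - 1) / 2, (W - 1) / 2)``.  Rigid
transforms rotate counter-clockwise (in the mathematical sense on the
``(x, y)`` axes) about that centre and then translate by ``(tx, ty)``
pixels, with ``x`` along columns and ``y`` along rows.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Pullback",
    "WarpingPath",
    "RigidTransform",
    "FramePairMatch",
    "DimensionMismatchError",
    "EmptyInputError",
    "read_pullback",
    "write_pullback",
    "write_registration_result",
    "read_registration_result",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


class DimensionMismatchError(ValueError):
    """Frames within a pullback (or across a pair) do not share a shape."""


class EmptyInputError(ValueError):
    """No frames found where at least one was required."""


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse a trailing channel axis by unweighted mean (RGB fallback)."""
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return arr[..., : min(arr.shape[-1], 3)].mean(axis=-1)
    if arr.ndim != 2:
        raise DimensionMismatchError(
            f"expected a 2-D grayscale frame, got shape {arr.shape}"
        )
    return arr


@dataclasses.dataclass
class Pullback:
    """An ordered stack of equally sized 2-D grayscale frames.

    Parameters
    ----------
    frames
        Array of shape ``(N, H, W)`` (or a sequence of ``(H, W)`` arrays,
        which is stacked).  Intensities must be finite and non-negative.
    pixel_spacing_mm
        Optional physical pixel size in millimetres per pixel; carried
        through the pipeline so translation errors can be reported in mm.
    identifier
        Free-form label used in logs and output file names.
    """

    frames: np.ndarray
    pixel_spacing_mm: float | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.frames, np.ndarray):
            frames = [np.asarray(f) for f in self.frames]
            if len(frames) == 0:
                raise EmptyInputError("a pullback needs at least one frame")
            shapes = {f.shape for f in frames}
            if len(shapes) != 1:
                raise DimensionMismatchError(f"mixed frame shapes: {sorted(shapes)}")
            self.frames = np.stack(frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise EmptyInputError(
                f"frames must form a non-empty (N, H, W) stack, got {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("pullback intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("pullback intensities must be non-negative")
        if self.pixel_spacing_mm is not None and not (
            math.isfinite(self.pixel_spacing_mm) and self.pixel_spacing_mm > 0
        ):
            raise ValueError("pixel_spacing_mm must be a positive finite scalar")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, index: int) -> np.ndarray:
        return self.frames[index]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def with_frames(self, frames: np.ndarray, suffix: str = "") -> "Pullback":
        """New pullback with the given frames, metadata preserved."""
        return Pullback(
            frames=frames,
            pixel_spacing_mm=self.pixel_spacing_mm,
            identifier=self.identifier + suffix,
        )


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: rotate about the frame centre, then translate.

    ``angle_deg`` is counter-clockwise on the ``(x, y)`` axes; ``tx_px``
    is the column-axis shift, ``ty_px`` the row-axis shift.
    """

    angle_deg: float = 0.0
    tx_px: float = 0.0
    ty_px: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.angle_deg, self.tx_px, self.ty_px):
            if not math.isfinite(v):
                raise ValueError("rigid transform parameters must be finite")

    @property
    def translation(self) -> np.ndarray:
        """Translation vector ``(tx, ty)`` in pixels."""
        return np.array([self.tx_px, self.ty_px], dtype=float)

    @property
    def is_identity(self) -> bool:
        return self.angle_deg == 0.0 and self.tx_px == 0.0 and self.ty_px == 0.0

    def rotation_matrix(self) -> np.ndarray:
        """2x2 rotation acting on ``(x, y)`` column vectors."""
        th = math.radians(self.angle_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` and then ``self``."""
        t = self.rotation_matrix() @ first.translation + self.translation
        return RigidTransform(self.angle_deg + first.angle_deg, float(t[0]), float(t[1]))

    def inverse(self) -> "RigidTransform":
        inv = RigidTransform(-self.angle_deg, 0.0, 0.0)
        t = -(inv.rotation_matrix() @ self.translation)
        return RigidTransform(-self.angle_deg, float(t[0]), float(t[1]))

    def as_params(self) -> np.ndarray:
        return np.array([self.angle_deg, self.tx_px, self.ty_px], dtype=float)

    @classmethod
    def from_params(cls, params: Sequence[float]) -> "RigidTransform":
        a, tx, ty = (float(v) for v in params)
        return cls(a, tx, ty)


@dataclasses.dataclass
class WarpingPath:
    """Monotone sequence of (i, j) frame-index correspondences.

    Consecutive pairs advance ``i``, ``j`` or both by exactly one
    (the standard DTW step set); both components are non-decreasing.
    """

    pairs: np.ndarray

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int)
        if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 1:
            raise ValueError("a warping path is a non-empty (L, 2) index array")
        steps = np.diff(pairs, axis=0)
        if steps.size and not (
            np.all(steps >= 0)
            and np.all(steps <= 1)
            and np.all(steps.sum(axis=1) >= 1)
        ):
            raise ValueError("warping path steps must be in {(0,1),(1,0),(1,1)}")
        if np.any(pairs < 0):
            raise ValueError("warping path indices must be non-negative")
        self.pairs = pairs

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.pairs))


@dataclasses.dataclass
class FramePairMatch:
    """One matched frame pair, optionally enriched by the axial stage."""

    index_a: int
    index_b: int
    dissimilarity: float
    transform: RigidTransform | None = None
    mi_before: float | None = None
    mi_after: float | None = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.dissimilarity <= 1 + 1e-9):
            raise ValueError("dissimilarity must lie in [0, 1]")
        self.dissimilarity = float(min(max(self.dissimilarity, 0.0), 1.0))


def read_pullback(
    path: str | Path,
    spacing_mm: float | None = None,
    identifier: str | None = None,
) -> Pullback:
    """Read a pullback from a multi-page TIFF or a directory of images.

    For a directory, lexicographic filename order defines frame order;
    multi-channel images are converted to grayscale by channel mean.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise EmptyInputError(f"no PNG/TIFF frames found in {path}")
        frames = []
        for p in files:
            if p.suffix.lower() in (".tif", ".tiff"):
                arr = tifffile.imread(p)
            else:
                arr = iio.imread(p)
            frames.append(_to_grayscale(np.asarray(arr)))
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise DimensionMismatchError(f"mixed frame sizes in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        stack = np.asarray(tifffile.imread(path))
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 4:  # pages with channels
            stack = np.stack([_to_grayscale(f) for f in stack])
    return Pullback(
        frames=stack,
        pixel_spacing_mm=spacing_mm,
        identifier=identifier if identifier is not None else path.stem,
    )


def write_pullback(pullback: Pullback, path: str | Path) -> None:
    """Write a pullback as a multi-page TIFF, one page per frame.

    Integer inputs are stored bit-exactly; floats are stored as float32.
    """
    frames = pullback.frames
    if np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float32)
    tifffile.imwrite(Path(path), frames, photometric="minisblack")


_RESULT_COLUMNS = [
    "index_a",
    "index_b",
    "dissimilarity",
    "angle_deg",
    "tx_px",
    "ty_px",
    "mi_before",
    "mi_after",
]


def write_registration_result(
    matches: Sequence[FramePairMatch],
    path: str | Path,
    config: dict | None = None,
) -> None:
    """Write matches as CSV plus a sidecar JSON with the run configuration."""
    if not matches:
        raise EmptyInputError("no matches to write")
    rows = []
    for m in matches:
        t = m.transform
        rows.append(
            {
                "index_a": m.index_a,
                "index_b": m.index_b,
                "dissimilarity": m.dissimilarity,
                "angle_deg": t.angle_deg if t is not None else np.nan,
                "tx_px": t.tx_px if t is not None else np.nan,
                "ty_px": t.ty_px if t is not None else np.nan,
                "mi_before": np.nan if m.mi_before is None else m.mi_before,
                "mi_after": np.nan if m.mi_after is None else m.mi_after,
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"config": config or {}}, indent=2, default=str))


def read_registration_result(path: str | Path) -> list[FramePairMatch]:
    """Read back a matches CSV written by :func:`write_registration_result`."""
    df = pd.read_csv(path)
    matches = []
    for row in df.itertuples(index=False):
        has_t = not (math.isnan(row.angle_deg) or math.isnan(row.tx_px) or math.isnan(row.ty_px))
        matches.append(
            FramePairMatch(
                index_a=int(row.index_a),
                index_b=int(row.index_b),
                dissimilarity=float(row.dissimilarity),
                transform=RigidTransform(row.angle_deg, row.tx_px, row.ty_px)
                if has_t
                else None,
                mi_before=None if math.isnan(row.mi_before) else float(row.mi_before),
                mi_after=None if math.isnan(row.mi_after) else float(row.mi_after),
            )
        )
    return matches
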