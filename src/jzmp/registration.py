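"""Fiducial-based 2-D similarity registration.

Microperimetry (MP) exams are anchored to the device's scanning-laser
ophthalmoscopy (SLO) fundus image, while geographic-atrophy tracings live on
the fundus-autofluorescence (FAF) image. Graders place fiducial markers at
corresponding retinal-vessel bifurcations in both frames; a least-squares
similarity transform (translation, rotation, isotropic scaling) fitted to
those pairs maps MP stimulus coordinates into the FAF frame.

Axis convention (fixed for cross-grader comparability): pixel coordinates are
(x, y) = (column, row), 0-based, origin at the top-left, y increasing
downward. Rotation is positive from +x toward +y.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateConfigurationError,
    InsufficientLandmarksError,
    InvalidInputError,
    ParseError,
)

__all__ = [
    "FiducialSet",
    "SimilarityTransform",
    "fit_similarity",
    "apply_transform",
    "invert_transform",
    "read_fiducials_csv",
    "write_fiducials_csv",
    "transform_to_json",
    "transform_from_json",
]

#: Fewer fiducial pairs than this triggers a quality warning in the CLI
#: (2 pairs are mathematically sufficient but leave no redundancy).
RECOMMENDED_MIN_PAIRS = 4


@dataclass(frozen=True)
class FiducialSet:
    """Paired landmark coordinates in two image frames, for one grader/eye.

    ``pairs`` is a sequence of ``((src_x, src_y), (dst_x, dst_y))`` tuples
    with source coordinates in the MP-SLO frame and target coordinates in
    the FAF frame, both in pixels.
    """

    pairs: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    grader_id: str = ""
    eye_id: str = ""

    def __post_init__(self) -> None:
        norm = tuple(
            (
                (float(s[0]), float(s[1])),
                (float(d[0]), float(d[1])),
            )
            for s, d in self.pairs
        )
        object.__setattr__(self, "pairs", norm)
        flat = np.asarray([c for s, d in norm for c in (*s, *d)], dtype=float)
        if flat.size and not np.all(np.isfinite(flat)):
            raise InvalidInputError(
                f"non-finite fiducial coordinates for eye={self.eye_id!r} "
                f"grader={self.grader_id!r}"
            )

    @property
    def source(self) -> np.ndarray:
        return np.asarray([s for s, _ in self.pairs], dtype=float).reshape(-1, 2)

    @property
    def target(self) -> np.ndarray:
        return np.asarray([d for _, d in self.pairs], dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SimilarityTransform:
    """Orientation-preserving 2-D similarity map ``p -> s * R(theta) p + t``.

    Attributes
    ----------
    scale:
        Isotropic scale factor ``s`` (unitless, > 0).
    rotation:
        Rotation angle ``theta`` in radians, positive from +x toward +y.
    translation:
        Pixel translation ``(t_x, t_y)`` in the target frame.
    rmse:
        Root-mean-square fit residual in target-frame pixels (0 for
        transforms constructed analytically).
    """

    scale: float
    rotation: float
    translation: tuple[float, float]
    rmse: float = 0.0

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise InvalidInputError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "translation", (float(self.translation[0]), float(self.translation[1])))

    @property
    def matrix(self) -> np.ndarray:
        """Linear part ``s * R(theta)`` as a 2x2 array (determinant +s^2)."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(scale=1.0, rotation=0.0, translation=(0.0, 0.0), rmse=0.0)


def fit_similarity(fiducials: FiducialSet) -> SimilarityTransform:
    """Fit the least-squares optimal orientation-preserving similarity.

    Uses the closed-form complex-number solution: with source points ``z``
    and target points ``w`` as complex numbers, the optimum of
    ``sum |a z + b - w|^2`` over complex ``a, b`` is
    ``a = cov(w, z*) / var(z)``, ``b = mean(w) - a mean(z)``; then
    ``s = |a|`` and ``theta = arg(a)``. Reflections cannot arise.

    Raises
    ------
    InsufficientLandmarksError
        Fewer than 2 pairs.
    DegenerateConfigurationError
        All source points coincident, or targets collapse (zero scale).
    """
    if len(fiducials) < 2:
        raise InsufficientLandmarksError(
            f"similarity fit needs >=2 fiducial pairs, got {len(fiducials)}"
        )
    src = fiducials.source
    dst = fiducials.target
    z = src[:, 0] + 1j * src[:, 1]
    w = dst[:, 0] + 1j * dst[:, 1]
    zc = z - z.mean()
    denom = float(np.sum(np.abs(zc) ** 2))
    if denom == 0.0:
        raise DegenerateConfigurationError("all source fiducials are coincident")
    a = np.sum((w - w.mean()) * np.conj(zc)) / denom
    scale = abs(a)
    if scale == 0.0:
        raise DegenerateConfigurationError(
            "target fiducials collapse to a point; scale is not identifiable"
        )
    b = w.mean() - a * z.mean()
    residuals = a * z + b - w
    rmse = float(np.sqrt(np.mean(np.abs(residuals) ** 2)))
    return SimilarityTransform(
        scale=float(scale),
        rotation=float(np.angle(a)),
        translation=(float(b.real), float(b.imag)),
        rmse=rmse,
    )


def apply_transform(
    t: SimilarityTransform, points: Sequence[Sequence[float]] | np.ndarray
) -> np.ndarray:
    """Map points (n, 2) from the source frame into the target frame.

    Output order matches input order. Raises :class:`InvalidInputError` on
    non-finite coordinates.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 2:
        raise InvalidInputError(f"expected (n, 2) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("non-finite input coordinates")
    out = pts @ t.matrix.T + np.asarray(t.translation)
    return out[0] if single else out


def invert_transform(t: SimilarityTransform) -> SimilarityTransform:
    """Exact inverse: ``s' = 1/s``, ``theta' = -theta``, ``t' = -R(-theta) t / s``.

    The inverse's ``rmse`` is the forward residual mapped into the source
    frame (``rmse / s``).
    """
    inv_scale = 1.0 / t.scale
    c, s = math.cos(-t.rotation), math.sin(-t.rotation)
    tx, ty = t.translation
    itx = -inv_scale * (c * tx - s * ty)
    ity = -inv_scale * (s * tx + c * ty)
    return SimilarityTransform(
        scale=inv_scale,
        rotation=-t.rotation,
        translation=(itx, ity),
        rmse=t.rmse * inv_scale,
    )


# ---------------------------------------------------------------------------
# I/O

_FIDUCIAL_COLUMNS = ["grader_id", "eye_id", "pair_index", "src_x", "src_y", "dst_x", "dst_y"]


def read_fiducials_csv(path: str | Path) -> list[FiducialSet]:
    """Read fiducial pairs, grouped into one :class:`FiducialSet` per
    (grader_id, eye_id), ordered by pair_index.

    CSV dialect: header ``grader_id,eye_id,pair_index,src_x,src_y,dst_x,dst_y``
    with pixel coordinates.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface a uniform parse error
        raise ParseError(f"cannot read fiducial CSV {path}: {exc}") from exc
    missing = [c for c in _FIDUCIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"fiducial CSV {path} missing columns {missing}")
    sets: list[FiducialSet] = []
    for (grader, eye), group in df.groupby(["grader_id", "eye_id"], sort=True):
        group = group.sort_values("pair_index")
        if group["pair_index"].duplicated().any():
            dup = int(group.loc[group["pair_index"].duplicated(), "pair_index"].iloc[0])
            raise ParseError(
                f"duplicate pair_index {dup} for grader={grader!r} eye={eye!r} in {path}"
            )
        pairs = tuple(
            ((row.src_x, row.src_y), (row.dst_x, row.dst_y))
            for row in group.itertuples()
        )
        sets.append(FiducialSet(pairs=pairs, grader_id=str(grader), eye_id=str(eye)))
    return sets


def write_fiducials_csv(sets: Iterable[FiducialSet], path: str | Path) -> None:
    rows = []
    for fs in sets:
        for i, (src, dst) in enumerate(fs.pairs):
            rows.append(
                {
                    "grader_id": fs.grader_id,
                    "eye_id": fs.eye_id,
                    "pair_index": i,
                    "src_x": src[0],
                    "src_y": src[1],
                    "dst_x": dst[0],
                    "dst_y": dst[1],
                }
            )
    pd.DataFrame(rows, columns=_FIDUCIAL_COLUMNS).to_csv(path, index=False)


def transform_to_json(t: SimilarityTransform) -> str:
    return json.dumps(
        {
            "scale": t.scale,
            "rotation_rad": t.rotation,
            "tx": t.translation[0],
            "ty": t.translation[1],
            "rmse": t.rmse,
        },
        sort_keys=True,
    )


def transform_from_json(text: str) -> SimilarityTransform:
    d = json.loads(text)
    return SimilarityTransform(
        scale=d["scale"],
        rotation=d["rotation_rad"],
        translation=(d["tx"], d["ty"]),
        rmse=d.get("rmse", 0.0),
    )
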