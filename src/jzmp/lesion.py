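"""Geographic-atrophy tracings and signed distances to the lesion margin.

A tracing is a set of polygonal lesion components in FAF pixel coordinates,
each an outer ring with optional hole rings (spared islands of surviving
retina). Components smaller than a minimum lesion size (default 0.05 mm^2,
inclusive) are removed before analysis. The signed Euclidean distance from a
point to the margin is negative inside atrophy and positive outside; a point
inside a hole is outside atrophy. The junctional zone is the band of fundus
within a half-width (default 250 um, inclusive) of the margin, on both sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .errors import InvalidInputError, InvalidMaskError, ParseError, UndefinedDistanceError

__all__ = [
    "GATracing",
    "SignedDistanceResult",
    "JunctionalZoneConfig",
    "filter_min_lesion_size",
    "signed_distance",
    "signed_distances",
    "zone_membership",
    "mask_to_polygons",
    "tracing_to_json",
    "tracing_from_json",
]

DEFAULT_MIN_AREA_MM2 = 0.05
DEFAULT_ZONE_HALF_WIDTH_UM = 250.0


@dataclass(frozen=True)
class JunctionalZoneConfig:
    """Junctional-zone definition: all fundus positions within
    ``half_width_um`` of the GA margin, inside and outside the atrophy."""

    half_width_um: float = DEFAULT_ZONE_HALF_WIDTH_UM
    boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.half_width_um > 0:
            raise InvalidInputError("half_width_um must be positive")


@dataclass(frozen=True)
class SignedDistanceResult:
    """Signed distance from one point to the nearest retained lesion margin.

    ``distance_um`` is negative inside atrophy, positive outside;
    ``nearest_component`` indexes the retained component whose margin is
    closest (lowest index on ties).
    """

    distance_um: float
    nearest_component: int
    in_junctional_zone: bool = False


@dataclass(frozen=True)
class GATracing:
    """GA lesion tracing: polygon components in FAF pixel coordinates.

    ``components`` are shapely polygons (outer ring plus optional holes).
    ``pixel_scale_um`` converts FAF pixels to micrometers.  ``filtered``
    records whether the minimum-lesion-size filter has been applied;
    ``empty`` flags a tracing with no retained component (downstream
    distance metrics are then undefined).
    """

    components: tuple[Polygon, ...]
    pixel_scale_um: float
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2
    filtered: bool = False

    def __post_init__(self) -> None:
        if not self.pixel_scale_um > 0:
            raise InvalidInputError("pixel_scale_um must be positive")
        comps = tuple(self.components)
        for i, poly in enumerate(comps):
            if not poly.is_valid:
                raise InvalidInputError(f"component {i} is not a simple polygon")
        object.__setattr__(self, "components", comps)

    @property
    def empty(self) -> bool:
        return len(self.components) == 0

    def component_areas_mm2(self) -> np.ndarray:
        """Component areas in mm^2 (holes subtract)."""
        scale = self.pixel_scale_um / 1000.0  # mm per px
        return np.asarray([p.area for p in self.components]) * scale**2

    def total_area_mm2(self) -> float:
        return float(self.component_areas_mm2().sum()) if self.components else 0.0


def filter_min_lesion_size(tracing: GATracing) -> GATracing:
    """Drop components with area < ``min_area_mm2`` (threshold inclusive:
    a component of exactly the minimum size is retained). An empty result is
    flagged via ``tracing.empty``, not an exception."""
    areas = tracing.component_areas_mm2() if tracing.components else np.empty(0)
    keep = tuple(
        poly
        for poly, area in zip(tracing.components, areas)
        if area >= tracing.min_area_mm2
    )
    return replace(tracing, components=keep, filtered=True)


def _require_components(tracing: GATracing) -> None:
    if tracing.empty:
        raise UndefinedDistanceError(
            "tracing has no retained lesion components; signed distance undefined"
        )


def signed_distances(
    points_faf_px: Sequence[Sequence[float]] | np.ndarray, tracing: GATracing
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized signed distance for an (n, 2) array of FAF-pixel points.

    Returns ``(distance_um, nearest_component)`` arrays. The magnitude is
    the Euclidean distance to the closest margin point over all retained
    components (outer and hole rings both count as margin); the sign is
    negative iff the point lies in the filled region of any component under
    the even-odd rule, so points inside holes are positive.
    """
    _require_components(tracing)
    pts = np.atleast_2d(np.asarray(points_faf_px, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("non-finite query coordinates")
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    boundaries = np.asarray([p.boundary for p in tracing.components], dtype=object)
    # (n, k) distances from each point to each component margin
    dist_px = shapely.distance(geoms[:, None], boundaries[None, :])
    nearest = np.argmin(dist_px, axis=1)  # lowest index wins ties
    min_dist = dist_px[np.arange(len(geoms)), nearest]
    inside = np.zeros(len(geoms), dtype=bool)
    for poly in tracing.components:
        inside |= shapely.covers(poly, geoms)
    sign = np.where(inside, -1.0, 1.0)
    return sign * min_dist * tracing.pixel_scale_um, nearest


def signed_distance(
    point_faf_px: Sequence[float],
    tracing: GATracing,
    cfg: JunctionalZoneConfig = JunctionalZoneConfig(),
) -> SignedDistanceResult:
    """Signed distance from one point, with junctional-zone membership."""
    d, idx = signed_distances(np.asarray(point_faf_px, dtype=float)[None, :], tracing)
    res = SignedDistanceResult(distance_um=float(d[0]), nearest_component=int(idx[0]))
    return replace(res, in_junctional_zone=zone_membership(res, cfg))


def zone_membership(
    d: SignedDistanceResult | float, cfg: JunctionalZoneConfig = JunctionalZoneConfig()
) -> bool:
    """True iff |distance| <= half-width (strict when boundary_inclusive=False)."""
    dist = d.distance_um if isinstance(d, SignedDistanceResult) else float(d)
    if cfg.boundary_inclusive:
        return abs(dist) <= cfg.half_width_um
    return abs(dist) < cfg.half_width_um


# ---------------------------------------------------------------------------
# Mask input

def mask_to_polygons(
    mask: np.ndarray | str | Path,
    pixel_scale_um: float,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> GATracing:
    """Convert a binary lesion mask (foreground = atrophy) to a polygon
    tracing via iso-contours at level 0.5.

    Accepts an array or a PNG path (8-bit, values 0/255). Contour rings are
    nested by containment depth: even depth -> component outer ring, odd
    depth -> hole of its immediate parent. Raises :class:`InvalidMaskError`
    for non-binary images.
    """
    from skimage import measure

    if isinstance(mask, (str, Path)):
        from PIL import Image

        arr = np.asarray(Image.open(mask).convert("L"))
    else:
        arr = np.asarray(mask)
    values = np.unique(arr)
    if not np.all(np.isin(values, [0, 1, 255])) or arr.ndim != 2:
        raise InvalidMaskError(
            f"mask must be a 2-D binary image (0/255), found values {values[:10]}"
        )
    binary = (arr > 0).astype(float)
    if binary.sum() == 0:
        return GATracing(components=(), pixel_scale_um=pixel_scale_um,
                         min_area_mm2=min_area_mm2, filtered=False)
    # pad so lesions touching the border still close
    padded = np.pad(binary, 1)
    contours = measure.find_contours(padded, 0.5)
    rings = []
    for c in contours:
        # find_contours yields (row, col); shift out the pad, convert to (x, y)
        xy = np.column_stack([c[:, 1] - 1.0, c[:, 0] - 1.0])
        if len(xy) >= 4:
            ring = Polygon(xy)
            if ring.is_valid and ring.area > 0:
                rings.append(ring)
    # nesting depth via containment of a point on each ring (contours from
    # distinct iso-lines never touch, so a vertex is strictly inside or
    # outside every other ring)
    from shapely.geometry import Point as _Point

    ring_pts = [_Point(r.exterior.coords[0]) for r in rings]
    depths = [
        sum(1 for j, other in enumerate(rings) if j != i and other.contains(ring_pts[i]))
        for i in range(len(rings))
    ]
    components = []
    for i, r in enumerate(rings):
        if depths[i] % 2 != 0:
            continue
        holes = [
            list(rings[j].exterior.coords)
            for j in range(len(rings))
            if depths[j] == depths[i] + 1 and r.contains(ring_pts[j])
        ]
        components.append(Polygon(r.exterior.coords, holes))
    return GATracing(
        components=tuple(components),
        pixel_scale_um=pixel_scale_um,
        min_area_mm2=min_area_mm2,
        filtered=False,
    )


# ---------------------------------------------------------------------------
# Polygon JSON: {"components": [{"outer": [[x,y],...], "holes": [...]}, ...],
#                "pixel_scale_um": float}

def tracing_to_json(tracing: GATracing) -> str:
    comps = []
    for poly in tracing.components:
        comps.append(
            {
                "outer": [list(c) for c in poly.exterior.coords],
                "holes": [[list(c) for c in ring.coords] for ring in poly.interiors],
            }
        )
    return json.dumps(
        {
            "components": comps,
            "pixel_scale_um": tracing.pixel_scale_um,
            "min_area_mm2": tracing.min_area_mm2,
        },
        sort_keys=True,
    )


def tracing_from_json(text: str | Path) -> GATracing:
    if isinstance(text, Path) or (isinstance(text, str) and "\n" not in text and text.endswith(".json")):
        text = Path(text).read_text()
    try:
        d = json.loads(text)
        components = tuple(
            Polygon(c["outer"], c.get("holes", [])) for c in d["components"]
        )
        return GATracing(
            components=components,
            pixel_scale_um=float(d["pixel_scale_um"]),
            min_area_mm2=float(d.get("min_area_mm2", DEFAULT_MIN_AREA_MM2)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed tracing JSON: {exc}") from exc
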