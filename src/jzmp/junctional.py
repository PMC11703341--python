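"""Per-stimulus junctional-zone analysis and per-eye endpoints.

Combines a registered MP exam with a GA tracing: every stimulus is mapped
into the FAF frame through the grader's similarity transform, given a signed
distance to the lesion margin, classified into or out of the junctional
zone, and classified as scotomatous. Per-eye endpoints are the mean
sensitivity over in-zone stimuli and the number of scotomatous points in the
zone; eyes with no in-zone stimuli report a missing mean, never zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import PairingError
from .lesion import GATracing, JunctionalZoneConfig, signed_distances, zone_membership
from .mp_exam import (
    NOT_SEEN,
    MPExam,
    ScotomaPolicy,
    UnitConventions,
    classify_scotomatous,
    deg_to_px,
)
from .registration import SimilarityTransform, apply_transform

__all__ = [
    "AnalysisConfig",
    "AnalyzedExam",
    "EyeEndpoints",
    "analyze_exam",
    "eye_endpoints",
    "stimulus_coordinate_differences",
    "write_analyzed_csv",
    "read_analyzed_csv",
]

#: Default SLO frame center (1024 x 1024 image): fixation maps here when
#: stimulus SLO positions are derived from grid degrees.
DEFAULT_SLO_CENTER_PX = (511.5, 511.5)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the per-eye analysis needs besides its inputs.

    ``not_seen_db`` is the sensitivity substituted for NOT_SEEN stimuli when
    averaging (-1 dB device-style convention; set to ``None`` to exclude
    NOT_SEEN points from means instead). The substitution used is recorded
    in every endpoint report.
    """

    zone: JunctionalZoneConfig = JunctionalZoneConfig()
    conventions: UnitConventions = UnitConventions()
    scotoma_policy: ScotomaPolicy = ScotomaPolicy()
    not_seen_db: Optional[float] = -1.0
    slo_center_px: tuple[float, float] = DEFAULT_SLO_CENTER_PX


@dataclass(frozen=True)
class AnalyzedExam:
    """One grader's fully analyzed exam.

    ``stimuli`` has one row per input stimulus with columns: stimulus_index,
    x_deg, y_deg, faf_x_px, faf_y_px, distance_um, nearest_component,
    in_zone, sensitivity_db (NaN for NOT_SEEN), not_seen, scotomatous.
    ``tracing_empty`` flags analyses against an empty (fully filtered)
    tracing: distances are then NaN and endpoints undefined.
    """

    eye_id: str
    grader_id: str
    stimuli: pd.DataFrame
    registration_rmse_px: float
    tracing_empty: bool = False


@dataclass(frozen=True)
class EyeEndpoints:
    """Junctional-zone endpoints for one eye/grader.

    ``mean_zone_sensitivity_db`` is None when no stimulus falls in the zone
    (or the tracing is empty); the denominator is the number of in-zone
    stimuli, not the grid size.
    """

    eye_id: str
    grader_id: str
    mean_zone_sensitivity_db: Optional[float]
    n_scotomatous_in_zone: int
    n_in_zone: int
    not_seen_substitution_db: Optional[float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "eye_id": self.eye_id,
                "grader_id": self.grader_id,
                "mean_zone_sensitivity_db": self.mean_zone_sensitivity_db,
                "n_scotomatous_in_zone": self.n_scotomatous_in_zone,
                "n_in_zone": self.n_in_zone,
                "not_seen_substitution_db": self.not_seen_substitution_db,
            },
            sort_keys=True,
        )


def _stimulus_slo_positions(exam: MPExam, cfg: AnalysisConfig) -> np.ndarray:
    """SLO pixel positions: recorded ones when present, otherwise derived
    from grid degrees through the SLO scale and center."""
    out = np.empty((len(exam.stimuli), 2))
    for i, s in enumerate(exam.stimuli):
        if s.position_slo_px is not None:
            out[i] = s.position_slo_px
        else:
            out[i] = deg_to_px(
                s.position_deg, cfg.conventions.slo_deg_per_px, cfg.slo_center_px
            )
    return out


def analyze_exam(
    exam: MPExam,
    transform: SimilarityTransform,
    tracing: GATracing,
    cfg: AnalysisConfig = AnalysisConfig(),
    grader_id: str = "",
) -> AnalyzedExam:
    """Transform, distance, and classify every stimulus of one exam.

    Deterministic given its inputs. With an empty tracing the distance and
    zone columns are NaN/False and ``tracing_empty`` is set, so endpoint
    undefined-ness propagates instead of raising.
    """
    slo_px = _stimulus_slo_positions(exam, cfg)
    faf_px = apply_transform(transform, slo_px)
    n = len(exam.stimuli)
    if tracing.empty:
        dist_um = np.full(n, np.nan)
        nearest = np.full(n, -1)
        in_zone = np.zeros(n, dtype=bool)
    else:
        dist_um, nearest = signed_distances(faf_px, tracing)
        in_zone = np.asarray([zone_membership(d, cfg.zone) for d in dist_um])
    rows = pd.DataFrame(
        {
            "stimulus_index": [s.index for s in exam.stimuli],
            "x_deg": [s.position_deg[0] for s in exam.stimuli],
            "y_deg": [s.position_deg[1] for s in exam.stimuli],
            "faf_x_px": faf_px[:, 0],
            "faf_y_px": faf_px[:, 1],
            "distance_um": dist_um,
            "nearest_component": nearest,
            "in_zone": in_zone,
            "sensitivity_db": [
                np.nan if s.sensitivity_db is NOT_SEEN else s.sensitivity_db
                for s in exam.stimuli
            ],
            "not_seen": [s.sensitivity_db is NOT_SEEN for s in exam.stimuli],
            "scotomatous": [
                classify_scotomatous(s.sensitivity_db, cfg.scotoma_policy)
                for s in exam.stimuli
            ],
        }
    )
    return AnalyzedExam(
        eye_id=exam.eye_id,
        grader_id=grader_id,
        stimuli=rows,
        registration_rmse_px=transform.rmse,
        tracing_empty=tracing.empty,
    )


def eye_endpoints(a: AnalyzedExam, cfg: AnalysisConfig = AnalysisConfig()) -> EyeEndpoints:
    """Mean zone sensitivity and scotomatous count over in-zone stimuli."""
    zone = a.stimuli[a.stimuli["in_zone"]]
    n_in_zone = int(len(zone))
    n_scot = int(zone["scotomatous"].sum())
    if n_in_zone == 0 or a.tracing_empty:
        mean = None
    else:
        values = zone["sensitivity_db"].to_numpy(dtype=float)
        seen = ~zone["not_seen"].to_numpy(dtype=bool)
        if cfg.not_seen_db is None:
            mean = float(values[seen].mean()) if seen.any() else None
        else:
            values = np.where(seen, values, cfg.not_seen_db)
            mean = float(values.mean())
    return EyeEndpoints(
        eye_id=a.eye_id,
        grader_id=a.grader_id,
        mean_zone_sensitivity_db=mean,
        n_scotomatous_in_zone=n_scot,
        n_in_zone=n_in_zone,
        not_seen_substitution_db=cfg.not_seen_db,
    )


def stimulus_coordinate_differences(
    a: AnalyzedExam,
    b: AnalyzedExam,
    conventions: UnitConventions = UnitConventions(),
) -> tuple[np.ndarray, float, float]:
    """Euclidean distances (um) between the two graders' transformed
    positions of each stimulus, paired by stimulus index.

    Returns ``(per_stimulus_um, mean_um, sd_um)`` (sample SD, ddof=1).
    Raises :class:`PairingError` when the stimulus sets differ.
    """
    if a.eye_id != b.eye_id:
        raise PairingError(f"exams are for different eyes: {a.eye_id!r} vs {b.eye_id!r}")
    ta = a.stimuli.set_index("stimulus_index").sort_index()
    tb = b.stimuli.set_index("stimulus_index").sort_index()
    if not ta.index.equals(tb.index):
        raise PairingError("stimulus sets differ between graders")
    delta = (
        ta[["faf_x_px", "faf_y_px"]].to_numpy() - tb[["faf_x_px", "faf_y_px"]].to_numpy()
    )
    dist_um = np.hypot(delta[:, 0], delta[:, 1]) * conventions.um_per_faf_px
    sd = float(dist_um.std(ddof=1)) if len(dist_um) > 1 else 0.0
    return dist_um, float(dist_um.mean()), sd


_ANALYZED_COLUMNS = [
    "stimulus_index", "x_deg", "y_deg", "faf_x_px", "faf_y_px",
    "distance_um", "nearest_component", "in_zone",
    "sensitivity_db", "not_seen", "scotomatous",
]


def write_analyzed_csv(a: AnalyzedExam, path: str | Path) -> None:
    df = a.stimuli[_ANALYZED_COLUMNS].copy()
    df.insert(0, "eye_id", a.eye_id)
    df.insert(1, "grader_id", a.grader_id)
    df.to_csv(path, index=False, float_format="%.10g")


def read_analyzed_csv(path: str | Path) -> AnalyzedExam:
    df = pd.read_csv(path)
    eye = str(df["eye_id"].iloc[0])
    grader = str(df["grader_id"].iloc[0]) if df["grader_id"].notna().any() else ""
    return AnalyzedExam(
        eye_id=eye,
        grader_id=grader,
        stimuli=df[_ANALYZED_COLUMNS].copy(),
        registration_rmse_px=float("nan"),
        tracing_empty=bool(df["distance_um"].isna().all()),
    )
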