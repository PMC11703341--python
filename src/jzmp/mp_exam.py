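"""Microperimetry exams: the 10-2 stimulus grid, unit conversions, scotoma
classification, and the MP CSV dialect.

The MAIA-style exam modeled here presents Goldmann size III stimuli
(0.43 deg diameter) on a rectilinear 10-2 grid (68 points, 2 deg spacing)
centered on the fovea and records threshold sensitivity in dB on a 0-36 dB
scale. A stimulus not seen at maximal intensity is exported as "<0" and is
represented in memory by ``None`` (the NOT_SEEN sentinel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError

__all__ = [
    "NOT_SEEN",
    "SENSITIVITY_MAX_DB",
    "StimulusRecord",
    "MPExam",
    "UnitConventions",
    "ScotomaPolicy",
    "generate_grid_10_2",
    "classify_scotomatous",
    "deg_to_um",
    "um_to_deg",
    "deg_to_px",
    "px_to_deg",
    "read_mp_csv",
    "write_mp_csv",
]

#: Sentinel for a stimulus not seen at maximal intensity ("<0 dB" exports).
NOT_SEEN = None

SENSITIVITY_MIN_DB = 0.0
SENSITIVITY_MAX_DB = 36.0

#: Eccentricity cutoff reproducing the canonical 68-point 10-2 set from the
#: odd-integer lattice; any value in (9.06, 9.49) deg gives the same set.
_GRID_10_2_CUTOFF_DEG = 9.2


@dataclass(frozen=True)
class UnitConventions:
    """Conversion constants between degrees of visual angle, micrometers on
    the retina, and image pixels.

    ``um_per_degree`` defaults to 288 um/deg, the emmetropic schematic-eye
    approximation; axial-length-individualized scaling can be supplied
    instead. FAF default: a 30 x 30 deg field sampled at 768 x 768 px.
    SLO default: a 36 x 36 deg field at 1024 x 1024 px (MAIA-style).
    """

    um_per_degree: float = 288.0
    faf_deg_per_px: float = 30.0 / 768.0
    slo_deg_per_px: float = 36.0 / 1024.0

    def __post_init__(self) -> None:
        for name in ("um_per_degree", "faf_deg_per_px", "slo_deg_per_px"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")

    @property
    def um_per_faf_px(self) -> float:
        """Micrometers per FAF pixel (11.25 um/px under defaults)."""
        return self.faf_deg_per_px * self.um_per_degree

    @property
    def um_per_slo_px(self) -> float:
        return self.slo_deg_per_px * self.um_per_degree


@dataclass(frozen=True)
class ScotomaPolicy:
    """Rule deciding whether a sensitivity value is scotomatous.

    Default (``threshold_db=None``): scotomatous iff the stimulus was not
    seen at maximal intensity (the device's "<0 dB" convention). Setting
    ``threshold_db`` instead classifies values strictly below the threshold
    (deep-scotoma variants such as "<10 dB"); NOT_SEEN always qualifies.
    """

    threshold_db: Optional[float] = None

    @property
    def label(self) -> str:
        return "not_seen" if self.threshold_db is None else f"<{self.threshold_db:g}dB"


def classify_scotomatous(
    sensitivity_db: Optional[float], policy: ScotomaPolicy = ScotomaPolicy()
) -> bool:
    """Classify one sensitivity value under the given policy."""
    if sensitivity_db is NOT_SEEN:
        return True
    s = float(sensitivity_db)
    if not (SENSITIVITY_MIN_DB <= s <= SENSITIVITY_MAX_DB):
        raise InvalidInputError(
            f"sensitivity {s} dB outside device range "
            f"[{SENSITIVITY_MIN_DB}, {SENSITIVITY_MAX_DB}]"
        )
    if policy.threshold_db is None:
        return False
    return s < policy.threshold_db


@dataclass(frozen=True)
class StimulusRecord:
    """One MP stimulus: grid position (deg relative to fixation), optional
    SLO pixel position, and measured threshold sensitivity."""

    index: int
    position_deg: tuple[float, float]
    sensitivity_db: Optional[float] = NOT_SEEN
    position_slo_px: Optional[tuple[float, float]] = None
    scotomatous: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.sensitivity_db is not NOT_SEEN:
            s = float(self.sensitivity_db)
            if not (SENSITIVITY_MIN_DB <= s <= SENSITIVITY_MAX_DB):
                raise InvalidInputError(
                    f"stimulus {self.index}: sensitivity {s} dB out of range"
                )


@dataclass(frozen=True)
class MPExam:
    """A complete MP exam for one eye."""

    eye_id: str
    stimuli: tuple[StimulusRecord, ...]
    grid_name: str = "10-2"
    stimulus_diameter_deg: float = 0.43

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        idx = [s.index for s in self.stimuli]
        if len(set(idx)) != len(idx):
            raise InvalidInputError(f"duplicate stimulus indices in exam {self.eye_id!r}")
        if self.grid_name == "10-2" and len(self.stimuli) != 68:
            raise InvalidInputError(
                f"10-2 exam {self.eye_id!r} must have 68 stimuli, got {len(self.stimuli)}"
            )

    def positions_deg(self) -> np.ndarray:
        return np.asarray([s.position_deg for s in self.stimuli], dtype=float)

    def sensitivities(self) -> list[Optional[float]]:
        return [s.sensitivity_db for s in self.stimuli]


def generate_grid_10_2() -> list[tuple[float, float]]:
    """The 68-point rectilinear 10-2 grid.

    Lattice points with x, y in {+-1, +-3, +-5, +-7, +-9} deg are retained
    when their eccentricity is <= 9.2 deg. The result is deterministic,
    sorted by (y, x), and 4-fold symmetric.
    """
    coords = [c for c in range(-9, 10, 2)]
    pts = [
        (float(x), float(y))
        for y in coords
        for x in coords
        if math.hypot(x, y) <= _GRID_10_2_CUTOFF_DEG
    ]
    return pts


def deg_to_um(p_deg: Sequence[float] | np.ndarray, conv: UnitConventions = UnitConventions()) -> np.ndarray:
    """Degrees of visual angle to micrometers on the retina (linear)."""
    return np.asarray(p_deg, dtype=float) * conv.um_per_degree


def um_to_deg(p_um: Sequence[float] | np.ndarray, conv: UnitConventions = UnitConventions()) -> np.ndarray:
    return np.asarray(p_um, dtype=float) / conv.um_per_degree


def deg_to_px(
    p_deg: Sequence[float] | np.ndarray,
    deg_per_px: float,
    center_px: Sequence[float],
) -> np.ndarray:
    """Field position (deg relative to fixation) to image pixels.

    The fixation point maps to ``center_px``; +x field is +x (rightward)
    pixels and +y field is +y (downward) pixels, consistent with the
    package-wide image axis convention.
    """
    return np.asarray(center_px, dtype=float) + np.asarray(p_deg, dtype=float) / deg_per_px


def px_to_deg(
    p_px: Sequence[float] | np.ndarray,
    deg_per_px: float,
    center_px: Sequence[float],
) -> np.ndarray:
    return (np.asarray(p_px, dtype=float) - np.asarray(center_px, dtype=float)) * deg_per_px


# ---------------------------------------------------------------------------
# MP CSV dialect: header eye_id,stimulus_index,x_deg,y_deg,sensitivity_db
# sensitivity "<0" denotes NOT_SEEN; UTF-8; comma-separated.

_MP_COLUMNS = ["eye_id", "stimulus_index", "x_deg", "y_deg", "sensitivity_db"]


def _parse_sensitivity(raw: object, row: int, path: object) -> Optional[float]:
    text = str(raw).strip()
    if text == "<0":
        return NOT_SEEN
    try:
        value = float(text)
    except ValueError as exc:
        raise ParseError(f"{path} row {row}: bad sensitivity {text!r}") from exc
    if not (SENSITIVITY_MIN_DB <= value <= SENSITIVITY_MAX_DB):
        raise ParseError(f"{path} row {row}: sensitivity {value} dB out of range")
    return value


def read_mp_csv(path: str | Path) -> MPExam:
    """Read one exam; raises :class:`ParseError` naming the offending row."""
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot read MP CSV {path}: {exc}") from exc
    missing = [c for c in _MP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"MP CSV {path} missing columns {missing}")
    eyes = df["eye_id"].unique()
    if len(eyes) != 1:
        raise ParseError(f"MP CSV {path} must contain exactly one eye, got {list(eyes)}")
    stimuli = []
    seen: set[int] = set()
    for i, row in enumerate(df.itertuples(), start=2):  # row 1 is the header
        try:
            idx = int(row.stimulus_index)
            x, y = float(row.x_deg), float(row.y_deg)
        except ValueError as exc:
            raise ParseError(f"{path} row {i}: malformed numeric field") from exc
        if idx in seen:
            raise ParseError(f"{path} row {i}: duplicate stimulus_index {idx}")
        seen.add(idx)
        sens = _parse_sensitivity(row.sensitivity_db, i, path)
        stimuli.append(
            StimulusRecord(index=idx, position_deg=(x, y), sensitivity_db=sens)
        )
    grid_name = "10-2" if len(stimuli) == 68 else "custom"
    return MPExam(eye_id=str(eyes[0]), stimuli=tuple(stimuli), grid_name=grid_name)


def write_mp_csv(exam: MPExam, path: str | Path) -> None:
    """Write an exam; ``read_mp_csv(write_mp_csv(e)) == e`` on valid exams."""
    rows = []
    for s in exam.stimuli:
        sens = "<0" if s.sensitivity_db is NOT_SEEN else f"{s.sensitivity_db:g}"
        rows.append(
            {
                "eye_id": exam.eye_id,
                "stimulus_index": s.index,
                "x_deg": f"{s.position_deg[0]:g}",
                "y_deg": f"{s.position_deg[1]:g}",
                "sensitivity_db": sens,
            }
        )
    pd.DataFrame(rows, columns=_MP_COLUMNS).to_csv(path, index=False)
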