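"""Synthetic two-grader studies with known ground truth.

Real junctional-zone repeatability studies need clinical MP exams, FAF
tracings and two human graders; none of that ships with the package.  This
module generates the whole study instead: smooth uni-/multifocal lesion
outlines (radial-Fourier-perturbed closed curves), a sensitivity field that
degrades logistically across the lesion margin, and two simulated graders
whose fiducial placements differ from the true landmark positions by iid
Gaussian jitter in both image frames.  Because the generating transform,
lesion and sensitivities are known exactly, pipeline outputs can be checked
against ground truth and the repeatability statistics against closed forms.

All randomness flows from ``numpy.random.default_rng`` seeded by
``(seed, eye_index)``, so each eye is reproducible in isolation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from shapely.geometry import Polygon
from shapely import affinity

from .errors import InvalidInputError
from .lesion import DEFAULT_MIN_AREA_MM2, GATracing, signed_distances
from .mp_exam import (
    NOT_SEEN,
    MPExam,
    SENSITIVITY_MAX_DB,
    StimulusRecord,
    UnitConventions,
    deg_to_px,
    generate_grid_10_2,
)
from .registration import FiducialSet, SimilarityTransform, apply_transform

__all__ = [
    "LesionParams",
    "SensitivityParams",
    "GraderParams",
    "SyntheticStudyConfig",
    "SyntheticEye",
    "SyntheticStudy",
    "make_lesion",
    "make_sensitivity",
    "simulate_two_grader_study",
    "coordinate_jitter_pair",
    "write_study",
    "read_study",
]

FAF_CENTER_PX = (383.5, 383.5)  # fovea at the center of the 768 x 768 FAF
SLO_CENTER_PX = (511.5, 511.5)  # fixation at the center of the 1024 x 1024 SLO


@dataclass(frozen=True)
class LesionParams:
    """Lesion-shape generator settings.

    ``mean_area_mm2`` is the geometric mean of the lognormal total-area
    distribution (8 mm^2, a mid-sized GA lesion whose margin crosses the
    central 10 degrees); ``area_sigma_log`` its log-SD. ``irregularity``
    scales the radial Fourier perturbation amplitudes. ``p_two_foci`` is
    the probability a lesion is bifocal rather than unifocal.
    """

    mean_area_mm2: float = 8.0
    area_sigma_log: float = 0.4
    irregularity: float = 0.15
    p_two_foci: float = 0.2


@dataclass(frozen=True)
class SensitivityParams:
    """Logistic sensitivity field across the margin.

    S(d) = floor + (healthy - floor) * logistic(d / tau) + Gaussian noise,
    d the signed margin distance in um (positive outside atrophy). Negative
    draws become NOT_SEEN; the rest are clipped to the device ceiling.
    """

    healthy_db: float = 27.0
    floor_db: float = -10.0
    tau_um: float = 100.0
    noise_sd_db: float = 1.5


@dataclass(frozen=True)
class GraderParams:
    """Simulated grader behaviour: how many vessel-bifurcation fiducials
    are placed and the per-axis Gaussian placement jitter (pixels of each
    frame). 1.5 px approximates careful manual clicking."""

    n_fiducials: int = 4
    jitter_sd_px: float = 1.5


@dataclass(frozen=True)
class SyntheticStudyConfig:
    n_eyes: int = 30
    seed: int = 0
    lesion: LesionParams = LesionParams()
    sensitivity: SensitivityParams = SensitivityParams()
    grader: GraderParams = GraderParams()
    conventions: UnitConventions = UnitConventions()

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise InvalidInputError("n_eyes must be >= 1")
        if self.grader.jitter_sd_px < 0 or self.sensitivity.noise_sd_db < 0:
            raise InvalidInputError("jitter/noise SDs must be >= 0")


@dataclass(frozen=True)
class SyntheticEye:
    eye_id: str
    tracing: GATracing
    exam: MPExam
    true_transform: SimilarityTransform
    fiducials: dict[str, FiducialSet]  # grader label -> jittered set
    true_fiducials_slo: np.ndarray
    true_fiducials_faf: np.ndarray


@dataclass(frozen=True)
class SyntheticStudy:
    config: SyntheticStudyConfig
    eyes: tuple[SyntheticEye, ...]


# ---------------------------------------------------------------------------
# Lesion outlines


def _fourier_ring(
    rng: np.random.Generator,
    r0_px: float,
    irregularity: float,
    center_px: tuple[float, float],
    n_vertices: int = 256,
    harmonics: range = range(2, 7),
) -> Polygon:
    """One radial-Fourier-perturbed closed curve.

    r(phi) = r0 (1 + sum_k a_k cos(k phi + phi_k)) with a_k drawn Gaussian
    at amplitude irregularity/k. If the curve self-intersects the amplitude
    is damped and the perturbation redrawn."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    amp = irregularity
    for _attempt in range(20):
        r = np.full_like(phi, 1.0)
        for k in harmonics:
            a_k = rng.normal(0.0, amp / k)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            r += a_k * np.cos(k * phi + phase)
        r = r0_px * r
        if np.all(r > 0):
            poly = Polygon(
                np.column_stack(
                    [center_px[0] + r * np.cos(phi), center_px[1] + r * np.sin(phi)]
                )
            )
            if poly.is_valid:
                return poly
        amp *= 0.5
        warnings.warn("lesion outline self-intersected; damping irregularity")
    raise InvalidInputError("could not generate a simple lesion outline")


def make_lesion(
    rng: np.random.Generator,
    area_mm2: float,
    irregularity: float = 0.15,
    n_foci: int = 1,
    pixel_scale_um: float = UnitConventions().um_per_faf_px,
    center_px: tuple[float, float] = FAF_CENTER_PX,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> GATracing:
    """Generate a uni- or multifocal lesion tracing of the given total area.

    Each focus is rescaled about its centroid so the total area matches
    ``area_mm2`` exactly; foci are disjoint by construction (re-placed on
    overlap)."""
    if area_mm2 <= 0:
        raise InvalidInputError("lesion area must be positive")
    px_per_mm = 1000.0 / pixel_scale_um
    fractions = [1.0] if n_foci == 1 else [0.65, 0.35][:n_foci]
    if n_foci > 2:
        fractions = list(np.full(n_foci, 1.0 / n_foci))
    polys: list[Polygon] = []
    for i, frac in enumerate(fractions):
        target_px2 = area_mm2 * frac * px_per_mm**2
        r0 = math.sqrt(target_px2 / math.pi)
        if i == 0:
            c = center_px
        else:
            # place satellite foci clear of earlier ones
            for _ in range(50):
                ang = rng.uniform(0.0, 2.0 * np.pi)
                sep = (polys[0].bounds[2] - polys[0].bounds[0]) / 2 + 2.2 * r0
                c = (center_px[0] + sep * math.cos(ang), center_px[1] + sep * math.sin(ang))
                candidate = _fourier_ring(rng, r0, irregularity, c)
                if all(not candidate.intersects(p) for p in polys):
                    break
            else:
                raise InvalidInputError("could not place disjoint lesion focus")
            poly = candidate
            poly = affinity.scale(poly, *(math.sqrt(target_px2 / poly.area),) * 2, origin="centroid")
            polys.append(poly)
            continue
        poly = _fourier_ring(rng, r0, irregularity, c)
        poly = affinity.scale(poly, *(math.sqrt(target_px2 / poly.area),) * 2, origin="centroid")
        polys.append(poly)
    return GATracing(
        components=tuple(polys),
        pixel_scale_um=pixel_scale_um,
        min_area_mm2=min_area_mm2,
        filtered=False,
    )


# ---------------------------------------------------------------------------
# Sensitivity field


def make_sensitivity(
    distances_um: np.ndarray,
    params: SensitivityParams = SensitivityParams(),
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Sensitivities for stimuli at the given signed margin distances.

    Returns a list mixing floats and NOT_SEEN (draws below 0 dB)."""
    from scipy.special import expit

    d = np.asarray(distances_um, dtype=float)
    mean = params.floor_db + (params.healthy_db - params.floor_db) * expit(d / params.tau_um)
    noise = 0.0 if rng is None else rng.normal(0.0, params.noise_sd_db, size=d.shape)
    raw = mean + noise
    return [
        NOT_SEEN if v < 0.0 else float(min(v, SENSITIVITY_MAX_DB)) for v in raw
    ]


# ---------------------------------------------------------------------------
# Study assembly


def _true_transform(rng: np.random.Generator, conv: UnitConventions) -> SimilarityTransform:
    """Ground-truth SLO->FAF map: nominal scale ratio of the two samplings
    with a few-percent calibration wobble, a small rotation, and a
    translation keeping fixation near the FAF center."""
    nominal = conv.slo_deg_per_px / conv.faf_deg_per_px  # 0.9 under defaults
    scale = nominal * (1.0 + rng.normal(0.0, 0.02))
    theta = rng.normal(0.0, math.radians(2.0))
    c, s = math.cos(theta), math.sin(theta)
    target_center = np.asarray(FAF_CENTER_PX) + rng.normal(0.0, 5.0, size=2)
    slo_c = np.asarray(SLO_CENTER_PX)
    lin = scale * np.array([[c, -s], [s, c]])
    t = target_center - lin @ slo_c
    return SimilarityTransform(scale=scale, rotation=theta, translation=(t[0], t[1]), rmse=0.0)


def _true_fiducials(rng: np.random.Generator, n: int) -> np.ndarray:
    """Vessel-bifurcation-like landmark positions in the SLO frame: spread
    around fixation at mid-peripheral radii, angularly stratified so no
    two are coincident or clustered."""
    base = rng.uniform(0.0, 2.0 * np.pi)
    angles = base + np.arange(n) * (2.0 * np.pi / n) + rng.normal(0.0, 0.2, size=n)
    radii = rng.uniform(220.0, 420.0, size=n)
    return np.asarray(SLO_CENTER_PX) + np.column_stack(
        [radii * np.cos(angles), radii * np.sin(angles)]
    )


def _make_eye(cfg: SyntheticStudyConfig, eye_index: int, area_mm2: float) -> SyntheticEye:
    rng = np.random.default_rng([cfg.seed, eye_index])
    conv = cfg.conventions
    n_foci = 2 if rng.uniform() < cfg.lesion.p_two_foci else 1
    tracing = make_lesion(
        rng,
        area_mm2=area_mm2,
        irregularity=cfg.lesion.irregularity,
        n_foci=n_foci,
        pixel_scale_um=conv.um_per_faf_px,
    )
    true_t = _true_transform(rng, conv)
    src = _true_fiducials(rng, cfg.grader.n_fiducials)
    dst = apply_transform(true_t, src)

    graders: dict[str, FiducialSet] = {}
    eye_id = f"eye_{eye_index:03d}"
    for grader in ("grader1", "grader2"):
        jitter_src = rng.normal(0.0, cfg.grader.jitter_sd_px, size=src.shape)
        jitter_dst = rng.normal(0.0, cfg.grader.jitter_sd_px, size=dst.shape)
        obs_src = src + jitter_src
        obs_dst = dst + jitter_dst
        graders[grader] = FiducialSet(
            pairs=tuple(
                (tuple(s), tuple(d)) for s, d in zip(obs_src, obs_dst)
            ),
            grader_id=grader,
            eye_id=eye_id,
        )

    grid = generate_grid_10_2()
    slo_px = deg_to_px(np.asarray(grid), conv.slo_deg_per_px, SLO_CENTER_PX)
    faf_px = apply_transform(true_t, slo_px)
    dist_um, _ = signed_distances(faf_px, tracing)
    sens = make_sensitivity(dist_um, cfg.sensitivity, rng)
    stimuli = tuple(
        StimulusRecord(
            index=i,
            position_deg=grid[i],
            sensitivity_db=sens[i],
            position_slo_px=(float(slo_px[i, 0]), float(slo_px[i, 1])),
        )
        for i in range(len(grid))
    )
    exam = MPExam(eye_id=eye_id, stimuli=stimuli)
    return SyntheticEye(
        eye_id=eye_id,
        tracing=tracing,
        exam=exam,
        true_transform=true_t,
        fiducials=graders,
        true_fiducials_slo=src,
        true_fiducials_faf=dst,
    )


def simulate_two_grader_study(cfg: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate the full study.

    Eye lesion areas are a systematically stratified sample of the
    lognormal area distribution (one draw per equal-probability stratum,
    strata shuffled across eyes), emulating stratified case selection."""
    rng = np.random.default_rng([cfg.seed, 0xA11CE])
    n = cfg.n_eyes
    quantiles = (np.arange(n) + rng.uniform(0.0, 1.0, size=n)) / n
    rng.shuffle(quantiles)
    from scipy.stats import norm

    areas = cfg.lesion.mean_area_mm2 * np.exp(
        cfg.lesion.area_sigma_log * norm.ppf(quantiles)
    )
    eyes = tuple(_make_eye(cfg, i, float(areas[i])) for i in range(n))
    return SyntheticStudy(config=cfg, eyes=eyes)


def coordinate_jitter_pair(
    n_stimuli: int,
    sigma_px: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct stimulus-coordinate jitter mode: two graders' copies of the
    same stimulus positions, each perturbed by iid per-axis Gaussian jitter
    of SD ``sigma_px``.

    The difference vector is then Gaussian with per-axis SD sigma*sqrt(2),
    so the mean coordinate difference has the closed form sigma*sqrt(pi)."""
    base = rng.uniform(100.0, 668.0, size=(n_stimuli, 2))
    a = base + rng.normal(0.0, sigma_px, size=base.shape)
    b = base + rng.normal(0.0, sigma_px, size=base.shape)
    return a, b


# ---------------------------------------------------------------------------
# Study directory I/O (per-eye MP CSV, per-grader fiducial CSVs, tracing
# JSON, ground-truth JSON)


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    from .lesion import tracing_to_json
    from .mp_exam import write_mp_csv
    from .registration import transform_to_json, write_fiducials_csv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_eyes": study.config.n_eyes,
        "seed": study.config.seed,
        "eyes": [e.eye_id for e in study.eyes],
        "lesion": asdict(study.config.lesion),
        "sensitivity": asdict(study.config.sensitivity),
        "grader": asdict(study.config.grader),
        "conventions": asdict(study.config.conventions),
    }
    (out / "study.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    for eye in study.eyes:
        d = out / eye.eye_id
        d.mkdir(exist_ok=True)
        write_mp_csv(eye.exam, d / "mp.csv")
        for grader, fs in sorted(eye.fiducials.items()):
            write_fiducials_csv([fs], d / f"fiducials_{grader}.csv")
        (d / "tracing.json").write_text(tracing_to_json(eye.tracing))
        truth = {
            "true_transform": json.loads(transform_to_json(eye.true_transform)),
            "true_fiducials_slo": eye.true_fiducials_slo.tolist(),
            "true_fiducials_faf": eye.true_fiducials_faf.tolist(),
            "lesion_area_mm2": eye.tracing.total_area_mm2(),
        }
        (d / "truth.json").write_text(json.dumps(truth, sort_keys=True))
    return out


def read_study(path: str | Path) -> dict:
    """Load a study directory into plain pipeline inputs.

    Returns ``{eye_id: {"exam": MPExam, "tracing": GATracing,
    "fiducials": {grader: FiducialSet}}}`` sorted by eye id."""
    from .lesion import tracing_from_json
    from .mp_exam import read_mp_csv
    from .registration import read_fiducials_csv

    root = Path(path)
    manifest = json.loads((root / "study.json").read_text())
    out: dict = {}
    for eye_id in manifest["eyes"]:
        d = root / eye_id
        fiducials: dict[str, FiducialSet] = {}
        for f in sorted(d.glob("fiducials_*.csv")):
            grader = f.stem.removeprefix("fiducials_")
            sets = read_fiducials_csv(f)
            fiducials[grader] = sets[0]
        out[eye_id] = {
            "exam": read_mp_csv(d / "mp.csv"),
            "tracing": tracing_from_json((d / "tracing.json").read_text()),
            "fiducials": fiducials,
        }
    return out
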