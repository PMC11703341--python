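"""Inter-grader agreement statistics.

Implements the agreement toolkit for paired two-grader measurements:

* Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD of the
  paired differences, sample SD).
* Intraclass correlation, two-way random effects, absolute agreement,
  single measure — ICC(A,1) in the McGraw & Wong taxonomy — computed from
  the explicit two-way ANOVA mean squares.
* Coefficient of repeatability (CoR). Two published estimators are
  provided and labeled: ``srd_sem`` (smallest real difference,
  1.96 * sqrt(2) * SEM with SEM = SD * sqrt(1 - ICC)) and ``ba``
  (1.96 * SD of the paired differences).
* Mixed-model limits of agreement for stimulus-level differences nested in
  eyes: d_ij = mu + b_i + e_ij with random eye intercepts, fitted by REML;
  LOA = mu +/- 1.96 * sqrt(sigma_b^2 + sigma_e^2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedICCError
from .junctional import AnalyzedExam
from .mp_exam import UnitConventions

__all__ = [
    "PairedMeasurements",
    "BlandAltman",
    "MixedModelLOA",
    "RepeatabilityReport",
    "bland_altman",
    "icc_absolute_agreement",
    "icc_consistency",
    "coefficient_of_repeatability",
    "mixed_model_loa",
    "stimulus_to_margin_agreement",
    "repeatability_report",
    "validate_report",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedMeasurements:
    """One endpoint measured by two graders on the same subjects.

    ``cluster_id`` (optional) groups stimulus-level rows by eye for the
    mixed-model analysis.
    """

    subject_id: tuple
    grader1: np.ndarray
    grader2: np.ndarray
    cluster_id: Optional[tuple] = None

    def __post_init__(self) -> None:
        g1 = np.asarray(self.grader1, dtype=float)
        g2 = np.asarray(self.grader2, dtype=float)
        if len(self.subject_id) != len(g1) or len(g1) != len(g2):
            raise InsufficientDataError("subject_id/grader1/grader2 lengths differ")
        if self.cluster_id is not None and len(self.cluster_id) != len(g1):
            raise InsufficientDataError("cluster_id length differs from measurements")
        object.__setattr__(self, "subject_id", tuple(self.subject_id))
        object.__setattr__(self, "grader1", g1)
        object.__setattr__(self, "grader2", g2)
        if self.cluster_id is not None:
            object.__setattr__(self, "cluster_id", tuple(self.cluster_id))

    def __len__(self) -> int:
        return len(self.grader1)

    @property
    def differences(self) -> np.ndarray:
        """grader1 - grader2."""
        return self.grader1 - self.grader2

    def dropna(self) -> "PairedMeasurements":
        """Drop subjects where either grader's value is missing (pairwise)."""
        ok = np.isfinite(self.grader1) & np.isfinite(self.grader2)
        return PairedMeasurements(
            subject_id=tuple(s for s, k in zip(self.subject_id, ok) if k),
            grader1=self.grader1[ok],
            grader2=self.grader2[ok],
            cluster_id=None
            if self.cluster_id is None
            else tuple(c for c, k in zip(self.cluster_id, ok) if k),
        )


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within_loa: float
    n: int


@dataclass(frozen=True)
class MixedModelLOA:
    mu: float
    sigma_b: float
    sigma_e: float
    loa_low: float
    loa_high: float
    n_clusters: int
    converged: bool
    method: str = "reml_random_intercept"


def bland_altman(p: PairedMeasurements) -> BlandAltman:
    """Bias and 95% limits of agreement of grader1 - grader2."""
    if len(p) < 2:
        raise InsufficientDataError(f"Bland-Altman needs >=2 pairs, got {len(p)}")
    d = p.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    low, high = bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd
    within = float(np.mean((d >= low) & (d <= high)) * 100.0)
    return BlandAltman(bias=bias, sd_diff=sd, loa_low=low, loa_high=high,
                       pct_within_loa=within, n=len(p))


def _anova_mean_squares(p: PairedMeasurements) -> tuple[float, float, float, int, int]:
    """Two-way (subjects x raters) ANOVA mean squares for k=2 raters.

    Returns (MSR, MSC, MSE, n, k): rows (subjects), columns (raters),
    residual mean squares.
    """
    if len(p) < 3:
        raise InsufficientDataError(f"ICC needs >=3 subjects, got {len(p)}")
    x = np.column_stack([p.grader1, p.grader2])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_absolute_agreement(p: PairedMeasurements) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)).
    Raises :class:`UndefinedICCError` when the total variance is zero.
    """
    msr, msc, mse, n, k = _anova_mean_squares(p)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise UndefinedICCError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)


def icc_consistency(p: PairedMeasurements) -> float:
    """ICC(C,1): two-way mixed, consistency, single measure
    ((MSR - MSE) / (MSR + (k-1) MSE)); insensitive to a constant
    between-grader offset, provided for comparison."""
    msr, _msc, mse, _n, k = _anova_mean_squares(p)
    denom = msr + (k - 1) * mse
    if denom == 0.0:
        raise UndefinedICCError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)


def coefficient_of_repeatability(p: PairedMeasurements, method: str = "srd_sem") -> float:
    """Coefficient of repeatability / smallest real difference.

    ``srd_sem``: 1.96 * sqrt(2) * SEM, SEM = SD_all * sqrt(1 - ICC(A,1))
    with SD_all the sample SD of the pooled 2n measurements.
    ``ba``: 1.96 * SD of the paired differences.
    """
    if method == "ba":
        if len(p) < 2:
            raise InsufficientDataError("CoR(ba) needs >=2 pairs")
        return float(LOA_MULTIPLIER * p.differences.std(ddof=1))
    if method == "srd_sem":
        icc = icc_absolute_agreement(p)  # may raise UndefinedICCError
        sd_all = float(np.concatenate([p.grader1, p.grader2]).std(ddof=1))
        sem = sd_all * np.sqrt(max(0.0, 1.0 - icc))
        return float(LOA_MULTIPLIER * np.sqrt(2.0) * sem)
    raise ValueError(f"unknown CoR method {method!r}")


def mixed_model_loa(p: PairedMeasurements) -> MixedModelLOA:
    """Limits of agreement for clustered (stimulus-in-eye) differences.

    Fits d_ij = mu + b_i + e_ij (random eye intercept, REML) with
    statsmodels MixedLM; LOA = mu +/- 1.96 sqrt(sigma_b^2 + sigma_e^2),
    so eye-level systematic shifts and stimulus-level noise both widen the
    limits. With a single cluster (or no cluster labels) this degenerates
    to the naive Bland-Altman limits, returned with a warning.
    """
    import statsmodels.formula.api as smf

    d = p.differences
    if p.cluster_id is None or len(set(p.cluster_id)) < 2:
        warnings.warn("single cluster: falling back to naive Bland-Altman LOA")
        ba = bland_altman(p)
        return MixedModelLOA(
            mu=ba.bias, sigma_b=0.0, sigma_e=ba.sd_diff,
            loa_low=ba.loa_low, loa_high=ba.loa_high,
            n_clusters=1, converged=True, method="bland_altman_fallback",
        )
    if len(set(p.cluster_id)) < 3:
        raise InsufficientDataError("mixed-model LOA needs >=3 clusters")
    if np.allclose(d, d[0]):
        # Degenerate: constant differences; REML has nothing to estimate.
        return MixedModelLOA(
            mu=float(d[0]), sigma_b=0.0, sigma_e=0.0,
            loa_low=float(d[0]), loa_high=float(d[0]),
            n_clusters=len(set(p.cluster_id)), converged=True,
        )
    frame = pd.DataFrame({"d": d, "eye": list(p.cluster_id)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits (sigma_b ~ 0) warn
        model = smf.mixedlm("d ~ 1", frame, groups=frame["eye"])
        fit = model.fit(reml=True)
    if not np.isfinite(fit.params.iloc[0]):
        raise InsufficientDataError("mixed model did not converge: " + str(fit.summary()))
    mu = float(fit.params.iloc[0])
    sigma_b = float(np.sqrt(max(0.0, float(fit.cov_re.iloc[0, 0]))))
    sigma_e = float(np.sqrt(fit.scale))
    half = LOA_MULTIPLIER * np.sqrt(sigma_b**2 + sigma_e**2)
    return MixedModelLOA(
        mu=mu, sigma_b=sigma_b, sigma_e=sigma_e,
        loa_low=mu - half, loa_high=mu + half,
        n_clusters=len(set(p.cluster_id)), converged=bool(fit.converged),
    )


# ---------------------------------------------------------------------------
# Report assembly


@dataclass(frozen=True)
class RepeatabilityReport:
    """Agreement summary for one endpoint across a paired-grader study."""

    endpoint: str
    n: int
    bland_altman: BlandAltman
    icc: Optional[float]
    cor_srd_sem: Optional[float]
    cor_ba: float
    mixed_loa: Optional[MixedModelLOA] = None
    n_dropped_missing: int = 0

    def to_dict(self) -> dict:
        ba = self.bland_altman
        out = {
            "endpoint": self.endpoint,
            "n": self.n,
            "n_dropped_missing": self.n_dropped_missing,
            "bias": ba.bias,
            "sd_diff": ba.sd_diff,
            "loa": [ba.loa_low, ba.loa_high],
            "pct_within_loa": ba.pct_within_loa,
            "icc": self.icc,
            "cor": {"srd_sem": self.cor_srd_sem, "ba": self.cor_ba},
        }
        if self.mixed_loa is not None:
            m = self.mixed_loa
            out["mixed_loa"] = {
                "mu": m.mu, "sigma_b": m.sigma_b, "sigma_e": m.sigma_e,
                "low": m.loa_low, "high": m.loa_high,
                "n_clusters": m.n_clusters, "method": m.method,
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def repeatability_report(
    p: PairedMeasurements, endpoint: str, with_mixed: bool = False
) -> RepeatabilityReport:
    """Full agreement report; ICC/CoR(srd) are None when undefined
    (zero variance), which is reported rather than raised."""
    clean = p.dropna()
    n_dropped = len(p) - len(clean)
    ba = bland_altman(clean)
    try:
        icc = icc_absolute_agreement(clean)
        cor_srd = coefficient_of_repeatability(clean, "srd_sem")
    except UndefinedICCError:
        icc, cor_srd = None, None
    mixed = mixed_model_loa(clean) if with_mixed and clean.cluster_id else None
    return RepeatabilityReport(
        endpoint=endpoint,
        n=len(clean),
        bland_altman=ba,
        icc=icc,
        cor_srd_sem=cor_srd,
        cor_ba=coefficient_of_repeatability(clean, "ba"),
        mixed_loa=mixed,
        n_dropped_missing=n_dropped,
    )


def stimulus_to_margin_agreement(
    exams_a: Sequence[AnalyzedExam], exams_b: Sequence[AnalyzedExam]
) -> RepeatabilityReport:
    """Agreement of signed stimulus-to-margin distances across all stimuli.

    Exams are paired by eye, stimuli by index; all stimulus points
    contribute regardless of junctional-zone membership (68 per eye on the
    10-2 grid). Summarized with Bland-Altman plus a mixed model with eyes
    as clusters, ICC, and CoR.
    """
    by_eye_b = {e.eye_id: e for e in exams_b}
    subj, g1, g2, cluster = [], [], [], []
    for ea in exams_a:
        eb = by_eye_b[ea.eye_id]
        ta = ea.stimuli.set_index("stimulus_index").sort_index()
        tb = eb.stimuli.set_index("stimulus_index").sort_index()
        for idx in ta.index:
            subj.append(f"{ea.eye_id}:{idx}")
            g1.append(ta.loc[idx, "distance_um"])
            g2.append(tb.loc[idx, "distance_um"])
            cluster.append(ea.eye_id)
    p = PairedMeasurements(
        subject_id=tuple(subj), grader1=np.asarray(g1), grader2=np.asarray(g2),
        cluster_id=tuple(cluster),
    )
    return repeatability_report(p, endpoint="stimulus_to_margin_distance_um", with_mixed=True)


# ---------------------------------------------------------------------------
# Report schema check (kept in-package so CLI outputs are self-validating)

_REPORT_REQUIRED = {
    "endpoint": str,
    "n": int,
    "bias": (int, float),
    "sd_diff": (int, float),
    "loa": list,
    "pct_within_loa": (int, float),
    "cor": dict,
}


def validate_report(d: dict) -> None:
    """Raise ValueError unless ``d`` matches the published report schema."""
    for key, typ in _REPORT_REQUIRED.items():
        if key not in d:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(d[key], typ):
            raise ValueError(f"report key {key!r} has type {type(d[key]).__name__}")
    if len(d["loa"]) != 2 or d["loa"][0] > d["loa"][1]:
        raise ValueError("report loa must be [low, high] with low <= high")
    if not (0.0 <= d["pct_within_loa"] <= 100.0):
        raise ValueError("pct_within_loa out of [0, 100]")
    if d.get("icc") is not None and not (-1.0 <= d["icc"] <= 1.0):
        raise ValueError("icc out of [-1, 1]")
    if not {"srd_sem", "ba"} <= set(d["cor"]):
        raise ValueError("cor must carry both 'srd_sem' and 'ba' labels")
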