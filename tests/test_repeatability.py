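import math
import warnings

import numpy as np
import pandas as pd
import pytest

from jzmp.errors import InsufficientDataError, UndefinedICCError
from jzmp.junctional import AnalysisConfig, analyze_exam
from jzmp.lesion import GATracing
from jzmp.mp_exam import UnitConventions
from jzmp.registration import SimilarityTransform
from jzmp.repeatability import (
    PairedMeasurements,
    bland_altman,
    coefficient_of_repeatability,
    icc_absolute_agreement,
    icc_consistency,
    mixed_model_loa,
    repeatability_report,
    stimulus_to_margin_agreement,
    validate_report,
)

from conftest import PX_UM, circle_polygon
from _oracles import anova_icc_a1, srd_from_formula_chain


def paired(g1, g2, cluster=None):
    g1 = np.asarray(g1, float)
    return PairedMeasurements(
        subject_id=tuple(range(len(g1))),
        grader1=g1,
        grader2=np.asarray(g2, float),
        cluster_id=cluster,
    )


class TestBlandAltman:
    def test_identical_columns(self):
        ba = bland_altman(paired([1, 2, 3], [1, 2, 3]))
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_hand_arithmetic_example(self):
        ba = bland_altman(paired([1, 3, 5], [2, 3, 4]))
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(-1.96)
        assert ba.loa_high == pytest.approx(1.96)

    def test_swapping_graders_negates_bias(self, rng):
        a, b = rng.normal(10, 2, 20), rng.normal(9, 2, 20)
        f, r = bland_altman(paired(a, b)), bland_altman(paired(b, a))
        assert f.bias == pytest.approx(-r.bias)
        assert f.loa_low == pytest.approx(-r.loa_high)
        assert f.loa_high == pytest.approx(-r.loa_low)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman(paired([1.0], [2.0]))

    def test_pct_within_loa_near_95_for_gaussian(self, rng):
        d = rng.normal(0, 1, 5000)
        ba = bland_altman(paired(d, np.zeros_like(d)))
        assert ba.pct_within_loa == pytest.approx(95.0, abs=2.0)


class TestICC:
    def test_perfect_agreement(self):
        assert icc_absolute_agreement(paired([1, 5, 9], [1, 5, 9])) == pytest.approx(1.0)

    def test_matches_looped_anova_on_random_tables(self, rng):
        for _ in range(25):
            n = rng.integers(4, 12)
            g1 = rng.normal(10, 4, n)
            g2 = g1 + rng.normal(0.5, 1.0, n)
            p = paired(g1, g2)
            ours = icc_absolute_agreement(p)
            assert ours == pytest.approx(anova_icc_a1(np.column_stack([g1, g2])), abs=1e-9)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for seed in range(5):
            r = np.random.default_rng(seed)
            g1 = r.normal(20, 5, 8)
            g2 = g1 + r.normal(0, 2, 8)
            df = pd.DataFrame(
                {
                    "subject": list(range(8)) * 2,
                    "rater": ["a"] * 8 + ["b"] * 8,
                    "score": np.concatenate([g1, g2]),
                }
            )
            ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
            ref_icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
            assert icc_absolute_agreement(paired(g1, g2)) == pytest.approx(ref_icc2, abs=1e-9)

    def test_offset_lowers_absolute_agreement_below_consistency(self, rng):
        g1 = rng.normal(15, 5, 10)
        g2 = g1 + 3.0  # pure constant offset
        p = paired(g1, g2)
        assert icc_absolute_agreement(p) < icc_consistency(p)
        assert icc_consistency(p) == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedICCError):
            icc_absolute_agreement(paired([2, 2, 2], [2, 2, 2]))

    def test_invariant_to_subject_order(self, rng):
        g1, g2 = rng.normal(0, 1, 9), rng.normal(0, 1, 9)
        perm = rng.permutation(9)
        assert icc_absolute_agreement(paired(g1, g2)) == pytest.approx(
            icc_absolute_agreement(paired(g1[perm], g2[perm])), abs=1e-12
        )


class TestCoR:
    def test_identical_columns_zero_under_both_methods(self):
        p = paired([1, 5, 9], [1, 5, 9])
        assert coefficient_of_repeatability(p, "srd_sem") == pytest.approx(0.0)
        assert coefficient_of_repeatability(p, "ba") == pytest.approx(0.0)

    def test_srd_matches_formula_chain(self, rng):
        for _ in range(10):
            n = rng.integers(4, 10)
            g1 = rng.normal(10, 4, n)
            g2 = g1 + rng.normal(0.3, 1.2, n)
            ours = coefficient_of_repeatability(paired(g1, g2), "srd_sem")
            assert ours == pytest.approx(
                srd_from_formula_chain(np.column_stack([g1, g2])), abs=1e-9
            )

    def test_homogeneity_under_scaling(self, rng):
        g1 = rng.normal(10, 4, 8)
        g2 = g1 + rng.normal(0, 1, 8)
        for method in ("srd_sem", "ba"):
            base = coefficient_of_repeatability(paired(g1, g2), method)
            scaled = coefficient_of_repeatability(paired(3.5 * g1, 3.5 * g2), method)
            assert scaled == pytest.approx(3.5 * base, rel=1e-9)

    def test_ba_method_available_when_icc_undefined(self):
        p = paired([2, 2, 2], [2, 2, 2])
        with pytest.raises(UndefinedICCError):
            coefficient_of_repeatability(p, "srd_sem")
        assert coefficient_of_repeatability(p, "ba") == 0.0


class TestMixedModelLOA:
    def test_all_zero_differences(self):
        p = paired(np.ones(30), np.ones(30), cluster=tuple(np.repeat(range(5), 6)))
        m = mixed_model_loa(p)
        assert m.mu == 0.0 and m.sigma_b == 0.0 and m.sigma_e == 0.0
        assert m.loa_low == 0.0 and m.loa_high == 0.0

    def test_recovers_generating_parameters(self):
        mu, sb, se, n_eyes, n_st = -3.0, 30.0, 40.0, 50, 68
        rng = np.random.default_rng(11)
        b = rng.normal(0, sb, n_eyes)
        d = mu + np.repeat(b, n_st) + rng.normal(0, se, n_eyes * n_st)
        p = paired(d, np.zeros_like(d), cluster=tuple(np.repeat(range(n_eyes), n_st)))
        m = mixed_model_loa(p)
        se_mu = math.sqrt(sb**2 / n_eyes + se**2 / (n_eyes * n_st))
        assert abs(m.mu - mu) < 3 * se_mu
        assert abs(m.sigma_b - sb) < 3 * sb / math.sqrt(2 * (n_eyes - 1))
        assert abs(m.sigma_e - se) < 3 * se / math.sqrt(2 * n_eyes * (n_st - 1))

    def test_degenerate_limit_matches_naive_loa(self):
        """With no eye-level variance the mixed LOA converge to Bland-Altman."""
        rng = np.random.default_rng(3)
        d = rng.normal(-1.0, 5.0, 40 * 30)
        p = paired(d, np.zeros_like(d), cluster=tuple(np.repeat(range(40), 30)))
        m = mixed_model_loa(p)
        ba = bland_altman(p)
        assert m.mu == pytest.approx(ba.bias, abs=0.3)
        assert m.loa_low == pytest.approx(ba.loa_low, abs=1.0)
        assert m.loa_high == pytest.approx(ba.loa_high, abs=1.0)

    def test_single_cluster_falls_back_with_warning(self):
        p = paired([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], cluster=("e1", "e1", "e1"))
        with pytest.warns(UserWarning, match="single cluster"):
            m = mixed_model_loa(p)
        assert m.method == "bland_altman_fallback"


class TestStimulusToMarginAgreement:
    def make_exams(self, transform, eye_ids):
        from jzmp.junctional import AnalysisConfig
        from jzmp.mp_exam import UnitConventions

        conv = UnitConventions(slo_deg_per_px=30.0 / 768.0)
        cfg = AnalysisConfig(conventions=conv, slo_center_px=(383.5, 383.5))
        lesion = circle_polygon((383.5, 383.5), 80.0)
        tr = GATracing(components=(lesion,), pixel_scale_um=PX_UM, filtered=True)
        from test_junctional_metrics import grid_exam

        return [
            analyze_exam(grid_exam(eye_id=e), transform, tr, cfg) for e in eye_ids
        ]

    def test_identical_registrations_graceful(self):
        eyes = [f"eye_{i}" for i in range(4)]
        a = self.make_exams(SimilarityTransform.identity(), eyes)
        b = self.make_exams(SimilarityTransform.identity(), eyes)
        rep = stimulus_to_margin_agreement(a, b)
        assert rep.bland_altman.bias == 0.0
        assert rep.bland_altman.sd_diff == 0.0
        # zero disagreement with positive between-stimulus variance: ICC is
        # exactly 1 and both repeatability coefficients vanish
        assert rep.icc == pytest.approx(1.0)
        assert rep.cor_srd_sem == pytest.approx(0.0, abs=1e-3)
        assert rep.cor_ba == 0.0

    def test_translation_bound_on_circular_lesion(self):
        """For a pure FAF translation the per-stimulus distance change is
        bounded by the shift magnitude, attained where the margin normal
        aligns with the shift."""
        eyes = ["eye_0"]
        shift_px = 4.0
        a = self.make_exams(SimilarityTransform.identity(), eyes)
        b = self.make_exams(
            SimilarityTransform(scale=1.0, rotation=0.0, translation=(shift_px, 0.0)), eyes
        )
        diffs = (
            a[0].stimuli.distance_um.to_numpy() - b[0].stimuli.distance_um.to_numpy()
        )
        bound = shift_px * PX_UM
        assert np.all(np.abs(diffs) <= bound + 1e-6)
        assert np.max(np.abs(diffs)) > 0.8 * bound

    def test_report_fields_populated_for_synthetic_study(self):
        from jzmp.cli import compare_graders_study
        from jzmp.junctional import AnalysisConfig
        from jzmp.synthetic import SyntheticStudyConfig, simulate_two_grader_study, write_study
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as d:
            study = simulate_two_grader_study(SyntheticStudyConfig(n_eyes=8, seed=42))
            write_study(study, Path(d) / "s")
            res = compare_graders_study(Path(d) / "s", AnalysisConfig())
        rep = res["reports"]["stimulus_to_margin_distance_um"]
        d = rep.to_dict()
        validate_report(d)
        assert d["n"] == 8 * 68
        assert np.isfinite([d["bias"], d["sd_diff"], d["icc"]]).all()
        assert rep.mixed_loa is not None and rep.mixed_loa.n_clusters == 8


class TestReportSchema:
    def test_validate_report_happy_and_sad(self, rng):
        g1 = rng.normal(20, 5, 10)
        g2 = g1 + rng.normal(0, 1, 10)
        rep = repeatability_report(paired(g1, g2), "demo").to_dict()
        validate_report(rep)
        bad = dict(rep)
        bad["loa"] = [1.0, -1.0]
        with pytest.raises(ValueError):
            validate_report(bad)
        del rep["cor"]
        with pytest.raises(ValueError):
            validate_report(rep)

    def test_missing_endpoints_dropped_pairwise(self, rng):
        g1 = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        g2 = np.array([1.1, 2.1, 3.0, np.nan, 5.2])
        rep = repeatability_report(paired(g1, g2), "demo")
        assert rep.n == 3 and rep.n_dropped_missing == 2
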