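"""AUROC, Pearson correlation and the patient-cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ropzone import (
    auroc,
    auroc_stat,
    cluster_bootstrap,
    compare_predictors,
    generate_cohort,
    group_difference,
    mean_stat,
    one_eye_per_patient,
    pearson_correlation,
)
from ropzone.cohort import validate_cohort
from ropzone.errors import AnalysisError, FormatError, UndefinedStatisticError


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expect",
        [
            ([0.9, 0.8, 0.7, 0.6, 0.4], [1, 1, 1, 0, 0], 1.0),
            ([0.9, 0.4, 0.5, 0.3], [1, 1, 0, 0], 0.75),
            ([0.5, 0.5], [1, 0], 0.5),
        ],
    )
    def test_examples(self, scores, labels, expect):
        assert auroc(scores, labels) == expect

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            auroc([1.0, 2.0], [1, 1])

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=30),
           st.lists(st.integers(0, 1), min_size=4, max_size=30))
    def test_monotone_transform_invariance_and_complement(self, scores, labels):
        n = min(len(scores), len(labels))
        # limit resolution so the float transform stays strictly monotone
        scores, labels = np.round(scores[:n], 3), np.array(labels[:n])
        if labels.min() == labels.max():
            return
        a = auroc(scores, labels)
        assert auroc(np.exp(scores) + 3, labels) == pytest.approx(a, abs=1e-12)
        assert auroc(scores, 1 - labels) == pytest.approx(1 - a, abs=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 9.0])
        y = np.array([0.3, -1.0, 2.0, 5.0, 4.0])
        expect = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert pearson_correlation(x, y) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(AnalysisError):
            pearson_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])

    def test_cohort_mean_vs_min_ral_strongly_correlated(self):
        df = one_eye_per_patient(generate_cohort(300, seed=8), seed=1)
        r = pearson_correlation(df.mean_ral_mm, df.min_ral_mm)
        assert r > 0.9


class TestClusterBootstrap:
    def test_constant_statistic_collapses_ci(self):
        df = generate_cohort(30, seed=0).assign(const=3.25)
        res = cluster_bootstrap(df, mean_stat("const"), n_reps=100, seed=1)
        assert res.point_estimate == res.ci_low == res.ci_high == 3.25

    def test_fixed_seed_bit_reproducible(self):
        df = generate_cohort(40, seed=2)
        a = cluster_bootstrap(df, auroc_stat("mean_ral_mm", "treated"), n_reps=150, seed=9)
        b = cluster_bootstrap(df, auroc_stat("mean_ral_mm", "treated"), n_reps=150, seed=9)
        assert a == b

    def test_ci_brackets_estimate_and_is_ordered(self):
        df = generate_cohort(60, seed=3)
        res = cluster_bootstrap(df, mean_stat("mean_ral_mm"), n_reps=300, seed=4)
        assert res.ci_low <= res.point_estimate <= res.ci_high
        assert res.n_replicates == 300 and res.n_clusters == 60

    def test_single_eye_reduces_to_iid_bootstrap(self):
        # with one eye per patient the cluster draw IS a row draw; replaying
        # the same spawned streams by hand must give identical replicates
        df = one_eye_per_patient(generate_cohort(35, seed=5), seed=0)
        res = cluster_bootstrap(df, mean_stat("mean_ral_mm"), n_reps=100, seed=6)
        vals = df.mean_ral_mm.to_numpy()
        streams = np.random.SeedSequence(6).spawn(100)
        reps = np.array([
            vals[np.random.default_rng(s).integers(0, len(vals), len(vals))].mean()
            for s in streams
        ])
        lo, hi = np.percentile(reps, [2.5, 97.5])
        assert res.ci_low == pytest.approx(lo, abs=1e-12)
        assert res.ci_high == pytest.approx(hi, abs=1e-12)

    def test_mostly_undefined_statistic_aborts(self):
        df = generate_cohort(10, seed=1).assign(treated=0)
        with pytest.raises(AnalysisError):
            cluster_bootstrap(df, auroc_stat("mean_ral_mm", "treated"),
                              n_reps=50, seed=2)


class TestComparePredictors:
    def test_identical_predictors_give_zero_ci(self):
        df = generate_cohort(40, seed=7)
        res, sig = compare_predictors(df, "mean_ral_mm", "mean_ral_mm", "treated",
                                      n_reps=100, seed=1)
        assert res.point_estimate == 0.0
        assert res.ci_low == res.ci_high == 0.0
        assert not sig

    def test_monotone_transform_gives_zero_difference(self):
        df = generate_cohort(40, seed=7).assign(
            transformed=lambda d: np.log(d.mean_ral_mm) * 4 + 2)
        res, sig = compare_predictors(df, "mean_ral_mm", "transformed", "treated",
                                      n_reps=100, seed=1)
        assert res.point_estimate == 0.0 and not sig

    def test_signal_vs_noise_is_significant(self):
        rng = np.random.default_rng(0)
        n = 120
        y = np.repeat([0, 1], n // 2)
        df = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "good": y + rng.normal(0, 0.05, n),  # near-perfect separation
            "noise": rng.normal(size=n),
            "y": y,
        })
        res, sig = compare_predictors(df, "good", "noise", "y", n_reps=300, seed=3)
        assert sig and res.ci_low > 0


class TestGroupDifference:
    def test_antisymmetric(self):
        df = generate_cohort(60, seed=9)
        d1 = group_difference(df, "mean_ral_mm", "I", "II")
        d2 = group_difference(df, "mean_ral_mm", "II", "I")
        assert d1 == pytest.approx(-d2, abs=1e-12)

    def test_identical_groups_zero(self):
        df = generate_cohort(30, seed=1).assign(zone="I")
        assert group_difference(df, "mean_ral_mm", "I", "I") == 0.0

    def test_empty_group_rejected(self):
        df = generate_cohort(30, zone_mix=(1.0, 0.0, 0.0), seed=2)
        with pytest.raises(AnalysisError):
            group_difference(df, "mean_ral_mm", "I", "II")

    def test_bootstrap_ci_attached(self):
        df = generate_cohort(80, seed=3)
        res = group_difference(df, "mean_ral_mm", "I", "II", n_reps=200, seed=5)
        assert res.ci_low < res.point_estimate < res.ci_high
        assert res.point_estimate > 3.0  # zones differ by ~4.5 mm


class TestTableUtilities:
    def test_one_eye_per_patient(self):
        df = generate_cohort(25, seed=4)
        sub = one_eye_per_patient(df, seed=1)
        assert len(sub) == 25
        assert sub.patient_id.is_unique

    def test_validate_rejects_three_eyes(self):
        df = generate_cohort(10, seed=0)
        extra = df.iloc[[0]]
        with pytest.raises(FormatError, match="more than 2 eyes"):
            validate_cohort(pd.concat([df, extra], ignore_index=True))

    def test_validate_reports_missing_columns(self):
        with pytest.raises(FormatError, match="missing columns"):
            validate_cohort(pd.DataFrame({"patient_id": ["a"]}))
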