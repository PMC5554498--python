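import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_laterality_table
from movemetrics.data_model import ValidationError
from movemetrics.group_stats import (
    correlated_mpis,
    correlation_table,
    ks_normality,
    laterality_relevance_pc,
    laterality_relevance_stages,
    laterality_table,
    spearman,
    wilcoxon_ranksum,
    wilcoxon_signed_rank,
)


class TestWilcoxonRanksum:
    def test_exact_small_sample(self):
        res = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    def test_identical_multisets_p_one(self):
        res = wilcoxon_ranksum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_and_asymptotic_agree(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(0.5, size=10)
            exact = wilcoxon_ranksum(a, b)
            from scipy import stats
            approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic")
            assert abs(exact.p_value - approx.pvalue) < 0.02

    @given(st.integers(0, 10 ** 6))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = rng.normal(0.3, size=9)
        p1 = wilcoxon_ranksum(a, b).p_value
        p2 = wilcoxon_ranksum(np.exp(a), np.exp(b)).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestKsNormality:
    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(6)
        res = ks_normality(rng.uniform(size=500))
        assert res.p_value < 0.05

    def test_normal_sample_type_one_rate(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            ks_normality(rng.normal(size=500)).p_value < 0.05
            for _ in range(400)
        )
        # nominal 5% level; binomial 99% envelope for 400 replicates
        assert 0.02 <= rejections / 400 <= 0.09

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality([1.0, 2.0, 3.0, 4.0])


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        res = spearman([1, 2, 3], [3, 1, 2])
        assert res.rho == pytest.approx(-0.5, abs=1e-12)
        # every permutation of 3 ranks yields |rho| >= 0.5, so exact p = 1
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_at_n5(self):
        # perfectly monotone n=5 tie-free: exact two-sided p = 2/5!
        res = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.p_value == pytest.approx(2 / 120, abs=1e-12)

    @given(st.integers(0, 10 ** 6))
    def test_invariant_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1 = spearman(x, y)
        r2 = spearman(np.exp(x), y ** 3)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-9)


class TestLateralityPatientsControls:
    def test_planted_patient_asymmetry_detected(self):
        table = make_laterality_table(seed=1)
        res = laterality_relevance_pc("emg-mav_GPP-EL", table)
        assert res.relevant

    def test_symmetric_generator_not_flagged(self):
        table = make_laterality_table(asymmetry=(1.0, 1.0, 1.0), seed=2)
        res = laterality_relevance_pc("emg-mav_GPP-EL", table)
        assert not res.relevant

    def test_control_asymmetry_fails_condition_two(self):
        table = make_laterality_table(control_asymmetry=0.7, seed=3)
        res = laterality_relevance_pc("emg-mav_GPP-EL", table)
        assert not res.relevant

    def test_unpaired_variant_runs(self):
        table = make_laterality_table(seed=4, n_per_stage=12)
        res = laterality_relevance_pc("emg-mav_GPP-EL", table, test="unpaired")
        assert "controls" in res.evidence


class TestLateralityStages:
    def test_stage_scaled_asymmetry_detected(self):
        table = make_laterality_table(seed=5)
        res = laterality_relevance_stages("emg-mav_GPP-EL", table)
        assert res.relevant
        assert res.evidence["levels_decreasing"]
        assert res.evidence["asymmetry_increasing"]

    def test_stage_constant_asymmetry_rejected(self):
        table = make_laterality_table(asymmetry=(0.7, 0.7, 0.7), seed=6)
        res = laterality_relevance_stages("emg-mav_GPP-EL", table)
        assert not res.relevant

    def test_understaffed_stage_rejected(self):
        table = make_laterality_table(n_per_stage=1, seed=7)
        with pytest.raises(ValidationError):
            laterality_relevance_stages("emg-mav_GPP-EL", table)

    def test_tidy_table(self):
        table = make_laterality_table(seed=8)
        out = laterality_table(table, analysis="pc")
        assert list(out.index) == ["emg-mav_GPP-EL"]
        assert out["relevant"].dtype == bool


class TestClinicalCorrelations:
    def _cohort(self, seed=0, noise=0.1, n=30):
        rng = np.random.default_rng(seed)
        severity = rng.uniform(0.3, 1.0, size=n)
        frame = pd.DataFrame({
            "acc-ssi_TT-P_R": severity * (1 + rng.normal(0, noise, n)),
            "acc-ssi_TT-P_L": severity * (1 + rng.normal(0, noise, n)),
            "group": "patient",
            "taps_proximal": np.round(40 * severity + rng.normal(0, 2, n)),
            "updrs3_total": np.round(60 * (1 - severity) + rng.normal(0, 3, n)),
        }, index=[f"S{i}" for i in range(n)])
        return frame

    def test_monotone_scale_recovered(self):
        cohort = self._cohort(seed=1)
        hits = correlated_mpis(cohort, "taps_proximal", "positive")
        assert set(hits) == {"acc-ssi_TT-P_R", "acc-ssi_TT-P_L"}
        neg = correlated_mpis(cohort, "updrs3_total", "negative")
        assert set(neg) == {"acc-ssi_TT-P_R", "acc-ssi_TT-P_L"}

    def test_pure_noise_scale_mostly_empty(self):
        empties = 0
        for seed in range(40):
            cohort = self._cohort(seed=seed)
            rng = np.random.default_rng(1000 + seed)
            cohort["taps_proximal"] = rng.normal(size=len(cohort))
            if not correlated_mpis(cohort, "taps_proximal", "positive"):
                empties += 1
        assert empties >= 38  # >= 95% of replicates

    def test_direction_flip_disjoint_on_monotone_data(self):
        cohort = self._cohort(seed=2)
        pos = set(correlated_mpis(cohort, "taps_proximal", "positive"))
        neg = set(correlated_mpis(cohort, "taps_proximal", "negative"))
        assert pos
        assert not (pos & neg)

    def test_correlation_table_has_all_mpi_columns(self):
        cohort = self._cohort(seed=3)
        table = correlation_table(cohort, "updrs3_total")
        assert len(table) == 2
        assert set(table.columns) >= {"rho", "p_value", "n"}
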