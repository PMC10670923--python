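"""Genotype classes, MAF, the LR trajectory test, GLM/MANOVA association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growthtraj.synthetic_data import SimulationConfig, SnpSpec, simulate_trajectories
from growthtraj.trajectory_qtl import (
    GenotypeClassing,
    GenotypeMatrix,
    build_classes,
    genotype_count_test,
    lr_trajectory_test,
    merge_similar_classes,
    minor_allele_freq,
    param_multitrait_association,
    per_year_glm,
)

from conftest import two_class_panel


def _matrix(calls_list, snp="SNP1"):
    return GenotypeMatrix(
        calls=pd.DataFrame({snp: calls_list}, index=[f"C{i:03d}" for i in range(len(calls_list))])
    )


class TestGenotypeMatrix:
    def test_het_calls_are_unordered(self):
        gm = _matrix(["A/G", "G/A", "A/A"])
        assert gm.calls["SNP1"].tolist() == ["A/G", "A/G", "A/A"]

    def test_undeclared_allele_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            GenotypeMatrix(
                calls=pd.DataFrame({"SNP1": ["A/T"]}, index=["C1"]),
                alleles={"SNP1": ("A", "G")},
            )

    def test_missing_calls(self):
        gm = _matrix(["A/G", "./.", None, "A/A"])
        assert gm.missing_fraction("SNP1") == 0.5


class TestMinorAlleleFreq:
    def test_monomorphic_is_zero(self):
        assert minor_allele_freq(_matrix(["A/A"] * 24), "SNP1") == 0.0

    def test_hand_counted_frequencies(self):
        gm = _matrix(["T/T"] * 12 + ["T/C"] * 12)
        assert minor_allele_freq(gm, "SNP1") == pytest.approx(12 / 48)
        gm2 = _matrix(["A/G"] * 2 + ["A/A"] * 22)
        assert minor_allele_freq(gm2, "SNP1") == pytest.approx(2 / 48)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            minor_allele_freq(_matrix(["./."] * 4), "SNP1")


class TestBuildClasses:
    def test_monomorphic_untestable(self):
        classing = build_classes(_matrix(["A/A"] * 24), "SNP1")
        assert not classing.testable

    def test_three_classes(self):
        gm = _matrix(["A/A"] * 10 + ["A/G"] * 10 + ["G/G"] * 4)
        classing = build_classes(gm, "SNP1")
        assert classing.labels == ["A/A", "A/G", "G/G"]
        assert [len(m) for _, m in classing.classes] == [10, 10, 4]

    def test_small_class_excluded_makes_snp_untestable(self):
        gm = _matrix(["A/A"] * 22 + ["A/G"] * 2)
        classing = build_classes(gm, "SNP1", min_class_size=3)
        assert not classing.testable
        assert classing.excluded == [("A/G", ["C022", "C023"])]


def _two_class_data(effect=0.0, noise=0.02, seed=0, dominance="dominant"):
    gm = two_class_panel()
    config = SimulationConfig(
        n_clones=24,
        snp_specs=(
            SnpSpec("SNP1", 0.25, effect_target="a", effect_size=effect, dominance=dominance),
        ),
        base_params={"height_m": (30.0, 0.2, 2.0)},
        noise_sd=noise,
        n_ramets=1,
        seed=seed,
    )
    pheno = simulate_trajectories(gm, config, seed=seed)
    return pheno, build_classes(gm, "SNP1")


class TestLRTrajectoryTest:
    def test_null_without_noise_gives_zero_lr(self):
        # identical class parameters and no noise: the nested models coincide
        pheno, classing = _two_class_data(effect=0.0, noise=0.0, seed=1)
        res = lr_trajectory_test(pheno, classing, "richard", "height_m", seed=1)
        assert res.df == 3
        assert -1e-6 <= res.lr < 1e-3
        assert res.p > 0.999

    def test_strong_asymptote_effect_detected(self):
        # classes with plateaus 30 vs 36 (20% shift), 12 clones each
        pheno, classing = _two_class_data(effect=0.2, noise=0.02, seed=2)
        res = lr_trajectory_test(pheno, classing, "richard", "height_m", seed=2)
        assert res.p < 0.001
        fits = res.class_fits
        # plateau is extrapolated beyond the 11-year record, so allow ~10%
        assert fits["A/A"].params[0] == pytest.approx(30.0, rel=0.10)
        assert fits["A/G"].params[0] == pytest.approx(36.0, rel=0.10)
        assert fits["A/G"].params[0] > fits["A/A"].params[0]

    def test_lr_is_nonnegative_and_chisquare_referenced(self):
        pheno, classing = _two_class_data(effect=0.05, noise=0.03, seed=3)
        res = lr_trajectory_test(pheno, classing, "richard", "height_m", seed=3)
        assert res.lr >= -1e-6
        assert res.p == pytest.approx(stats.chi2.sf(res.lr, res.df), rel=1e-12)

    def test_per_class_sigma_mode_counts_sigma_df_when_asked(self):
        pheno, classing = _two_class_data(effect=0.0, noise=0.02, seed=4)
        res = lr_trajectory_test(
            pheno, classing, "richard", "height_m", seed=4,
            sigma_mode="per_class", count_sigma_df=True,
        )
        assert res.df == 4

    def test_untestable_classing_refused(self):
        pheno, _ = _two_class_data(seed=5)
        mono = build_classes(_matrix(["A/A"] * 24), "SNP1")
        with pytest.raises(ValueError, match="usable genotype classes"):
            lr_trajectory_test(pheno, mono, "richard", "height_m")


class TestMergeSimilarClasses:
    def _three_class_data(self, seed=0):
        calls = ["G/G"] * 8 + ["A/G"] * 8 + ["A/A"] * 8
        gm = _matrix(calls)
        # allele counts tie, so ref = 'A'; the recessive alt-hom G/G carries
        # a 20% higher plateau while A/A and A/G share the base trajectory
        config = SimulationConfig(
            n_clones=24,
            snp_specs=(
                SnpSpec("SNP1", 0.5, effect_target="a", effect_size=0.2, dominance="recessive"),
            ),
            base_params={"height_m": (30.0, 0.2, 2.0)},
            noise_sd=0.01,
            n_ramets=1,
            seed=seed,
        )
        pheno = simulate_trajectories(gm, config, seed=seed)
        return pheno, build_classes(gm, "SNP1")

    def test_identical_trajectory_pair_merges(self):
        pheno, classing = self._three_class_data(seed=6)
        merged = merge_similar_classes(pheno, classing, "richard", "height_m", threshold=1e-3)
        assert len(merged.classes) == 2
        assert merged.merged_from == [["A/A", "A/G"]]
        labels = merged.labels
        assert "G/G" in labels and "A/A+A/G" in labels

    def test_zero_threshold_never_merges(self):
        pheno, classing = self._three_class_data(seed=7)
        merged = merge_similar_classes(pheno, classing, "richard", "height_m", threshold=0.0)
        assert merged.classes == classing.classes
        assert merged.merged_from is None


class TestPerYearGLM:
    def test_equal_means_give_zero_f(self):
        classing = GenotypeClassing("S", [("A/A", ["c1", "c2"]), ("A/G", ["c3", "c4"])])
        f, p = per_year_glm({"c1": 5.0, "c2": 7.0, "c3": 5.0, "c4": 7.0}, classing)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_anova(self):
        # groups {10,12} vs {20,22}: SSB = 100, SSW = 4, df = (1, 2), F = 50
        classing = GenotypeClassing("S", [("A/A", ["c1", "c2"]), ("A/G", ["c3", "c4"])])
        f, p = per_year_glm({"c1": 10.0, "c2": 12.0, "c3": 20.0, "c4": 22.0}, classing)
        assert f == pytest.approx(50.0, rel=1e-10)
        assert p == pytest.approx(stats.f.sf(50.0, 1, 2), rel=1e-10)
        assert p == pytest.approx(0.0194, abs=2e-4)

    def test_f_equals_t_squared_for_two_balanced_groups(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(10, 2, 8), rng.normal(11, 2, 8)
        classing = GenotypeClassing(
            "S",
            [("A/A", [f"a{i}" for i in range(8)]), ("G/G", [f"b{i}" for i in range(8)])],
        )
        values = {f"a{i}": x[i] for i in range(8)} | {f"b{i}": y[i] for i in range(8)}
        f, p = per_year_glm(values, classing)
        t, tp = stats.ttest_ind(x, y)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(tp, rel=1e-10)

    def test_insufficient_replication_refused(self):
        classing = GenotypeClassing("S", [("A/A", ["c1"]), ("A/G", ["c2", "c3"])])
        with pytest.raises(ValueError):
            per_year_glm({"c1": 5.0, "c2": 6.0, "c3": 7.0}, classing)


class TestParamManova:
    def _classing(self, n=24):
        ids = [f"C{i:03d}" for i in range(n)]
        half = n // 2
        return GenotypeClassing("S", [("A/A", ids[:half]), ("A/G", ids[half:])]), ids

    def test_identical_class_distributions_give_lambda_one(self):
        classing, ids = self._classing()
        rng = np.random.default_rng(0)
        block = rng.normal(0, 1, size=(12, 3))
        X = pd.DataFrame(np.vstack([block, block]), index=ids, columns=["a", "b", "c"])
        res = param_multitrait_association(X, classing)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_one_dimensional_input_reproduces_glm_f_test(self):
        classing, ids = self._classing()
        rng = np.random.default_rng(1)
        vals = rng.normal(10, 2, 24)
        X = pd.DataFrame({"a": vals}, index=ids)
        res = param_multitrait_association(X, classing)
        f, p = per_year_glm(dict(zip(ids, vals)), classing)
        assert res.f_stat == pytest.approx(f, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_single_parameter_shift_detected(self):
        classing, ids = self._classing()
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1, size=(24, 3)), index=ids, columns=["a", "b", "c"])
        X.loc[ids[12:], "a"] += 5.0  # 5 within-class sd shift in one parameter
        res = param_multitrait_association(X, classing)
        assert res.p < 0.01

    def test_singular_covariance_errors(self):
        classing, ids = self._classing()
        X = pd.DataFrame(np.ones((24, 3)), index=ids, columns=["a", "b", "c"])
        with pytest.raises(np.linalg.LinAlgError, match="standardiz"):
            param_multitrait_association(X, classing)


class TestGenotypeCountTest:
    def test_perfect_mendelian_counts(self):
        classing = GenotypeClassing(
            "S",
            [("A/A", ["x"] * 6), ("A/G", ["x"] * 12), ("G/G", ["x"] * 6)],
        )
        stat, p = genotype_count_test(classing)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        classing = GenotypeClassing(
            "S",
            [("A/A", ["x"] * 10), ("A/G", ["x"] * 10), ("G/G", ["x"] * 4)],
        )
        stat, p = genotype_count_test(classing)
        assert stat == pytest.approx(16 / 6 + 4 / 12 + 4 / 6, rel=1e-12)
        assert stat == pytest.approx(3.667, abs=5e-4)
        assert p == pytest.approx(stats.chi2.sf(stat, 2), rel=1e-12)

    def test_completely_skewed_two_class_counts(self):
        classing = GenotypeClassing("S", [("C/C", ["x"] * 24), ("C/T", [])])
        stat, p = genotype_count_test(classing, expected_ratio=(1, 1))
        assert stat == pytest.approx(24.0)
        assert p < 1e-5

    def test_zero_expected_count_errors(self):
        classing = GenotypeClassing("S", [("A/A", ["x"] * 5), ("A/G", ["x"] * 5)])
        with pytest.raises(ValueError, match="zero"):
            genotype_count_test(classing, expected_ratio=(1, 0))
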