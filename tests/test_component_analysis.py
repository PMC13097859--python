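"""PCA, permutation retention, loading selection and stability metrics."""

import numpy as np
import pandas as pd
import pytest

from vestgait.component_analysis import (
    bootstrap_stability,
    cattell_s,
    congruence_coefficient,
    cumulative_vaf_cut,
    fit_pca,
    impute_missing,
    permutation_vaf_test,
    select_loading_variables,
    standardize,
)


def frame(values, groups=None, columns=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    groups = groups or ["BV", "UV", "HS"] * (n // 3) + ["HS"] * (n % 3)
    columns = columns or [f"v{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=columns,
                      index=[f"p{i}" for i in range(n)])
    df.insert(0, "group", groups[:n])
    return df


def factor_data(rng, n=60, p=20, loading=0.8, n_loaded=10, k=1):
    """Planted k-factor data: first k*n_loaded vars load on k factors."""
    x = rng.normal(size=(n, p))
    for f in range(k):
        factor = rng.normal(size=n)
        cols = slice(f * n_loaded, (f + 1) * n_loaded)
        x[:, cols] = loading * factor[:, None] + np.sqrt(1 - loading**2) * x[:, cols]
    return frame(x)


class TestImputeMissing:
    def _with_hole(self):
        df = frame(np.arange(18, dtype=float).reshape(6, 3),
                   groups=["BV", "BV", "BV", "HS", "HS", "HS"])
        df.loc["p0", "v1"] = np.nan
        return df

    def test_group_median_uses_group(self):
        df = self._with_hole()
        filled, log = impute_missing(df, "group_median")
        # BV values in v1: p1=4, p2=7 -> median 5.5
        assert filled.loc["p0", "v1"] == pytest.approx(5.5)
        assert log[0]["participant_id"] == "p0"

    def test_no_missing_is_identity(self):
        df = frame(np.random.default_rng(0).normal(size=(6, 3)))
        filled, log = impute_missing(df, "overall_median")
        pd.testing.assert_frame_equal(filled, df)
        assert log == []

    def test_complete_case_drops_rows(self):
        df = self._with_hole()
        df.loc["p3", "v2"] = np.nan
        filled, log = impute_missing(df, "complete_case")
        assert filled.shape[0] == 4
        assert len(log) == 2

    def test_all_missing_column_rejected(self):
        df = self._with_hole()
        df["v1"] = np.nan
        with pytest.raises(ValueError, match="v1"):
            impute_missing(df, "group_median")


class TestStandardize:
    def test_symmetric_triple(self):
        df = frame(np.array([[1.0], [2.0], [3.0]]), columns=["v"])
        z = standardize(df)
        np.testing.assert_allclose(z["v"], [-1, 0, 1])

    def test_idempotent_and_contract(self, rng):
        df = frame(rng.normal(3, 7, size=(30, 4)))
        z = standardize(df)
        vals = z.drop(columns="group")
        assert np.all(np.abs(vals.mean()) < 1e-12)
        assert np.all(np.abs(vals.std(ddof=1) - 1) < 1e-12)
        z2 = standardize(z)
        np.testing.assert_allclose(z2.drop(columns="group"), vals, atol=1e-12)

    def test_zero_variance_column_named(self, rng):
        df = frame(rng.normal(size=(10, 2)), columns=["ok", "flat"])
        df["flat"] = 5.0
        with pytest.raises(ValueError, match="flat"):
            standardize(df)


class TestFitPca:
    def test_vaf_matches_independent_eigendecomposition(self, rng):
        df = standardize(frame(rng.multivariate_normal(
            np.zeros(3), [[1, 0.6, 0.2], [0.6, 1, 0.1], [0.2, 0.1, 1]], size=200)))
        model = fit_pca(df)
        z = df.drop(columns="group").to_numpy()
        corr = z.T @ z / (len(z) - 1)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(model.vaf, eig / eig.sum() * 100, atol=1e-9)

    def test_vaf_sums_to_100(self, rng):
        model = fit_pca(standardize(frame(rng.normal(size=(15, 40)))))
        assert model.vaf.sum() == pytest.approx(100.0, abs=1e-9)

    def test_rank_one_gives_full_first_component(self, rng):
        factor = rng.normal(size=50)
        x = np.outer(factor, rng.uniform(0.5, 2, size=6))
        model = fit_pca(standardize(frame(x)))
        assert model.vaf[0] == pytest.approx(100.0, abs=1e-9)

    def test_isotropic_two_columns(self, rng):
        model = fit_pca(standardize(frame(rng.normal(size=(4000, 2)))))
        assert model.vaf[0] == pytest.approx(50.0, abs=5.0)

    def test_deterministic_including_sign(self, rng):
        df = standardize(frame(rng.normal(size=(30, 8))))
        m1, m2 = fit_pca(df), fit_pca(df)
        pd.testing.assert_frame_equal(m1.loadings, m2.loadings)
        # sign convention: dominant loading entry positive
        for comp in m1.loadings.columns:
            col = m1.loadings[comp]
            assert col[col.abs().idxmax()] > 0


class TestPermutationRetention:
    def test_alpha_one_retains_everything(self, rng):
        df = standardize(frame(rng.normal(size=(20, 5))))
        assert permutation_vaf_test(df, n_perm=100, alpha=1.0, seed=0) == 5

    def test_planted_factor_always_retained(self, rng):
        for seed in range(5):
            df = standardize(factor_data(np.random.default_rng(seed)))
            assert permutation_vaf_test(df, n_perm=200, seed=seed) >= 1

    def test_pure_noise_rarely_retains_more_than_one(self):
        counts = []
        for seed in range(50):
            df = standardize(frame(np.random.default_rng(seed).normal(size=(60, 20))))
            counts.append(permutation_vaf_test(df, n_perm=200, seed=seed))
        assert np.mean([c <= 1 for c in counts]) >= 0.90


class TestCumulativeVafCut:
    def test_reference_spectrum_cuts_at_four(self):
        vaf = [32.5, 9.4, 7.1, 7.0, 4.0, 3.5, 3.0, 2.5]
        assert cumulative_vaf_cut(vaf, 0.50, permutation_retained=7) == 4

    @pytest.mark.parametrize(
        "vaf,retained,expected",
        [([60, 10], 2, 1), ([30, 15, 10], 3, 3), ([20, 10], 2, 2)],
    )
    def test_boundaries(self, vaf, retained, expected):
        assert cumulative_vaf_cut(vaf, 0.50, retained) == expected


class TestSelectLoadingVariables:
    def _model(self, loadings):
        loadings = np.asarray(loadings, dtype=float)
        names = [f"v{i}" for i in range(loadings.shape[0])]
        comps = [f"PC{i+1}" for i in range(loadings.shape[1])]
        from vestgait.component_analysis import PCAModel

        return PCAModel(
            loadings=pd.DataFrame(loadings, index=names, columns=comps),
            vaf=np.full(loadings.shape[1], 100 / loadings.shape[1]),
            scores=pd.DataFrame(),
            variable_names=names,
            n_components=loadings.shape[1],
        )

    def test_percent_and_cap_rule(self, rng):
        # 152 variables: 10% = 15.2 -> ceil 16, capped at 10
        model = self._model(rng.normal(size=(152, 2)))
        sel = select_loading_variables(model, 2)
        assert all(len(v) == 10 for v in sel.per_component.values())
        # 20 variables: ceil(2.0) = 2 per component
        small = self._model(rng.normal(size=(20, 1)))
        assert len(select_loading_variables(small, 1).per_component["PC1"]) == 2

    def test_threshold_equals_smallest_retained(self, rng):
        model = self._model(rng.normal(size=(152, 3)))
        sel = select_loading_variables(model, 3)
        for comp, names in sel.per_component.items():
            magnitudes = model.loadings[comp].abs()
            assert min(magnitudes[n] for n in names) == pytest.approx(
                sel.thresholds[comp]
            )
            excluded = magnitudes.drop(names)
            assert (excluded < sel.thresholds[comp]).all()

    def test_union_with_duplicates(self, rng):
        # 4 components x 10 selected with overlaps -> union smaller than 40
        base = rng.normal(size=(152, 4))
        strong = rng.choice(152, size=27, replace=False)
        base[strong] *= 10
        model = self._model(base)
        sel = select_loading_variables(model, 4)
        union = sel.union
        assert len(union) <= 40
        assert len(set(union)) == len(union)
        expected = set()
        for names in sel.per_component.values():
            expected |= set(names)
        assert set(union) == expected

    def test_exact_ties_all_included(self):
        loadings = np.array([[0.9], [0.5], [0.5], [0.1], [0.05], [0.01],
                             [0.02], [0.03], [0.04], [0.06]])
        model = self._model(loadings)
        sel = select_loading_variables(model, 1, pct=0.10, cap=10)
        # m = ceil(1.0) = 1, but v1 and v2 tie at the cut... m=1 keeps only v0
        assert sel.per_component["PC1"] == ["v0"]
        sel2 = select_loading_variables(model, 1, pct=0.20, cap=10)
        # m = 2: second slot ties between v1 and v2 -> both kept
        assert set(sel2.per_component["PC1"]) == {"v0", "v1", "v2"}


class TestSimilarityMetrics:
    def test_congruence_trivial_cases(self, rng):
        x = rng.normal(size=10)
        assert congruence_coefficient(x, x) == pytest.approx(1.0)
        assert congruence_coefficient(x, -x) == pytest.approx(-1.0)
        y = np.array([1.0, 0.0])
        assert congruence_coefficient(y, np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_congruence_scale_invariance(self, rng):
        x = rng.normal(size=8)
        for c in (0.1, -3.0, 7.5):
            assert congruence_coefficient(x, c * x) == pytest.approx(np.sign(c))
        with pytest.raises(ValueError):
            congruence_coefficient(x, np.zeros(8))

    def test_cattell_hand_example(self):
        x = np.array([0.5, 0.05, -0.5, 0.3])
        y = np.array([0.4, 0.02, -0.45, -0.2])
        assert cattell_s(x, y, 0.1) == pytest.approx(1 / 3)

    def test_cattell_extremes(self, rng):
        x = rng.uniform(0.2, 1.0, size=12) * rng.choice([-1, 1], size=12)
        assert cattell_s(x, x) == pytest.approx(1.0)
        assert cattell_s(x, -x) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            cattell_s(np.zeros(5), np.zeros(5))


class TestBootstrapStability:
    def test_self_comparison_is_perfect(self, rng):
        """Resampling the identical participant set reproduces loadings."""
        df = factor_data(rng, n=30, p=8, n_loaded=4)
        z = standardize(df)
        model = fit_pca(z)
        # a degenerate "bootstrap": compare the model against itself
        from vestgait.component_analysis import congruence_coefficient as cc

        first = model.loadings["PC1"].to_numpy()
        assert cc(first, first) == pytest.approx(1.0)
        assert np.sqrt(np.mean((first - first) ** 2)) == 0.0
        assert cattell_s(first, first) == pytest.approx(1.0)
        assert np.corrcoef(first, first)[0, 1] == pytest.approx(1.0)

    def test_strong_factor_is_stable(self, rng):
        df = factor_data(rng, n=60, p=20, loading=0.8, n_loaded=10)
        model = fit_pca(standardize(df))
        report = bootstrap_stability(df, model, components=1, n_boot=200, seed=1)
        assert report.cc["PC1"] >= 0.95
        assert report.pearson_r["PC1"] >= 0.9
        assert report.rms["PC1"] < 0.2

    def test_noise_less_stable_than_planted_factor(self):
        ccs_noise, ccs_factor = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noise = frame(rng.normal(size=(60, 20)))
            planted = factor_data(np.random.default_rng(seed + 100))
            for df, sink in ((noise, ccs_noise), (planted, ccs_factor)):
                model = fit_pca(standardize(df))
                rep = bootstrap_stability(df, model, 1, n_boot=50, seed=seed)
                sink.append(rep.cc["PC1"])
        assert np.mean(ccs_factor) > np.mean(ccs_noise)
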