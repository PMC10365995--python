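import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st_h
from scipy.stats import norm

from glossim.stats import (build_profiles, compare_mediation_models,
                           factor_congruence, fisher_z, fit_factor_model,
                           fit_gloss_regression, intersubject_agreement,
                           lda_loco, max_factors, reduce_terms, rsa,
                           select_top_loading)
from glossim.synthetic import make_observer_loadings


def _max_factors_oracle(p):
    # brute force over the degrees-of-freedom inequality
    return max(m for m in range(p + 1) if ((p - m) ** 2 - (p + m)) / 2 >= 0)


class TestTermReduction:
    def test_boundary_counts(self):
        usage = pd.DataFrame(0, index=range(15), columns=["a", "b"])
        usage.loc[:4, "a"] = 1     # 5 users -> retained
        usage.loc[:3, "b"] = 2     # 4 users -> dropped
        assert reduce_terms(usage) == ["a"]

    def test_known_counts_and_merges(self, rng):
        usage = pd.DataFrame(rng.integers(0, 2, (15, 6)),
                             columns=list("abcdef"))
        expected = [c for c in usage.columns if (usage[c] > 0).sum() >= 5]
        assert reduce_terms(usage) == expected
        merged = reduce_terms(usage, merges={"ab": ["a", "b"]})
        assert ("ab" in merged) == (("a" in expected) or ("b" in expected))
        assert "a" not in merged and "b" not in merged

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reduce_terms(pd.DataFrame())


class TestProfiles:
    def test_confidence_sums(self):
        resp = pd.DataFrame({
            "participant": [0, 1, 0],
            "stimulus": [0, 0, 1],
            "category": ["A", "A", "B"],
            "confidence": [3, 2, 1],
        })
        prof = build_profiles(resp)
        assert prof.loc[0, "A"] == 5
        assert prof.loc[1, "B"] == 1

    def test_zero_row_for_missing_stimulus(self):
        resp = pd.DataFrame({"participant": [0], "stimulus": [0],
                             "category": ["A"], "confidence": [2]})
        prof = build_profiles(resp, stimuli=[0, 1], categories=["A", "B"])
        assert prof.loc[1].sum() == 0
        assert prof.shape == (2, 2)

    def test_unknown_category_rejected(self):
        resp = pd.DataFrame({"participant": [0], "stimulus": [0],
                             "category": ["X"], "confidence": [2]})
        with pytest.raises(ValueError, match="unknown"):
            build_profiles(resp, categories=["A"])

    @given(seed=st_h.integers(0, 50))
    def test_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        resp = pd.DataFrame({
            "participant": r.integers(0, 5, 30),
            "stimulus": r.integers(0, 4, 30),
            "category": r.choice(list("ABC"), 30),
            "confidence": r.integers(1, 4, 30),
        })
        shuffled = resp.sample(frac=1, random_state=seed).reset_index(drop=True)
        pd.testing.assert_frame_equal(build_profiles(resp),
                                      build_profiles(shuffled))


class TestMaxFactors:
    @pytest.mark.parametrize("p,expected", [(18, 12), (6, 3), (2, 0)])
    def test_reference_values(self, p, expected):
        assert max_factors(p) == expected

    @pytest.mark.parametrize("p", range(2, 40))
    def test_matches_bruteforce(self, p):
        assert max_factors(p) == _max_factors_oracle(p)

    def test_small_p_rejected(self):
        with pytest.raises(ValueError):
            max_factors(1)


class TestFactorModel:
    def _synth_profiles(self, seed, n=924, p=18, m=8, noise=0.4):
        r = np.random.default_rng(seed)
        L = make_observer_loadings(p, m, seed=seed)
        S = r.normal(size=(n, m))
        X = S @ L.T + r.normal(scale=noise, size=(n, p))
        return pd.DataFrame(X), L, S

    def test_recovery_congruence(self):
        congr = []
        for seed in range(20):
            prof, L, _ = self._synth_profiles(seed)
            sol = fit_factor_model(prof, 8, rotation="varimax")
            congr.append(factor_congruence(sol.loadings.to_numpy(), L))
        assert np.mean(congr) >= 0.95

    def test_rank1_score_recovery(self):
        r = np.random.default_rng(1)
        L = r.uniform(0.6, 0.9, size=(18, 1))
        S = r.normal(size=(400, 1))
        X = S @ L.T + 0.1 * r.normal(size=(400, 18))
        sol = fit_factor_model(pd.DataFrame(X), 1)
        assert abs(np.corrcoef(sol.scores.iloc[:, 0], S[:, 0])[0, 1]) >= 0.99

    def test_noise_only_within_parallel_null(self):
        # First-factor shared variance (as a fraction of total variance) on
        # pure-noise profiles should sit inside the null distribution of the
        # same statistic over independent noise datasets.
        def first_factor_total_variance(seed):
            r = np.random.default_rng(seed)
            prof = pd.DataFrame(r.normal(size=(200, 18)))
            sol = fit_factor_model(prof, 1)
            return sol.total_variance.iloc[0]

        observed = first_factor_total_variance(999)
        null = [first_factor_total_variance(s) for s in range(30)]
        assert observed <= np.quantile(null, 0.99) * 1.05

    def test_variance_bookkeeping(self):
        prof, _, _ = self._synth_profiles(3)
        sol = fit_factor_model(prof, 8)
        csv = sol.cumulative_shared_variance.to_numpy()
        assert np.all(np.diff(csv) >= 0)
        assert csv[-1] == pytest.approx(1.0)
        assert np.all((sol.shared_variance >= 0)
                      & (sol.shared_variance <= 1))

    def test_negative_pole_dimension(self):
        prof, _, S = self._synth_profiles(5)
        sol = fit_factor_model(prof, 8)
        m = 8
        neg_dim = sol.assignments == m
        if sol.negative_factor is not None:
            assert neg_dim.sum() >= 5
            # stimuli on the negative dimension have negative extreme scores
            sc = sol.scores.to_numpy()
            for i in np.flatnonzero(neg_dim.to_numpy()):
                j = np.abs(sc[i]).argmax()
                assert sc[i, j] < 0
                assert j == sol.negative_factor

    def test_zero_variance_category_rejected(self):
        prof = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 5)))
        prof[2] = 1.0
        with pytest.raises(ValueError, match="singular"):
            fit_factor_model(prof, 2)

    def test_m_out_of_range_rejected(self):
        prof = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 6)))
        with pytest.raises(ValueError):
            fit_factor_model(prof, 4)  # max_factors(6) == 3


class TestGlossRegression:
    def test_noiseless_r2_one(self, rng):
        feats = pd.DataFrame(rng.uniform(0, 1, (50, 3)),
                             columns=["coverage", "sharpness", "contrast"])
        y = 0.2 + feats @ [0.5, 0.3, 0.2]
        res = fit_gloss_regression(feats, y)
        assert res.r_squared == pytest.approx(1.0)

    def test_residual_df_bookkeeping(self, rng):
        feats = pd.DataFrame(rng.uniform(0, 1, (920, 3)),
                             columns=["coverage", "sharpness", "contrast"])
        y = rng.uniform(0, 1, 920)
        res = fit_gloss_regression(feats, y)
        assert res.df_model == 3
        assert res.df_resid == 916

    def test_matches_normal_equations(self, rng):
        feats = pd.DataFrame(rng.uniform(0, 1, (60, 3)),
                             columns=["coverage", "sharpness", "contrast"])
        y = rng.uniform(0, 1, 60)
        res = fit_gloss_regression(feats, y)
        X = np.column_stack([np.ones(60), feats.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_too_few_stimuli_rejected(self, rng):
        feats = pd.DataFrame(rng.uniform(0, 1, (4, 3)),
                             columns=["coverage", "sharpness", "contrast"])
        with pytest.raises(ValueError):
            fit_gloss_regression(feats, np.ones(4))


class TestLdaLoco:
    def test_separable_classes_near_perfect(self, rng):
        centers = rng.normal(scale=20, size=(5, 6))
        X = np.concatenate([c + 0.01 * rng.normal(size=(40, 6))
                            for c in centers])
        y = np.repeat(np.arange(5), 40)
        cond = np.tile(np.repeat(np.arange(4), 10), 5)
        res = lda_loco(X, y, cond)
        assert res.overall_accuracy > 0.99

    def test_permuted_labels_at_chance_13_classes(self):
        # balanced labels permuted at random: held-out accuracy equals the
        # 1/13 = 7.7% chance level within Monte-Carlo error
        r = np.random.default_rng(7)
        n = 13 * 4 * 40
        X = r.normal(size=(n, 6))
        y = r.permutation(np.repeat(np.arange(13), n // 13))
        cond = np.tile(np.arange(4), n // 4)
        res = lda_loco(X, y, cond, shrinkage=0.1)
        # binomial MC error at n=2080 is ~0.6%
        assert res.overall_accuracy == pytest.approx(1 / 13, abs=0.02)

    def test_two_class_matches_bayes_rate(self):
        r = np.random.default_rng(8)
        delta = 1.2  # Mahalanobis distance for identity covariance
        n = 20000
        X = np.vstack([r.normal(size=(n, 4)),
                       r.normal(size=(n, 4)) + [delta, 0, 0, 0]])
        y = np.repeat([0, 1], n)
        cond = np.tile(np.arange(4), len(X) // 4)
        res = lda_loco(X, y, cond)
        bayes = norm.cdf(delta / 2)
        assert res.overall_accuracy == pytest.approx(bayes, abs=0.01)

    def test_absent_class_flagged_and_excluded(self):
        r = np.random.default_rng(9)
        X = r.normal(size=(90, 3))
        y = np.array([0] * 30 + [1] * 30 + [2] * 30)
        cond = np.zeros(90, int)
        cond[60:] = 1  # class 2 exists only in condition 1
        cond[:20] = 1  # make both folds have classes 0/1
        res = lda_loco(X, y, cond)
        assert any("absent" in f for f in res.flags)

    def test_condition_generalization(self, rng):
        # condition-invariant class structure: held-out accuracy close to
        # within-condition accuracy
        centers = rng.normal(scale=4, size=(6, 6))
        X, y, cond = [], [], []
        for c in range(4):
            for k, mu in enumerate(centers):
                X.append(mu + rng.normal(size=(25, 6)))
                y += [k] * 25
                cond += [c] * 25
        X = np.concatenate(X)
        res = lda_loco(X, np.array(y), np.array(cond))
        within = lda_loco(X, np.array(y),
                          np.tile(np.arange(4), len(X) // 4))
        assert abs(res.overall_accuracy - within.overall_accuracy) < 0.05


class TestSelection:
    def test_k1_argmax(self, rng):
        scores = pd.DataFrame(rng.normal(size=(20, 3)))
        sel, _ = select_top_loading(scores, k=1)
        for dim, grp in sel.groupby("dimension"):
            assert len(grp) == 1

    def test_planted_top_sets_recovered(self):
        scores = pd.DataFrame(np.zeros((30, 2)))
        scores.iloc[:10, 0] = np.linspace(2, 3, 10)
        scores.iloc[10:20, 1] = np.linspace(2, 3, 10)
        scores.iloc[20:, 0] = 0.1
        sel, _ = select_top_loading(scores, k=10)
        dim0 = set(sel[sel.dimension == 0].stimulus) & set(range(10))
        assert dim0 == set(range(10))

    def test_subset_bound_and_flags(self, rng):
        scores = pd.DataFrame(rng.normal(size=(100, 13)))
        sel, flags = select_top_loading(scores, k=36)
        assert len(sel) <= 36 * 13
        assert len(sel) == len(set(sel.stimulus))  # no duplicates
        assert flags  # 100 stimuli cannot fill 13 dimensions of 36


class TestAgreement:
    def test_identical_raters(self, rng):
        base = rng.uniform(0, 1, 40)
        R = np.vstack([base] * 4)
        med, loo, flags = intersubject_agreement(R)
        assert med == pytest.approx(1.0)
        assert loo == pytest.approx(1.0)
        assert not flags

    def test_independent_noise_near_zero(self):
        r = np.random.default_rng(3)
        R = r.normal(size=(20, 500))
        med, loo, _ = intersubject_agreement(R)
        assert abs(med) < 0.1

    def test_single_pair(self, rng):
        a, b = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        med, _, _ = intersubject_agreement(np.vstack([a, b]))
        assert med == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_constant_rater_flagged(self, rng):
        R = np.vstack([rng.uniform(0, 1, 30), rng.uniform(0, 1, 30),
                       np.full(30, 0.5)])
        _, _, flags = intersubject_agreement(R)
        assert any("constant" in f for f in flags)


class TestFisherZ:
    @pytest.mark.parametrize("r,z", [(0.0, 0.0), (0.5, 0.5493061443)])
    def test_reference_values(self, r, z):
        assert fisher_z(r) == pytest.approx(z)

    @given(r=st_h.floats(-0.999, 0.999))
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestRsa:
    def test_self_comparison_is_one(self, rng):
        # feature-derived dissimilarities compared with themselves: feed the
        # standardized features through both branches with the same metric
        F = rng.normal(size=(25, 6))
        Fz = (F - F.mean(0)) / F.std(0, ddof=1)
        feats = pd.DataFrame(Fz)
        assert rsa(feats, feats, profile_metric="euclidean") == \
            pytest.approx(1.0)

    def test_feature_driven_profiles_high_correlation(self):
        r = np.random.default_rng(4)
        feats = pd.DataFrame(r.normal(size=(40, 6)))
        # profiles whose rows are a smooth function of the features
        P = np.tanh(feats.to_numpy() @ r.normal(size=(6, 18)))
        assert rsa(pd.DataFrame(P), feats) >= 0.5

    def test_shuffled_rows_near_zero(self):
        r = np.random.default_rng(5)
        feats = pd.DataFrame(r.normal(size=(60, 6)))
        P = np.tanh(feats.to_numpy() @ r.normal(size=(6, 18)))
        P = P[r.permutation(60)]
        assert abs(rsa(pd.DataFrame(P), feats)) < 0.15

    def test_too_few_stimuli(self, rng):
        f = pd.DataFrame(rng.normal(size=(2, 6)))
        with pytest.raises(ValueError):
            rsa(f, f)


class TestMediation:
    def test_cues_win_when_gloss_is_imperfect_proxy(self):
        r = np.random.default_rng(6)
        feats = pd.DataFrame(r.uniform(0, 1, (300, 3)),
                             columns=["coverage", "sharpness", "contrast"])
        # material score built from the cues with weights different from the
        # gloss weights -> gloss is an imperfect proxy
        gloss = feats @ [0.6, 0.3, 0.1] + 0.05 * r.normal(size=300)
        score = feats @ [0.1, 0.2, 0.9] + 0.05 * r.normal(size=300)
        table = compare_mediation_models(
            feats, gloss, pd.DataFrame({"dim1": score}))
        assert table.loc["dim1", "winner"] == "cues"

    def test_models_tie_when_score_is_gloss(self):
        r = np.random.default_rng(7)
        feats = pd.DataFrame(r.uniform(0, 1, (300, 3)),
                             columns=["coverage", "sharpness", "contrast"])
        gloss = feats @ [0.6, 0.3, 0.1] + 0.02 * r.normal(size=300)
        score = gloss + 0.02 * r.normal(size=300)
        table = compare_mediation_models(
            feats, gloss, pd.DataFrame({"dim1": score}))
        assert abs(table.loc["dim1", "r2_gloss"]
                   - table.loc["dim1", "r2_cues"]) < 0.05

    def test_constant_scores_rejected(self, rng):
        feats = pd.DataFrame(rng.uniform(0, 1, (50, 3)),
                             columns=["coverage", "sharpness", "contrast"])
        with pytest.raises(ValueError, match="constant"):
            compare_mediation_models(feats, rng.uniform(0, 1, 50),
                                     pd.DataFrame({"d": np.ones(50)}))
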