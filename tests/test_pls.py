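import numpy as np
import pandas as pd
import pytest

from rumina.pls import (
    PLSError,
    clade_comparison,
    fit_pls,
    genus_associations,
    loo_select_components,
    standardize,
    vip,
)


def _standardized(rng, n=25, p=8):
    X = rng.normal(size=(n, p))
    Xz, _ = standardize(X)
    return Xz


class TestStandardize:
    def test_centering_and_scaling(self):
        rng = np.random.default_rng(0)
        Z, stats = standardize(rng.normal(3, 5, size=(40, 6)))
        assert np.abs(Z.mean(axis=0)).max() < 1e-12
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        M = rng.normal(3, 5, size=(30, 4))
        Z, stats = standardize(M)
        np.testing.assert_allclose(stats.inverse(Z), M, atol=1e-10)

    def test_constant_column_dropped(self):
        M = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        Z, stats = standardize(M)
        assert Z.shape[1] == 1
        assert stats.dropped == [1]

    def test_single_row_rejected(self):
        with pytest.raises(PLSError):
            standardize(np.ones((1, 3)))


class TestFitPLS:
    def test_first_weight_proportional_to_xty(self):
        rng = np.random.default_rng(2)
        Xz = _standardized(rng)
        y = Xz @ rng.normal(size=8) + rng.normal(0, 0.1, size=25)
        yz, _ = standardize(y)
        model = fit_pls(Xz, yz, 2)
        w_closed = Xz.T @ yz[:, 0]
        w_closed /= np.linalg.norm(w_closed)
        cosine = abs(model.W[:, 0] @ w_closed)
        assert cosine >= 1 - 1e-10

    def test_pls1_one_component_prediction_is_projection(self):
        rng = np.random.default_rng(3)
        Xz = _standardized(rng)
        y = Xz @ rng.normal(size=8)
        yz, _ = standardize(y)
        model = fit_pls(Xz, yz, 1)
        t1 = Xz @ (Xz.T @ yz[:, 0] / np.linalg.norm(Xz.T @ yz[:, 0]))
        proj = t1 * (t1 @ yz[:, 0]) / (t1 @ t1)
        yhat = (model.T[:, :1] @ model.Q[:, :1].T)[:, 0]
        np.testing.assert_allclose(yhat, proj, atol=1e-8)

    def test_exact_rank_A_fixture_r2_is_one(self):
        rng = np.random.default_rng(4)
        n, p, A = 30, 10, 3
        X = rng.normal(size=(n, p))
        Xz, _ = standardize(X)
        B = rng.normal(size=(p, 2))
        Y = Xz @ B  # Y lies in the column space of X
        Yz, _ = standardize(Y)
        model = fit_pls(Xz, Yz, min(n - 1, p))
        assert model.r2y_path[-1] == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_response_gives_near_zero_r2(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 5))
        Xz, _ = standardize(X)
        # build y orthogonal to every X column
        Q, _ = np.linalg.qr(np.column_stack([np.ones(40), Xz]))
        y = rng.normal(size=40)
        y = y - Q @ (Q.T @ y)
        yz, _ = standardize(y)
        model = fit_pls(Xz, yz, 2)
        assert model.r2y_cum < 1e-10

    def test_score_orthogonality(self):
        rng = np.random.default_rng(6)
        Xz = _standardized(rng, n=30, p=12)
        Y = Xz @ rng.normal(size=(12, 3)) + rng.normal(0, 0.5, size=(30, 3))
        Yz, _ = standardize(Y)
        model = fit_pls(Xz, Yz, 4)
        gram = model.T.T @ model.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_weights_unit_norm(self):
        rng = np.random.default_rng(7)
        Xz = _standardized(rng)
        Yz, _ = standardize(Xz @ rng.normal(size=(8, 2)))
        model = fit_pls(Xz, Yz, 3)
        for a in range(3):
            assert np.linalg.norm(model.W[:, a]) == pytest.approx(1.0, abs=1e-10)

    def test_r2_nondecreasing_in_A(self):
        rng = np.random.default_rng(8)
        Xz = _standardized(rng, n=30, p=10)
        Yz, _ = standardize(Xz @ rng.normal(size=(10, 2))
                            + rng.normal(0, 1, size=(30, 2)))
        model = fit_pls(Xz, Yz, 6)
        assert np.all(np.diff(model.r2y_path) >= -1e-12)

    def test_matches_sklearn_predictions(self):
        sk = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(9)
        Xz = _standardized(rng, n=30, p=6)
        y = Xz @ rng.normal(size=6) + rng.normal(0, 0.3, size=30)
        yz, _ = standardize(y)
        model = fit_pls(Xz, yz, 3)
        ref = sk.PLSRegression(n_components=3, scale=False).fit(Xz, yz)
        np.testing.assert_allclose(
            model.predict(Xz), ref.predict(Xz), atol=1e-8
        )

    def test_A_out_of_range(self):
        rng = np.random.default_rng(10)
        Xz = _standardized(rng, n=10, p=4)
        yz, _ = standardize(rng.normal(size=10))
        with pytest.raises(PLSError):
            fit_pls(Xz, yz, 0)
        with pytest.raises(PLSError):
            fit_pls(Xz, yz, 5)


class TestVIP:
    def _model(self, seed=0, p=10, A=3):
        rng = np.random.default_rng(seed)
        Xz = _standardized(rng, n=30, p=p)
        y = Xz @ rng.normal(size=p) + rng.normal(0, 0.5, size=30)
        yz, _ = standardize(y)
        return fit_pls(Xz, yz, A)

    def test_normalization_identity(self):
        for seed in range(5):
            model = self._model(seed)
            scores = vip(model)
            assert scores @ scores == pytest.approx(10, abs=1e-8)

    def test_one_component_closed_form(self):
        rng = np.random.default_rng(11)
        Xz = _standardized(rng, n=25, p=7)
        y = Xz @ rng.normal(size=7)
        yz, _ = standardize(y)
        model = fit_pls(Xz, yz, 1)
        expected = np.sqrt(7) * np.abs(model.W[:, 0])
        np.testing.assert_allclose(vip(model), expected, atol=1e-10)

    def test_zero_weight_predictor_zero_vip(self):
        # at A=1 the weight is X'y; a predictor orthogonal to y gets VIP 0
        rng = np.random.default_rng(12)
        n = 40
        Xz, _ = standardize(rng.normal(size=(n, 5)))
        yz, _ = standardize(rng.normal(size=n))
        y = yz[:, 0]
        ortho = Xz[:, 4] - y * (y @ Xz[:, 4]) / (y @ y)
        Xz[:, 4] = ortho / ortho.std(ddof=1)
        model = fit_pls(Xz, yz, 1)
        assert vip(model)[4] == pytest.approx(0.0, abs=1e-8)


class TestLOOSelection:
    def _two_latent(self, n=30, p=12, noise=0.3, seed=21):
        rng = np.random.default_rng(seed)
        T = rng.normal(size=(n, 2))  # two true latent factors
        X = T @ rng.normal(size=(2, p))  # X has exact rank 2
        y = T @ np.array([2.0, -1.5]) + rng.normal(0, noise, size=n)
        return X, y

    def test_selects_two_components(self):
        X, y = self._two_latent()
        A, press = loo_select_components(X, y, 6)
        assert A == 2

    def test_pure_noise_selects_one(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        A, press = loo_select_components(X, y, 5)
        # PRESS on noise rarely improves with A; the tie rule keeps A small
        assert A <= 2

    def test_deterministic(self):
        X, y = self._two_latent()
        A1, p1 = loo_select_components(X, y, 5)
        A2, p2 = loo_select_components(X, y, 5)
        assert A1 == A2
        np.testing.assert_array_equal(p1, p2)

    def test_a_max_truncated(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        A, press = loo_select_components(X, y, 20)
        assert len(press) == 4  # n - 2


class TestGenusAssociations:
    def _dataset(self, p=80, seed=30, flip=False):
        rng = np.random.default_rng(seed)
        n = 32
        X = pd.DataFrame(
            rng.lognormal(0, 0.5, size=(n, p)),
            columns=[f"g{j}" for j in range(p)],
            index=[f"s{i}" for i in range(n)],
        )
        X = X.div(X.sum(axis=1), axis=0)
        y = 0.02 + 0.004 * (
            (X["g0"] - X["g0"].mean()) / X["g0"].std()
        ) + rng.normal(0, 0.001, size=n)
        if flip:
            y = -y
        return X, pd.Series(y, index=X.index, name="ndf_rate")

    def test_percentile_lists_hold_four_of_eighty(self):
        X, y = self._dataset()
        rep = genus_associations(X, y, A_max=5)
        pos = rep.percentile_list("positive")
        neg = rep.percentile_list("negative")
        assert len(pos) + len(neg) == 4  # ceil(0.05 * 80)

    def test_planted_positive_genus_in_positive_list(self):
        X, y = self._dataset()
        rep = genus_associations(X, y, A_max=5)
        assert "g0" in rep.percentile_list("positive")

    def test_sign_symmetry(self):
        X, y = self._dataset()
        rep_pos = genus_associations(X, y, A_max=5)
        rep_neg = genus_associations(X, -y, A_max=5)
        assert set(rep_pos.percentile_list("positive")) == set(
            rep_neg.percentile_list("negative")
        )
        assert set(rep_pos.percentile_list("negative")) == set(
            rep_neg.percentile_list("positive")
        )

    def test_important_flag_threshold(self):
        X, y = self._dataset()
        rep = genus_associations(X, y, A_max=5)
        t = rep.table
        assert (t.loc[t["important"], "vip"] > 0.8).all()
        assert (~(t.loc[~t["important"], "vip"] > 0.8)).all()


class TestCladeComparison:
    def test_duplicated_response_block_invariance(self):
        rng = np.random.default_rng(40)
        n = 24
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         index=[f"s{i}" for i in range(n)])
        X.columns = [f"c{j}" for j in range(10)]
        y = pd.DataFrame(
            {"r1": X["c0"] + rng.normal(0, 0.1, n),
             "r2": X["c1"] + rng.normal(0, 0.1, n)},
            index=X.index,
        )
        doubled = pd.concat([y, y.add_suffix("_copy")], axis=1)
        one = clade_comparison({"genus": X}, y, A_max=4)
        two = clade_comparison({"genus": X}, doubled, A_max=4)
        assert one.loc[0, "pct_explained"] == pytest.approx(
            two.loc[0, "pct_explained"], abs=1e-8
        )

    def test_six_levels_in_six_rows_out(self):
        rng = np.random.default_rng(41)
        n = 20
        idx = [f"s{i}" for i in range(n)]
        tables = {
            lvl: pd.DataFrame(rng.normal(size=(n, 4 + k)), index=idx)
            for k, lvl in enumerate(
                ["phylum", "class", "order", "family", "genus", "species"]
            )
        }
        Y = pd.DataFrame(rng.normal(size=(n, 2)), index=idx,
                         columns=["r1", "r2"])
        out = clade_comparison(tables, Y, A_max=3)
        assert len(out) == 6
        assert out["best"].sum() >= 1

    def test_mismatched_level_skipped(self):
        rng = np.random.default_rng(42)
        idx = [f"s{i}" for i in range(15)]
        good = pd.DataFrame(rng.normal(size=(15, 5)), index=idx)
        bad = pd.DataFrame(rng.normal(size=(15, 5)),
                           index=[f"z{i}" for i in range(15)])
        Y = pd.DataFrame(rng.normal(size=(15, 2)), index=idx)
        out = clade_comparison({"genus": good, "phylum": bad}, Y, A_max=3)
        assert list(out["level"]) == ["genus"]
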