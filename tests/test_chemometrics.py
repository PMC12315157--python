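"""SPXY splitting, PLSR/SVR model fitting, the five-fold protocol, and
the SPA / CARS / RC baseline wavelength selectors."""

import numpy as np
import pytest

from specgp.chemometrics import (
    CARSSelector,
    GridSVR,
    PLSRCV,
    RCSelector,
    SPASelector,
    crossval_protocol,
    spxy_split,
)


def linear_problem(rng, n=40, p=12, noise=0.0, informative=(1, 3)):
    X = rng.random((n, p))
    y = sum(X[:, j] for j in informative) + noise * rng.standard_normal(n)
    return X, np.asarray(y)


class TestSPXY:
    def test_collinear_extremes_go_to_calibration(self):
        # three equally spaced collinear samples: the two extremes seed
        # the calibration set (hand trace of the greedy rule)
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        split = spxy_split(X, y, ratio=2 / 3)
        assert set(split.calibration.tolist()) == {0, 2}
        assert split.prediction.tolist() == [1]

    def test_deterministic(self, rng):
        X = rng.random((30, 5))
        y = rng.random(30)
        s1 = spxy_split(X, y)
        s2 = spxy_split(X, y)
        np.testing.assert_array_equal(s1.calibration, s2.calibration)

    def test_150_samples_give_100_50(self, rng):
        X = rng.random((150, 10))
        y = rng.random(150)
        split = spxy_split(X, y, ratio=2 / 3)
        assert len(split.calibration) == 100
        assert len(split.prediction) == 50
        assert set(split.calibration) | set(split.prediction) == set(range(150))

    def test_greedy_insertion_trace(self, rng):
        # every selected sample had, at its insertion, the largest minimum
        # joint distance among the then-remaining candidates
        X = rng.random((15, 3))
        y = rng.random(15)
        diff = X[:, None, :] - X[None, :, :]
        dx = np.sqrt((diff**2).sum(axis=2))
        dy = np.abs(y[:, None] - y[None, :])
        d = dx / dx.max() + dy / dy.max()
        split = spxy_split(X, y, ratio=2 / 3)
        first = np.unravel_index(np.argmax(d), d.shape)
        selected = [int(first[0]), int(first[1])]
        remaining = [i for i in range(15) if i not in selected]
        while len(selected) < len(split.calibration):
            min_d = d[np.ix_(remaining, selected)].min(axis=1)
            pick = remaining[int(np.argmax(min_d))]
            others = min_d.max()
            assert d[pick, selected].min() == pytest.approx(others)
            selected.append(pick)
            remaining.remove(pick)
        assert sorted(selected) == split.calibration.tolist()

    def test_duplicate_only_data_degenerate(self):
        X = np.ones((5, 3))
        y = np.ones(5)
        with pytest.raises(ValueError):
            spxy_split(X, y)


class TestPLSRCV:
    def test_exact_linear_recovery(self, rng):
        X, y = linear_problem(rng, n=30, p=6)
        model = PLSRCV(max_lv=5).fit(X, y)
        assert model.rmsecv_ < 1e-2 * y.std()
        # the RMSECV-selected component count reproduces the relation to
        # well below the data scale
        np.testing.assert_allclose(model.predict(X), y, atol=1e-3)

    def test_pure_noise_small_rmsecv_near_sd(self, rng):
        X = rng.random((40, 8))
        y = rng.standard_normal(40)
        model = PLSRCV(max_lv=6).fit(X, y)
        assert model.rmsecv_ < 2.0 * y.std()
        assert model.rmsecv_ > 0.5 * y.std()

    def test_chosen_lv_within_bound(self, rng):
        X, y = linear_problem(rng, n=25, p=10, noise=0.1)
        model = PLSRCV(max_lv=4).fit(X, y)
        assert 1 <= model.n_components_ <= 4


class TestGridSVR:
    def test_proportional_relation_recovered(self, rng):
        x = rng.uniform(0, 1, 50)[:, None]
        y = 2.0 * x.ravel()
        model = GridSVR("linear").fit(x, y)
        from sklearn.metrics import r2_score

        assert r2_score(y, model.predict(x)) > 0.99

    def test_single_point_grid_chosen(self, rng):
        x = rng.random((20, 2))
        y = x[:, 0]
        model = GridSVR("linear", grid={"C": [3.0], "epsilon": [0.05]}).fit(x, y)
        assert model.best_params_ == {"C": 3.0, "epsilon": 0.05}

    def test_grid_search_never_worse_than_worst_member(self, rng):
        # exhaustive check on a tiny grid: the selected CV-MSE equals the
        # minimum over individually evaluated grid members
        from sklearn.model_selection import KFold, cross_val_score
        from sklearn.svm import SVR

        x = rng.random((30, 3))
        y = x[:, 0] + 0.1 * rng.standard_normal(30)
        grid = {"C": [0.1, 10.0], "epsilon": [0.01, 0.5]}
        model = GridSVR("linear", grid=grid, random_state=0).fit(x, y)
        cv = KFold(5, shuffle=True, random_state=0)
        scores = []
        for c in grid["C"]:
            for eps in grid["epsilon"]:
                s = cross_val_score(
                    SVR(kernel="linear", C=c, epsilon=eps), x, y, cv=cv,
                    scoring="neg_mean_squared_error",
                ).mean()
                scores.append(-s)
        assert model.cv_mse_ == pytest.approx(min(scores))


class TestCrossvalProtocol:
    def test_noise_free_linear_all_metrics_ideal(self, rng):
        X, y = linear_problem(rng, n=30, p=4)
        Xp, yp = linear_problem(rng, n=12, p=4)
        m = crossval_protocol(PLSRCV(max_lv=4), X, y, Xp, yp)
        assert m.r2_cal > 0.999 and m.r2_cv > 0.999 and m.r2_pred > 0.999
        assert m.mse_cal < 1e-6 and m.mse_cv < 1e-6 and m.mse_pred < 1e-6

    def test_metrics_average_matches_hand_bookkeeping(self, rng):
        from sklearn.base import clone
        from sklearn.metrics import mean_squared_error, r2_score
        from sklearn.model_selection import KFold

        X, y = linear_problem(rng, n=25, p=5, noise=0.3)
        Xp, yp = linear_problem(rng, n=10, p=5, noise=0.3)
        model = PLSRCV(max_lv=3)
        got = crossval_protocol(model, X, y, Xp, yp, random_state=7)
        rows = []
        for train, test in KFold(5, shuffle=True, random_state=7).split(X):
            m = clone(model).fit(X[train], y[train])
            rows.append(
                [
                    r2_score(y[train], m.predict(X[train])),
                    mean_squared_error(y[train], m.predict(X[train])),
                    r2_score(y[test], m.predict(X[test])),
                    mean_squared_error(y[test], m.predict(X[test])),
                    r2_score(yp, m.predict(Xp)),
                    mean_squared_error(yp, m.predict(Xp)),
                ]
            )
        expected = np.asarray(rows).mean(axis=0)
        np.testing.assert_allclose(
            list(got.as_dict().values()), expected, rtol=1e-10
        )

    def test_too_few_samples_raise(self, rng):
        X, y = linear_problem(rng, n=4, p=4)
        with pytest.raises(ValueError):
            crossval_protocol(PLSRCV(max_lv=2), X, y, X, y, k=5)


class TestSPA:
    def test_identical_columns_never_both_selected(self, rng):
        X = rng.random((30, 5))
        X[:, 3] = X[:, 1]  # exact duplicate
        y = X[:, 1] + X[:, 0]
        sel = SPASelector(max_vars=4).fit(X, y)
        assert not {1, 3} <= set(sel.selected_idx_.tolist())

    def test_orthogonal_recovery(self, rng):
        # y loads on two orthogonal columns of distinct (largest) norms;
        # the projection chains surface them first and validation keeps them
        g = rng.standard_normal((30, 6))
        g -= g.mean(axis=0)
        q, _ = np.linalg.qr(g)  # zero-mean orthonormal columns
        X = q.copy()
        X[:, 2] *= 1.5
        X[:, 5] *= 2.0
        y = X[:, 2] + X[:, 5]
        sel = SPASelector(max_vars=2, min_vars=2).fit(X, y)
        assert set(sel.selected_idx_.tolist()) == {2, 5}

    def test_projection_chain_matches_gram_schmidt(self, rng):
        # the deflation step equals explicit Gram-Schmidt residual norms
        X = rng.random((20, 6))
        Xc = X - X.mean(axis=0)
        chain = SPASelector.projection_chain(X, 0, 4)
        picked = [chain[0]]
        for step in range(1, len(chain)):
            basis = Xc[:, picked]
            proj = basis @ np.linalg.lstsq(basis, Xc, rcond=None)[0]
            residual = Xc - proj
            residual[:, picked] = 0.0
            norms = np.linalg.norm(residual, axis=0)
            assert chain[step] == int(np.argmax(norms))
            picked.append(chain[step])

    def test_indices_unique_and_in_range(self, rng):
        X, y = linear_problem(rng, n=25, p=8, noise=0.1)
        sel = SPASelector(max_vars=5).fit(X, y)
        idx = sel.selected_idx_
        assert len(set(idx.tolist())) == len(idx)
        assert idx.min() >= 0 and idx.max() < 8

    def test_transform_subsets_columns(self, rng):
        X, y = linear_problem(rng, n=25, p=8, noise=0.1)
        sel = SPASelector(max_vars=4).fit(X, y)
        np.testing.assert_array_equal(sel.transform(X), X[:, sel.selected_idx_])


class TestCARS:
    def test_retention_schedule_decreases(self, rng):
        X, y = linear_problem(rng, n=30, p=20, noise=0.05)
        sel = CARSSelector(n_mc=15, random_state=0).fit(X, y)
        path = sel.retention_path_
        assert (np.diff(path) <= 1e-12).all()
        assert path[0] == pytest.approx(1.0)

    def test_final_subset_within_band_count(self, rng):
        X, y = linear_problem(rng, n=30, p=20, noise=0.05)
        sel = CARSSelector(n_mc=15, random_state=0).fit(X, y)
        assert 1 <= len(sel.selected_idx_) <= 20
        assert len(set(sel.selected_idx_.tolist())) == len(sel.selected_idx_)

    def test_informative_bands_retained(self, rng):
        # strong two-band signal in pure-noise background
        X = rng.random((40, 25))
        y = 5.0 * X[:, 4] + 5.0 * X[:, 17] + 0.01 * rng.standard_normal(40)
        kept = 0
        for seed in range(5):
            sel = CARSSelector(n_mc=20, random_state=seed).fit(X, y)
            kept += {4, 17} <= set(sel.selected_idx_.tolist())
        assert kept >= 4

    def test_n_mc_too_small_raises(self, rng):
        X, y = linear_problem(rng)
        with pytest.raises(ValueError):
            CARSSelector(n_mc=1).fit(X, y)


class TestRC:
    def test_single_peak_kept_at_wide_window(self):
        values = np.array([0.1, 0.2, 5.0, 0.2, 0.1, 0.05])
        kept = RCSelector.non_maximum_suppression(values, window=10, threshold=0.5)
        assert kept.tolist() == [2]

    def test_two_separated_peaks_both_kept(self):
        values = np.zeros(30)
        values[5] = 1.0
        values[20] = 0.8
        kept = RCSelector.non_maximum_suppression(values, window=5, threshold=0.1)
        assert kept.tolist() == [5, 20]

    def test_suppression_matches_bruteforce_scan(self, rng):
        values = rng.random(50)
        window, threshold = 3, 0.3
        kept = RCSelector.non_maximum_suppression(values, window, threshold)
        brute = []
        for i in range(50):
            lo, hi = max(0, i - window), min(50, i + window + 1)
            seg = values[lo:hi]
            if values[i] >= threshold and values[i] == seg.max():
                if i - lo == int(np.argmax(seg)):
                    brute.append(i)
        assert kept.tolist() == brute

    def test_fit_selects_informative_band(self, rng):
        X = rng.random((40, 20))
        y = 3.0 * X[:, 7] + 0.05 * rng.standard_normal(40)
        sel = RCSelector(nms_window=5, random_state=0).fit(X, y)
        assert any(abs(int(i) - 7) <= 1 for i in sel.selected_idx_)


def test_noise_free_models_reach_high_prediction_r2(rng):
    # every model path attains Rp2 >= 0.99 on noise-free linear data
    X, y = linear_problem(rng, n=45, p=6)
    Xp, yp = linear_problem(rng, n=15, p=6)
    for model in (PLSRCV(max_lv=6), GridSVR("linear")):
        metrics = crossval_protocol(model, X, y, Xp, yp)
        assert metrics.r2_pred >= 0.99
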