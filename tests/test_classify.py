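import numpy as np
import pytest

from leukosmear.classify import (MaxMarginModel, TrainConfig, early_stop_epoch,
                                 load_model, mse, predict, save_model,
                                 train_max_margin, train_mlp)


@pytest.fixture(scope="module")
def blobs():
    """Two well-separated Gaussian blobs with a train/val/test assignment."""
    rng = np.random.default_rng(7)
    n = 200
    x = np.vstack([rng.normal(-2.0, 0.5, (n // 2, 5)),
                   rng.normal(2.0, 0.5, (n // 2, 5))])
    y = np.repeat([0, 1], n // 2)
    parts = np.array((["train"] * 35 + ["validation"] * 7 + ["test"] * 8) * 2
                     + ["train"] * (n - 100))
    perm = rng.permutation(n)
    return x[perm], y[perm], np.resize(parts, n)[perm]


class TestMSE:
    def test_identical_matrices_zero(self, rng):
        a = rng.normal(size=(4, 2))
        assert mse(a, a) == 0.0

    def test_hand_arithmetic(self):
        assert mse([1.0, 2.0], [3.0, 2.0]) == pytest.approx(2.0)

    def test_quadratic_homogeneity(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        assert mse(a, a + 2 * (b - a)) == pytest.approx(4 * mse(a, b))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mse([], [])


class TestEarlyStopping:
    def test_halts_patience_epochs_after_worsening_begins(self):
        # val loss strictly worsens from epoch 2 onward -> halt at epoch 2 + 6
        losses = [5.0, 4.0, 3.0] + [3.0 + 0.1 * k for k in range(1, 10)]
        assert early_stop_epoch(losses, patience=6) == 8

    def test_counter_resets_on_improvement(self):
        losses = [5, 6, 6, 6, 6, 6, 4, 6, 6, 6, 6, 6, 6]
        assert early_stop_epoch(losses, patience=6) == 12

    def test_never_triggered_runs_to_end(self):
        losses = [5, 4, 3, 2, 1]
        assert early_stop_epoch(losses, patience=6) == 5


class TestTrainMLP:
    @pytest.mark.parametrize("objective", ["mse", "cross_entropy"])
    def test_separable_blobs_reach_perfect_training_accuracy(self, blobs, objective):
        x, y, parts = blobs
        config = TrainConfig(objective=objective, max_epochs=300)
        model, trace = train_mlp(x, y, parts, config)
        pred, _ = predict(model, x[parts == "train"])
        assert (pred == y[parts == "train"]).mean() == 1.0

    def test_same_seed_identical_weights(self, blobs):
        x, y, parts = blobs
        config = TrainConfig(max_epochs=50)
        m1, _ = train_mlp(x, y, parts, config)
        m2, _ = train_mlp(x, y, parts, config)
        assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))

    def test_returns_best_validation_checkpoint(self, blobs):
        x, y, parts = blobs
        model, trace = train_mlp(x, y, parts, TrainConfig(max_epochs=200))
        assert trace.best_epoch == int(np.argmin(trace.val_loss))

    def test_failure_counter_never_exceeds_patience(self, blobs):
        x, y, parts = blobs
        config = TrainConfig(max_epochs=400, max_validation_failures=6)
        _, trace = train_mlp(x, y, parts, config)
        assert max(trace.failure_counter) <= 6
        if trace.stopped_epoch < config.max_epochs - 1:
            assert trace.failure_counter[-1] == 6

    def test_best_so_far_training_loss_non_increasing(self, blobs):
        x, y, parts = blobs
        _, trace = train_mlp(x, y, parts, TrainConfig(max_epochs=100))
        best = np.minimum.accumulate(trace.train_loss)
        assert np.all(np.diff(best) <= 1e-15)

    def test_single_class_training_rejected(self):
        x = np.zeros((10, 3))
        y = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="both classes"):
            train_mlp(x, y, np.array(["train"] * 10))

    def test_divergence_reports_epoch_and_rate(self, blobs, monkeypatch):
        # the squashing activations keep every loss finite for any step size,
        # so exercise the guard by injecting a non-finite loss evaluation
        import leukosmear.classify as mod
        x, y, parts = blobs
        monkeypatch.setattr(mod, "_loss", lambda *a, **k: float("nan"))
        with pytest.raises(FloatingPointError, match="learning rate"):
            train_mlp(x, y, parts, TrainConfig(max_epochs=5))


def brute_force_max_margin(points, labels):
    """Exact small-case maximizer: the optimal separating hyperplane is
    equidistant from 2 or 3 defining points; enumerate all candidates."""
    pos = points[labels == 1]
    neg = points[labels == 0]
    best = (-np.inf, None)

    def margin_of(w, b):
        signed = (points @ w + b) * np.where(labels == 1, 1.0, -1.0)
        return signed.min()

    # pairs: one from each class -> perpendicular bisector
    for p in pos:
        for q in neg:
            w = p - q
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                continue
            w = w / norm
            b = -w @ (p + q) / 2.0
            best = max(best, (margin_of(w, b), (w, b)), key=lambda t: t[0])
    # triples: two same-class + one other -> hyperplane parallel to the pair
    for same, other in ((pos, neg), (neg, pos)):
        for i in range(len(same)):
            for j in range(i + 1, len(same)):
                d = same[j] - same[i]
                for o in other:
                    # normal orthogonal to d, in the plane spanned by d and (o - same[i])
                    v = o - same[i]
                    n = v - (v @ d) / max(d @ d, 1e-12) * d
                    norm = np.linalg.norm(n)
                    if norm < 1e-12:
                        continue
                    n = n / norm
                    mid = (n @ same[i] + n @ o) / 2.0
                    for w in (n, -n):
                        b = -mid * (1 if w is n else -1)
                        best = max(best, (margin_of(w, b), (w, b)), key=lambda t: t[0])
    return best[0]


class TestMaxMargin:
    def test_symmetric_pair_boundary_at_midpoint(self):
        model = train_max_margin(np.array([[-1.0], [1.0]]), np.array([0, 1]))
        _, score = predict(model, np.array([[0.0]]))
        assert score[0] == pytest.approx(0.0, abs=1e-9)
        assert set(model.support_indices) == {0, 1}

    def test_margin_matches_exhaustive_small_case_oracle(self):
        points = np.array([[0.0, 0.0], [1.0, 0.5], [0.2, 1.0],
                           [3.0, 3.0], [4.0, 2.5]])
        labels = np.array([0, 0, 0, 1, 1])
        model = train_max_margin(points, labels, C=1e6, tol=1e-8)  # hard margin
        # the optimization runs on standardized coordinates; compare there
        standardized = model.scaler.transform(points)
        w, b = model.weight_vector, model.bias
        geom_margin = ((standardized @ w + b)
                       * np.where(labels == 1, 1, -1)).min() / np.linalg.norm(w)
        assert geom_margin == pytest.approx(
            brute_force_max_margin(standardized, labels), abs=1e-6)

    def test_separable_blobs_zero_training_errors(self, blobs):
        x, y, parts = blobs
        model = train_max_margin(x[parts == "train"], y[parts == "train"])
        pred, _ = predict(model, x[parts == "train"])
        assert (pred == y[parts == "train"]).mean() == 1.0

    def test_duplicating_points_leaves_boundary_unchanged(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(-1, 0.3, (10, 2)), rng.normal(1, 0.3, (10, 2))])
        y = np.repeat([0, 1], 10)
        m1 = train_max_margin(x, y)
        m2 = train_max_margin(np.vstack([x, x]), np.concatenate([y, y]))
        assert np.allclose(m1.weight_vector, m2.weight_vector, atol=1e-6)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-6)

    def test_removing_non_support_vectors_keeps_boundary(self):
        # symmetric toy: boundary is the y-axis with or without the two
        # far-away points, and the dataset mean stays at the origin
        points = np.array([[-1.0, 0.0], [-1.2, 0.4], [-0.8, -0.4],
                           [1.0, 0.0], [1.2, -0.4], [0.8, 0.4],
                           [-3.0, 0.0], [3.0, 0.0]])
        labels = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        model = train_max_margin(points, labels, C=1e6)
        assert 6 not in model.support_indices and 7 not in model.support_indices
        reduced = train_max_margin(points[:6], labels[:6], C=1e6)

        def raw_boundary(m):
            w = m.weight_vector / m.scaler.std
            b = m.bias - np.sum(m.weight_vector * m.scaler.mean / m.scaler.std)
            scale = np.linalg.norm(w)
            return w / scale, b / scale

        w1, b1 = raw_boundary(model)
        w2, b2 = raw_boundary(reduced)
        assert np.allclose(w1, w2, atol=1e-4)
        assert b1 == pytest.approx(b2, abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_max_margin(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestPredict:
    def test_mlp_scores_sum_to_one(self, blobs):
        x, y, parts = blobs
        model, _ = train_mlp(x, y, parts, TrainConfig(max_epochs=20))
        xs = model.scaler.transform(x[:10])
        probs = model.forward(xs)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_batch_order_invariance(self, blobs):
        x, y, parts = blobs
        model, _ = train_mlp(x, y, parts, TrainConfig(max_epochs=20))
        _, fwd = predict(model, x[:20])
        _, rev = predict(model, x[:20][::-1])
        assert np.allclose(fwd, rev[::-1])

    def test_width_mismatch_rejected(self, blobs):
        x, y, parts = blobs
        model, _ = train_mlp(x, y, parts, TrainConfig(max_epochs=5))
        with pytest.raises(ValueError, match="width"):
            predict(model, np.zeros((3, 7)))


class TestSerialization:
    def test_mlp_round_trip(self, blobs, tmp_path):
        x, y, parts = blobs
        model, _ = train_mlp(x, y, parts, TrainConfig(max_epochs=20))
        save_model(model, tmp_path / "mlp.npz")
        back = load_model(tmp_path / "mlp.npz")
        _, s1 = predict(model, x[:10])
        _, s2 = predict(back, x[:10])
        assert np.allclose(s1, s2)

    def test_max_margin_round_trip(self, blobs, tmp_path):
        x, y, parts = blobs
        model = train_max_margin(x[parts == "train"], y[parts == "train"])
        save_model(model, tmp_path / "svm.npz")
        back = load_model(tmp_path / "svm.npz")
        _, s1 = predict(model, x[:10])
        _, s2 = predict(back, x[:10])
        assert np.allclose(s1, s2)
        assert isinstance(back, MaxMarginModel)
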