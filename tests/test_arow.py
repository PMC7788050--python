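import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylarow import (
    ArowClassState,
    BetaMatrix,
    MulticlassArowModel,
    arow_update_binary,
    load_checkpoint,
    save_checkpoint,
)

PROBES3 = ["cg00000001", "cg00000002", "cg00000003"]


class TestInitialState:
    def test_fresh_model_is_zero_mean_unit_confidence(self):
        model = MulticlassArowModel(PROBES3, r=1.0)
        for cls in model.classes:
            st_ = model.state(cls)
            assert np.array_equal(st_.mu, np.zeros(3))
            assert np.array_equal(st_.sigma, np.ones(3))
        assert model.epoch_count == 0

    def test_fresh_model_scores_are_zero(self):
        model = MulticlassArowModel(PROBES3, r=0.5)
        scores = model.decision_scores(np.array([0.2, 0.9, 0.4]))
        assert all(v == 0.0 for v in scores.values())

    @pytest.mark.parametrize("r", [0.0, -1.0])
    def test_nonpositive_r_rejected(self, r):
        with pytest.raises(ValueError, match="r must be > 0"):
            MulticlassArowModel(PROBES3, r=r)


class TestBinaryUpdate:
    def test_hand_computed_single_step(self):
        # mu=0, sigma=1, r=1, x=(1,0), y=+1:
        # m=0, beta=1/(1+1)=0.5, alpha=0.5 -> mu=(0.5,0), sigma=(0.5,1)
        state = ArowClassState(np.zeros(2), np.ones(2), r=1.0)
        out = arow_update_binary(state, np.array([1.0, 0.0]), +1)
        assert np.allclose(out.mu, [0.5, 0.0])
        assert np.allclose(out.sigma, [0.5, 1.0])

    def test_no_update_when_margin_met(self):
        state = ArowClassState(np.array([2.0, 0.0]), np.array([0.3, 0.9]), r=1.0)
        out = arow_update_binary(state, np.array([1.0, 1.0]), +1)  # m = 2 >= 1
        assert np.array_equal(out.mu, state.mu)
        assert np.array_equal(out.sigma, state.sigma)

    def test_zero_input_changes_nothing(self):
        state = ArowClassState(np.array([0.1, -0.2]), np.array([0.5, 0.5]), r=2.0)
        out = arow_update_binary(state, np.zeros(2), -1)
        assert np.array_equal(out.mu, state.mu)
        assert np.array_equal(out.sigma, state.sigma)

    def test_dimension_mismatch_rejected(self):
        state = ArowClassState(np.zeros(2), np.ones(2), r=1.0)
        with pytest.raises(ValueError, match="dimension"):
            arow_update_binary(state, np.zeros(3), +1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_sigma_positive_and_non_increasing_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        state = ArowClassState(np.zeros(5), np.ones(5), r=float(rng.uniform(0.1, 2.0)))
        for _ in range(30):
            x = rng.random(5)
            y = int(rng.choice([-1, 1]))
            new = arow_update_binary(state, x, y)
            assert (new.sigma > 0).all()
            assert (new.sigma <= state.sigma + 1e-15).all()
            state = new

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_update_happens_iff_margin_below_one(self, seed):
        rng = np.random.default_rng(seed)
        state = ArowClassState(rng.normal(size=4), np.abs(rng.normal(size=4)) + 0.1,
                               r=1.0)
        x = rng.random(4)
        y = int(rng.choice([-1, 1]))
        m = y * float(state.mu @ x)
        new = arow_update_binary(state, x, y)
        changed = not np.array_equal(new.mu, state.mu)
        assert changed == (m < 1.0 and x.any())


class TestPrediction:
    def test_single_term_dot_product(self):
        model = MulticlassArowModel(PROBES3)
        model.mu[model.classes.index("iPSC"), 0] = 1.0
        scores = model.decision_scores(np.array([0.8, 0.0, 0.0]))
        assert scores["iPSC"] == pytest.approx(0.8)

    def test_argmax_and_tie_break_by_class_order(self):
        model = MulticlassArowModel(["p"])
        model.mu[:, 0] = [0.1, 0.9, 0.0, -0.2]
        assert model.predict(np.array([1.0])) == "iPSC"
        model.mu[:, 0] = 0.0
        assert model.predict(np.array([1.0])) == "ESC"  # tie -> first class

    def test_scores_match_elementwise_oracle(self, rng):
        model = MulticlassArowModel([f"p{i}" for i in range(30)])
        model.mu = rng.normal(size=model.mu.shape)
        x = rng.random(30)
        scores = model.decision_scores(x)
        for c, cls in enumerate(model.classes):
            brute = sum(model.mu[c, j] * x[j] for j in range(30))
            assert scores[cls] == pytest.approx(brute)

    def test_predict_matches_linear_scan_oracle(self, rng):
        model = MulticlassArowModel([f"p{i}" for i in range(8)])
        for _ in range(50):
            model.mu = rng.normal(size=model.mu.shape)
            x = rng.random(8)
            scores = model.decision_scores(x)
            best, best_v = None, -np.inf
            for cls in model.classes:  # first-max scan = class-order tie-break
                if scores[cls] > best_v:
                    best, best_v = cls, scores[cls]
            assert model.predict(x) == best

    def test_misaligned_probe_set_errors(self):
        model = MulticlassArowModel(PROBES3)
        with pytest.raises(KeyError, match="missing"):
            model.decision_scores({"cg00000001": 0.5})


def _separable_toy():
    """10 samples, 5 features; feature 0 alone separates the two classes."""
    rng = np.random.default_rng(0)
    X = rng.random((5, 10)) * 0.2
    labels = ["ESC"] * 5 + ["iPSC"] * 5
    X[0, :5] = 0.9  # ESC high on feature 0
    X[0, 5:] = 0.05
    return X, labels


class TestTraining:
    def test_toy_set_is_separable_by_exhaustive_threshold_search(self):
        X, labels = _separable_toy()
        y = np.array([1 if l == "ESC" else -1 for l in labels])
        separable = False
        for j in range(X.shape[0]):  # single-feature threshold oracle
            vals = X[j]
            for t in vals:
                for sign in (1, -1):
                    if ((sign * np.sign(vals - t + 1e-12)) == y).all():
                        separable = True
        assert separable

    def test_linearly_separable_toy_reaches_perfect_training_accuracy(self):
        X, labels = _separable_toy()
        model = MulticlassArowModel([f"p{i}" for i in range(5)], r=1.0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            model.train_epoch(X, labels, rng)
        pred = model.predict_matrix(X)
        assert pred == labels
        assert model.epoch_count == 20

    def test_fixed_seed_reproduces_weights(self):
        X, labels = _separable_toy()
        runs = []
        for _ in range(2):
            model = MulticlassArowModel([f"p{i}" for i in range(5)])
            rng = np.random.default_rng(9)
            for _ in range(5):
                model.train_epoch(X, labels, rng)
            runs.append(model.mu.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_unlabeled_sample_errors(self):
        beta = BetaMatrix(
            pd.DataFrame([[0.1, 0.2]], index=["p"], columns=["s1", "s2"])
        )
        model = MulticlassArowModel(["p"])
        with pytest.raises(KeyError, match="unlabeled"):
            model.train_epoch(beta, {"s1": "ESC"}, np.random.default_rng(0))

    def test_training_invariant_to_feature_permutation(self):
        X, labels = _separable_toy()
        probes = [f"p{i}" for i in range(5)]
        model = MulticlassArowModel(probes)
        rng = np.random.default_rng(3)
        for _ in range(10):
            model.train_epoch(X, labels, rng)

        perm = np.random.default_rng(4).permutation(5)
        model_p = MulticlassArowModel([probes[i] for i in perm])
        rng = np.random.default_rng(3)
        for _ in range(10):
            model_p.train_epoch(X[perm], labels, rng)
        # dot products sum in permuted order, so equality is to rounding
        assert np.allclose(model_p.mu, model.mu[:, perm], rtol=1e-10, atol=1e-12)
        Xt = np.random.default_rng(5).random((5, 7))
        assert model.predict_matrix(Xt) == model_p.predict_matrix(Xt[perm])

    def test_separable_toy_converges_with_vanishing_updates(self):
        # AROW's confidence-scaled updates shrink as evidence accumulates,
        # so margins approach the target and per-epoch changes vanish
        X, labels = _separable_toy()
        model = MulticlassArowModel([f"p{i}" for i in range(5)])
        rng = np.random.default_rng(2)
        model.train_epoch(X, labels, rng)
        first_epoch_delta = np.abs(model.mu).max()
        for _ in range(39):
            model.train_epoch(X, labels, rng)
        y = np.array([[1 if l == c else -1 for l in labels] for c in model.classes])
        margins = y * (model.mu @ X)
        assert (margins > 0).all()  # every sample on the correct side
        mu_before = model.mu.copy()
        model.train_epoch(X, labels, rng)
        late_delta = np.abs(model.mu - mu_before).max()
        assert late_delta < 0.02 * first_epoch_delta


class TestCheckpoint:
    def test_round_trip_equality(self, tmp_path, rng):
        model = MulticlassArowModel(PROBES3, r=0.25, rng_seed=11)
        model.mu = rng.normal(size=model.mu.shape)
        model.sigma = rng.random(model.sigma.shape) * 0.9 + 0.05
        model.epoch_count = 250
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        assert load_checkpoint(path) == model

    def test_truncated_file_raises(self, tmp_path):
        model = MulticlassArowModel(PROBES3)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="cannot load"):
            load_checkpoint(path)

    def test_checkpointed_model_predicts_identically(self, tmp_path):
        X, labels = _separable_toy()
        model = MulticlassArowModel([f"p{i}" for i in range(5)])
        rng = np.random.default_rng(6)
        for _ in range(15):
            model.train_epoch(X, labels, rng)
        path = tmp_path / "m.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        Xt = np.random.default_rng(7).random((5, 20))
        assert back.predict_matrix(Xt) == model.predict_matrix(Xt)
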