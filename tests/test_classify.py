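"""One-class authentication layer, identification CV, biometric rates."""

import numpy as np
import pytest

from eegselect import (
    authenticate_then_identify,
    crossval_identification,
    evaluate_authentication,
    train_one_class,
)


@pytest.fixture(scope="module")
def blob():
    rng = np.random.default_rng(0)
    return rng.standard_normal((60, 5))


class TestOneClassTraining:
    def test_training_acceptance_respects_nu_bound(self, blob):
        # nu upper-bounds the training-error fraction (plus solver slack)
        for nu in (0.05, 0.2, 0.5):
            model = train_one_class(blob, nu=nu, gamma=0.1)
            frac_rejected = 1.0 - np.mean(model.accepts(blob))
            assert frac_rejected <= nu + 0.1

    def test_far_outlier_rejected(self, blob):
        model = train_one_class(blob, nu=0.1, gamma=0.1)
        outlier = blob.mean(axis=0) + 100.0
        assert not model.accepts(outlier[None, :])[0]

    def test_rejection_monotone_in_nu(self, blob):
        fractions = []
        for nu in (0.05, 0.2, 0.4, 0.6, 0.8):
            model = train_one_class(blob, nu=nu, gamma=0.1)
            fractions.append(1.0 - np.mean(model.accepts(blob)))
        diffs = np.diff(fractions)
        assert np.all(diffs >= -0.05)  # solver tolerance slack

    def test_dimension_mismatch(self, blob):
        model = train_one_class(blob, nu=0.1, gamma=0.1)
        with pytest.raises(ValueError):
            model.accepts(np.zeros((3, 7)))

    @pytest.mark.parametrize("nu,gamma", [(0.0, 0.1), (1.5, 0.1), (0.1, 0.0)])
    def test_parameter_ranges(self, blob, nu, gamma):
        with pytest.raises(ValueError):
            train_one_class(blob, nu=nu, gamma=gamma)

    def test_extreme_table_values_still_fit(self, blob):
        # the decoded parameter table spans 1e-6..1.0 for nu
        for nu in (1e-6, 1.0):
            model = train_one_class(blob, nu=nu, gamma=0.1)
            assert model.nu == nu


class _FixedModel:
    """Stand-in decision function with scripted acceptances."""

    def __init__(self, genuine_accepted, intruder_accepted):
        self.script = list(genuine_accepted) + list(intruder_accepted)

    def accepts(self, vectors):
        n = len(np.atleast_2d(vectors))
        out, self.script = self.script[:n], self.script[n:]
        return np.array(out, dtype=bool)


class TestAuthenticationMetrics:
    def test_counting_oracle(self):
        model = _FixedModel([True] * 8 + [False] * 2, [True] * 3 + [False] * 9)
        metrics = evaluate_authentication(model, np.zeros((10, 2)), np.zeros((12, 2)))
        assert metrics.tar == pytest.approx(0.8)
        assert metrics.trr == pytest.approx(0.75)
        assert metrics.far == pytest.approx(1.0 - metrics.trr)
        assert metrics.n_genuine_accepted == 8
        assert metrics.n_intruder_accepted == 3

    def test_accept_everything(self):
        model = _FixedModel([True] * 4, [True] * 4)
        metrics = evaluate_authentication(model, np.zeros((4, 2)), np.zeros((4, 2)))
        assert metrics.tar == 1.0 and metrics.trr == 0.0

    def test_empty_sets_named(self, blob):
        model = train_one_class(blob, nu=0.1, gamma=0.1)
        with pytest.raises(ValueError, match="genuine"):
            evaluate_authentication(model, np.empty((0, 5)), blob)
        with pytest.raises(ValueError, match="intruder"):
            evaluate_authentication(model, blob, np.empty((0, 5)))


class TestIdentificationCV:
    def test_separable_classes_score_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 3)) * 0.1
        y = np.repeat(["a", "b"], 20)
        x[y == "b", 0] += 50.0
        mean, std = crossval_identification(x, y, k=5, seed=0)
        assert mean == 1.0 and std == 0.0

    def test_permuted_labels_score_chance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((120, 4))
        y = np.repeat(["a", "b", "c"], 40)
        accs = []
        for seed in range(3):
            y_perm = np.random.default_rng(seed).permutation(y)
            mean, _ = crossval_identification(x, y_perm, k=5, seed=0)
            accs.append(mean)
        # chance level 1/3; permutation std on 120 samples is a few percent
        assert abs(np.mean(accs) - 1 / 3) < 0.15

    def test_class_smaller_than_folds(self):
        x = np.zeros((12, 2))
        y = ["a"] * 9 + ["b"] * 3
        with pytest.raises(ValueError, match="smaller k"):
            crossval_identification(x, y, k=5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((60, 4))
        y = np.repeat(["a", "b", "c"], 20)
        a = crossval_identification(x, y, k=5, seed=7)
        b = crossval_identification(x, y, k=5, seed=7)
        assert a == b


class TestTwoLayerFlow:
    def test_identification_only_after_acceptance(self, blob):
        model = train_one_class(blob, nu=0.1, gamma=0.1)

        class ConstantIdentifier:
            def predict(self, vectors):
                return np.array(["S1"] * len(vectors))

        outlier = blob.mean(axis=0) + 100.0
        vectors = np.vstack([blob[:2], outlier[None, :]])
        labels = authenticate_then_identify(model, ConstantIdentifier(), vectors)
        assert labels[2] is None  # rejected instances are never identified
        assert all(lab in ("S1", None) for lab in labels)
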