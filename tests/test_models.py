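import numpy as np
import pytest
from scipy.optimize import lsq_linear

from sirnakit import (
    GAWeightFusion,
    Layer1Regressor,
    NeuralNetFusion,
    SVRFusion,
    StackingFrame,
    SyntheticSpec,
    TwoLayerPredictor,
    ValidationError,
    admit_methods,
    build_stacking_frame,
    generate_synthetic,
    pearson_r,
)


def _dummy_layer1(name: str, cv_r: float) -> Layer1Regressor:
    m = Layer1Regressor(method_name=name)
    m.cv_r_ = cv_r
    return m


def _noisy_frame(seed: int, n: int = 150) -> StackingFrame:
    """Two imperfect predictors of a common target."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 100, n)
    p1 = y + rng.normal(0, 12, n)
    p2 = 0.6 * y + 15 + rng.normal(0, 15, n)
    return StackingFrame(p1, p2, y, ("m1", "m2"))


def box_ls_mse(frame: StackingFrame) -> float:
    """Independent oracle: box-constrained least squares over [0,1]^2."""
    res = lsq_linear(frame.X, frame.observed, bounds=(0.0, 1.0))
    return float(np.mean((frame.observed - frame.X @ res.x) ** 2))


class TestLayer1:
    def test_signal_is_learnable_and_deterministic(self):
        ds = generate_synthetic(SyntheticSpec(200, 7, "gc_linear", 5.0, 20.0))
        m1 = Layer1Regressor("Binary", random_state=1).fit(ds.sequences, ds.efficacies)
        m2 = Layer1Regressor("Binary", random_state=1).fit(ds.sequences, ds.efficacies)
        assert m1.cv_r_ > 0.6
        assert m1.cv_r_ == m2.cv_r_
        assert np.array_equal(
            m1.predict(ds.sequences[:10]), m2.predict(ds.sequences[:10])
        )

    def test_pure_noise_has_no_cv_signal(self):
        ds = generate_synthetic(SyntheticSpec(300, 13, "gc_linear", 10.0, 0.0))
        m = Layer1Regressor("Binary", random_state=2).fit(ds.sequences, ds.efficacies)
        assert abs(m.cv_r_) < 0.2

    def test_degenerate_labels_rejected(self):
        ds = generate_synthetic(SyntheticSpec(30, 1))
        with pytest.raises(ValidationError, match="zero variance"):
            Layer1Regressor("Binary").fit(ds.sequences, [50.0] * 30)

    def test_minimum_n(self):
        ds = generate_synthetic(SyntheticSpec(10, 1))
        with pytest.raises(ValidationError, match="n >= 20"):
            Layer1Regressor("Binary").fit(ds.sequences, ds.efficacies)


class TestAdmission:
    def test_threshold_is_inclusive(self):
        groups = admit_methods(
            [
                _dummy_layer1("Binary", 0.61),
                _dummy_layer1("Hybrid", 0.59),
                _dummy_layer1("F85", 0.60),
            ]
        )
        names = {m.method_name for g in groups.values() for m in g}
        assert names == {"Binary", "F85"}  # 0.60 admitted, 0.59 not

    def test_all_below_threshold_errors(self):
        with pytest.raises(ValidationError, match="admission"):
            admit_methods([_dummy_layer1("Binary", 0.3), _dummy_layer1("F85", 0.2)])

    def test_missing_category_errors(self):
        with pytest.raises(ValidationError, match="sequence-type"):
            admit_methods([_dummy_layer1("F85", 0.9), _dummy_layer1("F65", 0.8)])

    def test_eight_pairs_from_two_by_four(self):
        models = [_dummy_layer1(n, 0.7) for n in
                  ("Binary", "Hybrid", "F162", "F85", "F65", "F47")]
        groups = admit_methods(models)
        pairs = [(s.method_name, f.method_name)
                 for s in groups["sequence"] for f in groups["feature"]]
        assert len(pairs) == 8


class TestStackingFrame:
    def test_partition_law_and_alignment(self):
        ds = generate_synthetic(SyntheticSpec(100, 3, "gc_linear", 5.0, 20.0))
        m1 = Layer1Regressor("Binary", random_state=0).fit(ds.sequences, ds.efficacies)
        m2 = Layer1Regressor("F162", random_state=0).fit(ds.sequences, ds.efficacies)
        frame = build_stacking_frame(ds.sequences, ds.efficacies, (m1, m2), seed=0)
        # every record appears exactly once, predictions are all finite
        assert len(frame) == 100
        assert np.isfinite(frame.pred1).all() and np.isfinite(frame.pred2).all()
        assert np.array_equal(frame.observed, np.asarray(ds.efficacies))
        assert frame.X.shape == (100, 2)
        # out-of-fold r does not exceed the resubstitution r (no leakage)
        in_fold = pearson_r(m1.predict(ds.sequences), ds.efficacies)
        out_fold = pearson_r(frame.pred1, ds.efficacies)
        assert out_fold <= in_fold + 1e-9

    def test_misaligned_columns_rejected(self):
        with pytest.raises(ValidationError, match="align"):
            StackingFrame(np.zeros(3), np.zeros(4), np.zeros(3), ("a", "b"))


class TestFusionMechanisms:
    @pytest.mark.parametrize("cls", [SVRFusion, NeuralNetFusion, GAWeightFusion])
    def test_perfect_component_limit(self, cls):
        rng = np.random.default_rng(0)
        y = rng.uniform(5, 95, 200)
        X = np.column_stack([y, rng.uniform(0, 100, 200)])
        f = cls(random_state=1).fit(X, y)
        assert pearson_r(f.predict(X), y) > 0.99

    def test_nn_reproducible_and_in_range(self):
        frame = _noisy_frame(5)
        a = NeuralNetFusion(random_state=3).fit(frame.X, frame.observed)
        b = NeuralNetFusion(random_state=3).fit(frame.X, frame.observed)
        assert np.array_equal(a.W1_, b.W1_) and np.array_equal(a.W2_, b.W2_)
        pred = a.predict(frame.X)
        assert pred.min() >= 0.0 and pred.max() <= 100.0

    def test_ga_degenerate_weights_pass_through(self):
        frame = _noisy_frame(6)
        f = GAWeightFusion(random_state=0)
        f.weights_ = np.array([1.0, 0.0])
        assert np.array_equal(f.predict(frame.X), frame.pred1)

    def test_ga_elitism_monotone_and_near_optimal(self):
        frame = _noisy_frame(7)
        ga = GAWeightFusion(generations=400, random_state=11).fit(
            frame.X, frame.observed
        )
        assert np.all(np.diff(ga.mse_trajectory_) <= 1e-12)
        assert ga.mse_ <= 1.05 * box_ls_mse(frame)
        assert 0.0 <= ga.weights_.min() and ga.weights_.max() <= 1.0

    def test_ga_parameter_validation(self):
        with pytest.raises(ValidationError, match="crossover_rate"):
            GAWeightFusion(crossover_rate=1.5)._validate()
        frame = _noisy_frame(8)
        with pytest.raises(ValidationError, match="zero-variance"):
            GAWeightFusion().fit(
                np.column_stack([np.ones(10), np.arange(10.0)]), np.arange(10.0)
            )

    def test_fusion_does_not_degrade_components(self):
        frame = _noisy_frame(9, n=250)
        best_component = max(
            pearson_r(frame.pred1, frame.observed),
            pearson_r(frame.pred2, frame.observed),
        )
        f = SVRFusion(random_state=0).fit(frame.X, frame.observed)
        fused = pearson_r(f.predict(frame.X), frame.observed)
        assert fused >= best_component - 0.05


@pytest.fixture(scope="module")
def data():
    tr = generate_synthetic(SyntheticSpec(200, 21, "gc_linear", 8.0, 20.0))
    te = generate_synthetic(SyntheticSpec(80, 22, "gc_linear", 8.0, 20.0))
    return tr, te


class TestTwoLayerPredictor:

    def test_fit_predict_deterministic(self, data):
        tr, te = data
        kwargs = dict(methods=("Binary", "F85"), fusion="svr", random_state=5)
        m1 = TwoLayerPredictor(**kwargs).fit(tr.sequences, tr.efficacies)
        m2 = TwoLayerPredictor(**kwargs).fit(tr.sequences, tr.efficacies)
        p1, p2 = m1.predict(te.sequences), m2.predict(te.sequences)
        assert np.array_equal(p1, p2)
        assert m1.pair_ == ("Binary", "F85")
        assert pearson_r(p1, te.efficacies) > 0.5

    def test_requires_both_categories(self, data):
        tr, _ = data
        with pytest.raises(ValidationError, match="sequence-type"):
            TwoLayerPredictor(methods=("Binary", "Hybrid")).fit(
                tr.sequences, tr.efficacies
            )

    def test_explicit_pair_must_be_sequence_feature(self, data):
        tr, _ = data
        m = TwoLayerPredictor(
            methods=("Binary", "F85"), pair=("F85", "Binary"), random_state=5
        )
        with pytest.raises(ValidationError, match="sequence"):
            m.fit(tr.sequences, tr.efficacies)

    def test_ga_fusion_records_trajectory(self, data):
        tr, te = data
        m = TwoLayerPredictor(
            methods=("Binary", "F85"),
            fusion="ga_linear",
            fusion_params={"generations": 200},
            random_state=5,
        ).fit(tr.sequences, tr.efficacies)
        assert len(m.fusion_.mse_trajectory_) == 201
        w = m.fusion_.weights_
        assert 0.0 <= w.min() and w.max() <= 1.0
        assert pearson_r(m.predict(te.sequences), te.efficacies) > 0.5
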