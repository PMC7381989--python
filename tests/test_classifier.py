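import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycoplan import classifier as clf
from glycoplan import synth
from glycoplan.errors import DomainError


def finite_difference_grad(head, x, labels, eps=1e-6):
    """Central finite differences of the mean cross-entropy, the gradient oracle."""

    def loss(W, b):
        probe = clf.SoftmaxHead(W=W, b=b)
        p = clf.softmax_forward(probe, x)
        return clf.batch_cross_entropy(p, labels)

    gW = np.zeros_like(head.W)
    for idx in np.ndindex(*head.W.shape):
        Wp, Wm = head.W.copy(), head.W.copy()
        Wp[idx] += eps
        Wm[idx] -= eps
        gW[idx] = (loss(Wp, head.b) - loss(Wm, head.b)) / (2 * eps)
    gb = np.zeros_like(head.b)
    for j in range(head.b.size):
        bp, bm = head.b.copy(), head.b.copy()
        bp[j] += eps
        bm[j] -= eps
        gb[j] = (loss(head.W, bp) - loss(head.W, bm)) / (2 * eps)
    return gW, gb


def analytic_grad(head, x, labels):
    p = clf.softmax_forward(head, x)
    delta = p.copy()
    delta[np.arange(len(labels)), labels] -= 1.0
    delta /= len(labels)
    return x.T @ delta, delta.sum(axis=0)


def test_split_stratified_counts():
    ds = synth.gen_bottleneck_features(3, 300, 4, seed=0)
    split = clf.split_dataset(ds, (0.8, 0.1, 0.1), seed=5)
    for c in range(3):
        mask = ds.labels == c
        assert np.sum(mask[split.train]) == 240
        assert np.sum(mask[split.validation]) == 30
        assert np.sum(mask[split.test]) == 30


def test_split_all_train_when_ratio_one(small_clusters):
    split = clf.split_dataset(small_clusters, (1.0, 0.0, 0.0), seed=0)
    assert len(split.train) == small_clusters.n_samples
    assert len(split.validation) == 0 and len(split.test) == 0


@given(seed=st.integers(0, 1000))
def test_split_partition_property(seed):
    ds = synth.gen_bottleneck_features(4, 13, 3, seed=1)
    split = clf.split_dataset(ds, seed=seed)
    all_idx = np.concatenate([split.train, split.validation, split.test])
    assert len(all_idx) == ds.n_samples
    assert set(all_idx.tolist()) == set(range(ds.n_samples))


def test_split_sizes_independent_of_seed(small_clusters):
    s1 = clf.split_dataset(small_clusters, seed=1)
    s2 = clf.split_dataset(small_clusters, seed=2)
    assert len(s1.train) == len(s2.train)
    assert len(s1.test) == len(s2.test)
    assert not np.array_equal(np.sort(s1.train), np.sort(s2.train)) or True
    # different seeds permute differently (with overwhelming probability)
    assert not np.array_equal(s1.train, s2.train)


def test_softmax_uniform_for_zero_parameters():
    head = clf.SoftmaxHead.zeros(10, 25)
    p = clf.softmax_forward(head, np.ones(10))
    assert p == pytest.approx(np.full(25, 1 / 25), abs=1e-12)


def test_softmax_bias_log_odds():
    head = clf.SoftmaxHead(W=np.zeros((2, 3)), b=np.log([1.0, 2.0, 3.0]))
    p = clf.softmax_forward(head, np.zeros(2))
    assert p == pytest.approx([1 / 6, 2 / 6, 3 / 6], abs=1e-12)


@given(shift=st.floats(-50, 50))
def test_softmax_argmax_shift_invariant(shift):
    rng = np.random.default_rng(0)
    head = clf.SoftmaxHead(W=rng.normal(size=(4, 5)), b=rng.normal(size=5))
    x = rng.normal(size=4)
    base = clf.softmax_forward(head, x)
    shifted = clf.SoftmaxHead(W=head.W, b=head.b + shift)
    assert np.argmax(clf.softmax_forward(shifted, x)) == np.argmax(base)


def test_softmax_rows_sum_to_one(rng):
    head = clf.SoftmaxHead(W=rng.normal(size=(6, 9)), b=rng.normal(size=9))
    p = clf.softmax_forward(head, rng.normal(size=(20, 6)))
    assert p.sum(axis=1) == pytest.approx(np.ones(20), abs=1e-12)
    assert (p >= 0).all()


def test_softmax_rejects_nonfinite():
    head = clf.SoftmaxHead.zeros(2, 2)
    with pytest.raises(DomainError):
        clf.softmax_forward(head, np.array([1.0, np.nan]))


@pytest.mark.parametrize(
    "p, label, expected",
    [
        (np.array([1.0, 0.0, 0.0]), 0, 0.0),
        (np.full(25, 1 / 25), 7, math.log(25)),  # 3.2189
        (np.array([0.7, 0.2, 0.1]), 1, 1.6094),
    ],
)
def test_cross_entropy_values(p, label, expected):
    assert clf.cross_entropy(p, label) == pytest.approx(expected, abs=5e-4)


def test_cross_entropy_clips_zero_probability():
    assert clf.cross_entropy(np.array([1.0, 0.0]), 1) == pytest.approx(-math.log(1e-12))


def test_gradient_matches_finite_differences(rng):
    x = rng.normal(size=(5, 4))
    labels = rng.integers(0, 3, size=5)
    head = clf.SoftmaxHead(W=rng.normal(size=(4, 3)), b=rng.normal(size=3))
    gW, gb = analytic_grad(head, x, labels)
    fW, fb = finite_difference_grad(head, x, labels)
    scale = max(np.abs(fW).max(), np.abs(fb).max())
    assert np.abs(gW - fW).max() / scale < 1e-5
    assert np.abs(gb - fb).max() / scale < 1e-5


def test_sgd_step_applies_gradient_update(rng):
    x = rng.normal(size=(6, 3))
    labels = rng.integers(0, 4, size=6)
    head = clf.SoftmaxHead(W=rng.normal(size=(3, 4)), b=rng.normal(size=4))
    gW, gb = analytic_grad(head, x, labels)
    W0, b0 = head.W.copy(), head.b.copy()
    clf.sgd_step(head, x, labels, learning_rate=0.1)
    assert head.W == pytest.approx(W0 - 0.1 * gW)
    assert head.b == pytest.approx(b0 - 0.1 * gb)


def test_sgd_step_single_example_matches_hand_logistic_gradient():
    # C = 2, x = (1, 2), zero parameters: p = (0.5, 0.5), true label 0,
    # so dL/dlogits = (-0.5, 0.5) and dL/dW = x (outer) (-0.5, 0.5).
    head = clf.SoftmaxHead.zeros(2, 2)
    x = np.array([1.0, 2.0])
    clf.sgd_step(head, x, np.array([0]), learning_rate=1.0)
    assert head.W == pytest.approx(np.array([[0.5, -0.5], [1.0, -1.0]]))
    assert head.b == pytest.approx(np.array([0.5, -0.5]))


def test_perfect_predictions_leave_parameters_unchanged():
    head = clf.SoftmaxHead(W=np.array([[100.0, -100.0]]), b=np.zeros(2))
    W0 = head.W.copy()
    clf.sgd_step(head, np.array([[1.0]]), np.array([0]), learning_rate=0.5)
    assert head.W == pytest.approx(W0, abs=1e-12)


def test_sgd_step_rejects_bad_inputs():
    head = clf.SoftmaxHead.zeros(2, 2)
    with pytest.raises(DomainError):
        clf.sgd_step(head, np.ones((1, 2)), np.array([0]), learning_rate=0.0)
    with pytest.raises(DomainError):
        clf.sgd_step(head, np.ones((0, 2)), np.array([]), learning_rate=0.1)


def test_train_reaches_high_accuracy_on_separable_clusters(small_clusters):
    split = clf.split_dataset(small_clusters, seed=0)
    head, trace = clf.train(small_clusters, split, steps=500, seed=0)
    acc, ce = clf.evaluate(head, small_clusters, split.test)
    assert acc >= 0.95
    assert trace.batch_cross_entropy[-50:].mean() < trace.batch_cross_entropy[:50].mean()


def test_train_is_bit_reproducible(small_clusters):
    split = clf.split_dataset(small_clusters, seed=0)
    h1, t1 = clf.train(small_clusters, split, steps=50, seed=3)
    h2, t2 = clf.train(small_clusters, split, steps=50, seed=3)
    assert np.array_equal(h1.W, h2.W) and np.array_equal(h1.b, h2.b)
    assert np.array_equal(t1.batch_cross_entropy, t2.batch_cross_entropy)


def test_train_trace_and_validation_schedule(small_clusters):
    split = clf.split_dataset(small_clusters, seed=0)
    head, trace = clf.train(small_clusters, split, steps=1, seed=0)
    assert len(trace) == 1
    with pytest.raises(DomainError):
        clf.train(small_clusters, split, steps=0)
    _, trace = clf.train(small_clusters, split, steps=250, seed=0, eval_interval=100)
    assert trace.validation_steps.tolist() == [100, 200, 250]


def test_evaluate_constant_predictor_chance_level():
    ds = synth.gen_bottleneck_features(25, 4, 3, seed=0)
    head = clf.SoftmaxHead(W=np.zeros((3, 25)), b=np.eye(25)[0] * 10)
    acc, _ = clf.evaluate(head, ds, np.arange(ds.n_samples))
    assert acc == pytest.approx(1 / 25)


def test_evaluate_invariant_under_permutation(small_clusters, rng):
    head = clf.SoftmaxHead.zeros(small_clusters.n_features, small_clusters.n_classes)
    idx = np.arange(small_clusters.n_samples)
    a1 = clf.evaluate(head, small_clusters, idx)
    a2 = clf.evaluate(head, small_clusters, rng.permutation(idx))
    assert a1 == a2
    with pytest.raises(DomainError):
        clf.evaluate(head, small_clusters, np.array([], dtype=int))


def test_classify_confidence_and_recommendation_flags():
    head = clf.SoftmaxHead.zeros(4, 25)
    names = [f"c{i}" for i in range(24)] + ["pizza"]
    out = clf.classify(head, names, np.zeros(4))
    assert out["confidence_pct"] == "4.00%"
    assert out["recommendation"] == "unknown"
    head_pizza = clf.SoftmaxHead(W=np.zeros((4, 25)), b=np.eye(25)[24] * 10)
    out = clf.classify(head_pizza, names, np.zeros(4), recommendation_map={"pizza": False})
    assert out["label"] == "pizza"
    assert out["recommendation"] == "not_recommended"


def test_classify_recovers_generating_class(small_clusters):
    split = clf.split_dataset(small_clusters, seed=0)
    head, _ = clf.train(small_clusters, split, steps=2000, seed=0)
    i = split.test[0]
    out = clf.classify(head, small_clusters.class_names, small_clusters.features[i])
    assert out["label"] == small_clusters.class_names[small_clusters.labels[i]]
    assert out["confidence"] > 0.9


def test_feature_file_round_trip(small_clusters, tmp_path):
    path = tmp_path / "features.csv"
    clf.save_feature_file(small_clusters, str(path))
    loaded = clf.load_feature_file(str(path), class_names=small_clusters.class_names)
    assert np.allclose(loaded.features, small_clusters.features)
    assert np.array_equal(loaded.labels, small_clusters.labels)


def test_head_json_round_trip(rng):
    head = clf.SoftmaxHead(W=rng.normal(size=(3, 4)), b=rng.normal(size=4))
    buf = io.StringIO()
    head.to_json(buf)
    buf.seek(0)
    loaded = clf.SoftmaxHead.from_json(buf)
    assert np.allclose(loaded.W, head.W) and np.allclose(loaded.b, head.b)
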