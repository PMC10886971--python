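"""Network arithmetic, gradients, training behavior, and evaluation metrics."""

import numpy as np
import pytest

from ripplecam import (
    CnnArchitecture,
    RippleEpisodeCNN,
    RippleError,
    TrainingConfig,
    cross_entropy,
    forward,
    metrics_from_confusion,
    split_dataset,
    zero_pad,
)
from ripplecam.cnn import init_params, loss_and_grads, one_hot
from conftest import make_wave

TEST_CONFUSION = np.array(
    [[7, 1, 2, 0, 0],
     [2, 6, 0, 0, 2],
     [1, 1, 7, 0, 1],
     [0, 1, 0, 8, 1],
     [1, 0, 1, 0, 8]]
)


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def test_default_architecture_layer_sizes():
    a = CnnArchitecture()
    assert a.conv_out_len == 171
    assert a.pool_out_len == 33
    assert a.flatten_size == 4224


def test_degenerate_architecture_rejected():
    with pytest.raises(RippleError):
        CnnArchitecture(input_len=100, conv_kernel=500)


# ---------------------------------------------------------------------------
# forward / loss
# ---------------------------------------------------------------------------

def test_forward_outputs_probabilities(toy_arch):
    params = init_params(toy_arch, seed=0, dtype=np.float64)
    X = np.random.default_rng(0).normal(size=(6, toy_arch.input_len))
    p = forward(params, X, toy_arch)
    assert p.shape == (6, toy_arch.n_classes)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(p >= 0)


def test_zero_weights_give_uniform_output(toy_arch):
    params = {k: np.zeros_like(v) for k, v in init_params(toy_arch).items()}
    X = np.random.default_rng(1).normal(size=(3, toy_arch.input_len))
    np.testing.assert_allclose(forward(params, X, toy_arch),
                               1.0 / toy_arch.n_classes, atol=1e-12)


def test_forward_rejects_wrong_length(toy_arch):
    params = init_params(toy_arch)
    with pytest.raises(RippleError):
        forward(params, np.zeros((2, toy_arch.input_len + 1)), toy_arch)


def test_cross_entropy_anchors():
    assert cross_entropy(np.array([1.0, 0, 0]), np.array([1.0, 0, 0])) == 0.0
    uniform = np.full(5, 0.2)
    target = np.eye(5)[2]
    assert cross_entropy(uniform, target) == pytest.approx(np.log(5))
    batch = np.stack([uniform, uniform])
    targets = np.stack([target, target])
    assert cross_entropy(batch, targets) == pytest.approx(np.log(5))


def test_cross_entropy_clamps_zero_probability():
    p = np.array([[0.0, 1.0]])
    t = np.array([[1.0, 0.0]])
    val = cross_entropy(p, t)
    assert np.isfinite(val) and val > 20  # -ln(1e-12) ~ 27.6


# ---------------------------------------------------------------------------
# gradients vs finite differences
# ---------------------------------------------------------------------------

def test_parameter_gradients_match_finite_differences(toy_arch):
    """Backprop gradient of every parameter agrees with central differences."""
    rng = np.random.default_rng(5)
    params = init_params(toy_arch, seed=2, dtype=np.float64)
    X = rng.normal(size=(20, toy_arch.input_len))
    y = rng.integers(0, toy_arch.n_classes, size=20)
    _, grads = loss_and_grads(params, X, y, toy_arch)
    eps = 1e-6
    for name, g in grads.items():
        flat = params[name].ravel()
        # probe a subset of coordinates of each parameter tensor
        probe = rng.choice(flat.size, size=min(25, flat.size), replace=False)
        for idx in probe:
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = loss_and_grads(params, X, y, toy_arch)
            flat[idx] = orig - eps
            lm, _ = loss_and_grads(params, X, y, toy_arch)
            flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            gi = g.ravel()[idx]
            denom = max(abs(fd), abs(gi), 1e-8)
            assert abs(fd - gi) / denom < 1e-4, f"{name}[{idx}]: {fd} vs {gi}"


def test_full_batch_descent_is_monotone(toy_arch):
    """With one full-gradient batch and a small step, loss never increases."""
    rng = np.random.default_rng(8)
    n = 12
    X = rng.normal(size=(n, toy_arch.input_len))
    y = rng.integers(0, toy_arch.n_classes, size=n)
    model = RippleEpisodeCNN(X, y, architecture=toy_arch, init_seed=1,
                             dtype=np.float64)
    cfg = TrainingConfig(batch_size=n, epochs=30, learning_rate=1e-3,
                         momentum=0.0, weight_decay=0.0,
                         shuffle_each_epoch=False, seed=0)
    res = model.fit(cfg)
    losses = res.history["loss"].to_numpy()
    assert np.all(np.diff(losses) <= 1e-10)


# ---------------------------------------------------------------------------
# training behavior
# ---------------------------------------------------------------------------

def _toy_two_class(n_per=20, seed=0):
    """Two classes with strong fixed motifs at random positions."""
    rng = np.random.default_rng(seed)
    arch = CnnArchitecture(input_len=120, conv_filters=8, conv_kernel=30,
                           conv_stride=5, pool_size=4, pool_stride=2,
                           fc_hidden=16, n_classes=2)
    trng = np.random.default_rng(99)
    motifs = [trng.normal(size=30), trng.normal(size=30)]
    X, y = [], []
    for cls in (0, 1):
        for _ in range(n_per):
            x = rng.normal(0, 0.2, size=120)
            pos = rng.integers(0, 120 - 30)
            x[pos : pos + 30] += motifs[cls]
            X.append(x)
            y.append(cls)
    return arch, np.array(X), np.array(y)


def test_separable_toy_problem_is_learned():
    arch, X, y = _toy_two_class()
    model = RippleEpisodeCNN(X, y, architecture=arch, init_seed=0)
    cfg = TrainingConfig(batch_size=8, epochs=120, learning_rate=0.01,
                         momentum=0.5, weight_decay=0.0005, seed=1)
    res = model.fit(cfg)
    assert res.history.shape[0] == 120
    assert res.history["accuracy"].iloc[-1] >= 0.99


def test_training_is_reproducible():
    arch, X, y = _toy_two_class()
    cfg = TrainingConfig(batch_size=8, epochs=5, learning_rate=0.01, seed=3)
    r1 = RippleEpisodeCNN(X, y, architecture=arch, init_seed=2).fit(cfg)
    r2 = RippleEpisodeCNN(X, y, architecture=arch, init_seed=2).fit(cfg)
    assert r1.history.equals(r2.history)
    for k in r1.params:
        np.testing.assert_array_equal(r1.params[k], r2.params[k])


def test_batch_size_must_fit():
    arch, X, y = _toy_two_class(n_per=3)
    model = RippleEpisodeCNN(X, y, architecture=arch)
    with pytest.raises(RippleError):
        model.fit(TrainingConfig(batch_size=64, epochs=1))


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def _padded_events(counts, seed=0):
    rng = np.random.default_rng(seed)
    evs = []
    for cat, cnt in counts.items():
        for i in range(cnt):
            w = make_wave(rng.normal(size=1000), id=f"{cat}{i}", category=cat,
                          stage="standardized")
            evs.append(zero_pad(w))
    return evs


def test_split_is_stratified_and_deterministic():
    evs = _padded_events({"Restraint": 15, "Female": 12, "Before": 30})
    tr, te = split_dataset(evs, test_per_category=4, seed=1)
    assert len(te) == 12 and len(tr) == len(evs) - 12
    from collections import Counter
    assert set(Counter(e.category for e in te).values()) == {4}
    assert {e.id for e in tr}.isdisjoint({e.id for e in te})
    tr2, te2 = split_dataset(evs, test_per_category=4, seed=1)
    assert [e.id for e in te2] == [e.id for e in te]


def test_split_guards_empty_training_class():
    evs = _padded_events({"Restraint": 10, "Female": 15})
    with pytest.raises(RippleError):
        split_dataset(evs, test_per_category=10, seed=0)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def test_published_confusion_matrix_metrics():
    """The printed 5x5 test confusion matrix yields 72% accuracy and equal
    micro precision / balanced accuracy / micro F1."""
    r = metrics_from_confusion(TEST_CONFUSION)
    assert r.accuracy == pytest.approx(0.72)
    assert r.micro_precision == pytest.approx(0.72)
    assert r.balanced_accuracy == pytest.approx(0.72)
    assert r.micro_f1 == pytest.approx(0.72)


def test_perfect_predictions():
    r = metrics_from_confusion(np.diag([10, 10, 10, 10, 10]))
    assert r.accuracy == r.balanced_accuracy == r.micro_f1 == 1.0


def test_micro_metrics_equal_accuracy_on_random_matrices():
    rng = np.random.default_rng(4)
    for _ in range(20):
        cm = rng.integers(0, 30, size=(5, 5))
        cm[np.arange(5), np.arange(5)] += 1  # keep non-degenerate
        r = metrics_from_confusion(cm)
        assert r.micro_precision == r.micro_recall == r.micro_f1 == r.accuracy
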