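"""Learning-rate schedule, training loop reproducibility, evaluation and
Grad-CAM."""

import numpy as np
import pytest

from ehfrnet import (SyntheticSpec, TrainConfig, build_network,
                     generate_dataset, evaluate, load_image_folder,
                     lr_at_step, train)
from ehfrnet.nn.autograd import Tensor
from ehfrnet.nn.layers import GlobalAvgPool2d, Linear, Module
from ehfrnet.training import MetricLog, cross_entropy, gradcam

from oracles import gradcam_linear_oracle


SHORT = dict(batch_size=8, resolution=64, warmup_iterations=5,
             total_iterations=30, seed=3)


@pytest.fixture(scope="module")
def small_corpus(tmp_path_factory):
    root = tmp_path_factory.mktemp("train") / "corpus"
    generate_dataset(SyntheticSpec(image_size=32, num_classes=3,
                                   samples_per_class=8, jitter=1.0,
                                   noise_sigma=0.02, seed=13), root)
    return root


# ------------------------------------------------------------- schedule ----

def test_schedule_starts_at_warmup_floor():
    assert lr_at_step(0, TrainConfig()) == pytest.approx(1e-6)


def test_schedule_reaches_maximum_at_warmup_end():
    cfg = TrainConfig()
    assert lr_at_step(cfg.warmup_iterations, cfg) == pytest.approx(0.002)


def test_schedule_terminal_value():
    cfg = TrainConfig()
    assert lr_at_step(cfg.total_iterations, cfg) == pytest.approx(0.0002)


def test_schedule_continuous_at_junction():
    cfg = TrainConfig()
    before = lr_at_step(cfg.warmup_iterations - 1, cfg)
    at = lr_at_step(cfg.warmup_iterations, cfg)
    after = lr_at_step(cfg.warmup_iterations + 1, cfg)
    assert abs(at - before) < 1e-6 and abs(after - at) < 1e-9 * 1e6
    assert before < at


def test_schedule_monotone_anneal_and_range():
    cfg = TrainConfig(total_iterations=40_000)
    values = [lr_at_step(s, cfg) for s in range(cfg.warmup_iterations,
                                                cfg.total_iterations, 997)]
    assert all(a >= b for a, b in zip(values, values[1:]))
    assert all(cfg.cosine_lr_min <= v <= cfg.cosine_lr_max for v in values)


def test_schedule_step_out_of_range_is_an_error():
    cfg = TrainConfig()
    with pytest.raises(ValueError):
        lr_at_step(-1, cfg)
    with pytest.raises(ValueError):
        lr_at_step(cfg.total_iterations + 1, cfg)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        TrainConfig(warmup_start_lr=0.01)        # above cosine range
    with pytest.raises(ValueError):
        TrainConfig(warmup_iterations=10, total_iterations=5)


# ------------------------------------------------------------- training ----

def test_short_training_run_reduces_loss(small_corpus):
    data = load_image_folder(small_corpus, resolution=64, mode="train")
    model = build_network(alpha=0.5, num_classes=3, seed=1)
    log = train(model, data, TrainConfig(**SHORT))
    assert len(log.losses) == SHORT["total_iterations"]
    assert np.mean(log.losses[-5:]) < np.mean(log.losses[:5])


def test_training_is_seed_reproducible(small_corpus):
    losses = []
    for _ in range(2):
        data = load_image_folder(small_corpus, resolution=64, mode="train")
        model = build_network(alpha=0.5, num_classes=3, seed=1)
        cfg = TrainConfig(**{**SHORT, "total_iterations": 8})
        losses.append(train(model, data, cfg).losses)
    assert losses[0] == losses[1]


def test_zero_iterations_writes_initial_checkpoint_only(small_corpus,
                                                        tmp_path):
    data = load_image_folder(small_corpus, resolution=64, mode="train")
    model = build_network(alpha=0.5, num_classes=3, seed=1)
    cfg = TrainConfig(**{**SHORT, "total_iterations": 0})
    log = train(model, data, cfg, out_dir=tmp_path)
    assert (tmp_path / "initial.npz").exists()
    assert not (tmp_path / "last.npz").exists()
    assert log.losses == [] and log.iterations == []


def test_class_count_mismatch_is_an_error(small_corpus):
    data = load_image_folder(small_corpus, resolution=64, mode="train")
    model = build_network(alpha=0.5, num_classes=7, seed=1)
    with pytest.raises(ValueError, match="classes"):
        train(model, data, TrainConfig(**SHORT))


def test_metric_log_requires_increasing_iterations():
    log = MetricLog()
    log.append(1, 0.5, 1e-3)
    with pytest.raises(ValueError, match="increasing"):
        log.append(1, 0.4, 1e-3)


def test_cross_entropy_with_smoothing_is_finite_and_positive(rng):
    logits = Tensor(rng.normal(size=(4, 5)).astype(np.float32),
                    requires_grad=True)
    loss = cross_entropy(logits, np.array([0, 1, 2, 3]), 0.1)
    assert float(loss.data) > 0
    loss.backward()
    np.testing.assert_allclose(logits.grad.sum(axis=1), 0.0, atol=1e-6)


# ------------------------------------------------------------ evaluation ---

class StubModel(Module):
    """Returns pre-set logits row by row, for metric arithmetic tests."""

    def __init__(self, logits):
        super().__init__()
        self.logits = np.asarray(logits, dtype=np.float32)
        self.cursor = 0

    def forward(self, x):
        n = x.shape[0]
        out = self.logits[self.cursor:self.cursor + n]
        self.cursor += n
        return Tensor(out)


def test_evaluate_counts_argmax_matches(small_corpus):
    ds = load_image_folder(small_corpus, resolution=32)
    labels = ds.labels
    # 2 of the first 4 correct, everything else wrong
    logits = np.zeros((len(ds), 3), dtype=np.float32)
    for i, lab in enumerate(labels):
        if i < 2:
            logits[i, lab] = 1.0            # correct
        else:
            logits[i, (lab + 1) % 3] = 1.0  # wrong
    acc = evaluate(StubModel(logits), ds)
    assert acc == pytest.approx(100.0 * 2 / len(ds))


def test_evaluate_perfect_oracle_scores_100(small_corpus):
    ds = load_image_folder(small_corpus, resolution=32)
    onehot = np.eye(3, dtype=np.float32)[ds.labels]
    assert evaluate(StubModel(onehot), ds) == 100.0


def test_evaluate_empty_dataset_is_an_error(small_corpus):
    ds = load_image_folder(small_corpus, resolution=32)
    ds.samples = []
    with pytest.raises(ValueError, match="empty"):
        evaluate(StubModel(np.zeros((0, 3))), ds)


def test_evaluate_ties_resolve_to_lowest_index():
    class TiedData:
        labels = np.array([0, 2])

        def __len__(self):
            return 2

        def batches(self, batch_size):
            yield np.zeros((2, 3, 8, 8), dtype=np.float32), self.labels

    tied = np.zeros((2, 3), dtype=np.float32)   # all logits equal
    acc = evaluate(StubModel(tied), TiedData())
    assert acc == pytest.approx(50.0)           # index 0 wins both ties


# -------------------------------------------------------------- Grad-CAM ---

class ToyLinearConv(Module):
    """conv1x1 -> GAP -> linear; used for the closed-form heatmap oracle."""

    def __init__(self, rng):
        super().__init__()
        from ehfrnet.nn.layers import Conv2d
        self.conv = Conv2d(3, 5, 1, rng=rng)
        self.pool = GlobalAvgPool2d()
        self.head = Linear(5, 4, rng=rng)

    def layer_names(self):
        return ["feat"]

    def forward(self, x, capture=None):
        y = self.conv(x)
        if capture is not None:
            capture["feat"] = y
        return self.head(self.pool(y))


def test_gradcam_matches_linear_model_oracle(rng):
    model = ToyLinearConv(np.random.default_rng(0))
    x = rng.normal(size=(1, 3, 6, 6)).astype(np.float32)
    cam = gradcam(model, x, target_class=2, layer_name="feat")
    act = model.conv(Tensor(x)).data[0]
    want = gradcam_linear_oracle(act, model.head.weight.data, 2)
    np.testing.assert_allclose(cam, want, rtol=1e-5, atol=1e-5)


def test_gradcam_range_and_shape(rng):
    model = build_network(alpha=0.5, num_classes=3, seed=2)
    x = rng.normal(size=(3, 64, 64)).astype(np.float32)
    cam = gradcam(model, x, target_class=1, layer_name="group4")
    assert cam.shape == (64, 64)
    assert cam.min() >= 0.0 and cam.max() <= 1.0


def test_gradcam_unknown_layer_lists_available(rng):
    model = build_network(alpha=0.5, num_classes=3, seed=2)
    x = rng.normal(size=(3, 64, 64)).astype(np.float32)
    with pytest.raises(ValueError, match="group5"):
        gradcam(model, x, target_class=0, layer_name="nope")
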