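import numpy as np
import pytest

from vstseg.model import VSTConfig, VSTNet
from vstseg.nn import Tensor
from vstseg.phantom import PhantomSpec, generate_dataset
from vstseg.training import (
    TrainConfig,
    cross_entropy_loss,
    dice_loss,
    evaluate_dsc,
    foreground_dsc,
    make_folds,
    prepare_inputs,
    run_crossval,
    total_loss,
    train_model,
)

RNG = np.random.default_rng(31)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_dice_loss_near_zero_for_confident_correct_prediction():
    target = RNG.integers(0, 3, size=(1, 8, 8))
    scores = np.full((1, 3, 8, 8), -50.0)
    for c in range(3):
        scores[0, c][target[0] == c] = 50.0
    assert float(dice_loss(scores, target).data) < 1e-4


def test_dice_loss_uniform_binary_is_half():
    """Uniform probabilities on a balanced binary target: dice = 0.5 per the
    linear-denominator definition, so the loss is 0.5."""
    target = np.zeros((1, 4, 4), dtype=np.int64)
    target[0, :2] = 1  # half foreground
    scores = np.zeros((1, 2, 4, 4))
    assert float(dice_loss(scores, target).data) == pytest.approx(0.5, abs=1e-5)


def test_dice_loss_excludes_background():
    """An all-background target with uniform predictions still has a defined
    loss driven by the foreground class's zero overlap."""
    target = np.zeros((1, 4, 4), dtype=np.int64)
    scores = np.zeros((1, 2, 4, 4))
    # class 1: inter=0, denom = 8 (predicted mass) + 0 -> dice ~ eps/8
    assert float(dice_loss(scores, target).data) == pytest.approx(1.0, abs=1e-4)


def test_dice_loss_spatial_permutation_invariance():
    scores = RNG.normal(size=(1, 3, 4, 4))
    target = RNG.integers(0, 3, size=(1, 4, 4))
    perm = RNG.permutation(16)
    sp = scores.reshape(1, 3, 16)[:, :, perm].reshape(1, 3, 4, 4)
    tp = target.reshape(1, 16)[:, perm].reshape(1, 4, 4)
    assert float(dice_loss(scores, target).data) == pytest.approx(
        float(dice_loss(sp, tp).data), abs=1e-12)


def test_dice_loss_rejects_bad_labels():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((1, 2, 2, 2)), np.full((1, 2, 2), 5))


def test_cross_entropy_uniform_equals_log_n_classes():
    for c in (2, 7):
        scores = np.zeros((1, c, 3, 3))
        target = RNG.integers(0, c, size=(1, 3, 3))
        assert float(cross_entropy_loss(scores, target).data) == pytest.approx(
            np.log(c), abs=1e-12)


def test_cross_entropy_matches_hand_computation():
    scores = RNG.normal(size=(1, 3, 2, 2))
    target = RNG.integers(0, 3, size=(1, 2, 2))
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    logp = np.log(e / e.sum(axis=1, keepdims=True))
    expected = -np.mean([logp[0, target[0, i, j], i, j]
                         for i in range(2) for j in range(2)])
    assert float(cross_entropy_loss(scores, target).data) == pytest.approx(
        expected, abs=1e-12)


def test_cross_entropy_gradient_sign():
    """The gradient pushes the target class's score up."""
    scores = Tensor(np.zeros((1, 3, 1, 1)), requires_grad=True)
    target = np.array([[[2]]])
    cross_entropy_loss(scores, target).backward()
    assert scores.grad[0, 2, 0, 0] < 0  # descending increases score of class 2
    assert scores.grad[0, 0, 0, 0] > 0


def test_total_loss_additivity_exact():
    scores = Tensor(RNG.normal(size=(2, 4, 8, 8)))
    aux = [Tensor(RNG.normal(size=(2, 4, 4, 4))),
           Tensor(RNG.normal(size=(2, 4, 2, 2)))]
    target = RNG.integers(0, 4, size=(2, 8, 8))
    total, terms = total_loss(scores, target, aux, (0.5, 0.25))
    recon = terms.l_dice + terms.l_ce + sum(
        w * l for w, l in zip(terms.aux_weights, terms.l_aux))
    assert terms.l_total == pytest.approx(recon, rel=1e-12)
    assert float(total.data) == terms.l_total


def test_total_loss_weight_count_mismatch_raises():
    scores = Tensor(np.zeros((1, 2, 4, 4)))
    aux = [Tensor(np.zeros((1, 2, 2, 2)))]
    with pytest.raises(ValueError):
        total_loss(scores, np.zeros((1, 4, 4), dtype=int), aux, ())


def test_foreground_dsc_hand_case():
    pred = np.zeros((4, 4), dtype=int)
    ref = np.zeros((4, 4), dtype=int)
    pred[:2, :2] = 1  # 4 voxels
    ref[:2, :3] = 1   # 6 voxels, overlap 4
    assert foreground_dsc(pred, ref) == pytest.approx(2 * 4 / (4 + 6))
    assert foreground_dsc(ref, ref) == 1.0


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_make_folds_partitions_exactly():
    split = make_folds(23, 5, seed=0)
    sizes = [len(split.fold_items(f)) for f in range(5)]
    assert sum(sizes) == 23 and max(sizes) - min(sizes) <= 1
    for f in range(5):
        tr, va = split.train_val(f)
        assert len(np.intersect1d(tr, va)) == 0
        assert np.array_equal(np.sort(np.concatenate([tr, va])), np.arange(23))


def test_make_folds_deterministic_and_repeat_dependent():
    a = make_folds(20, 5, seed=3, repeat_index=1)
    b = make_folds(20, 5, seed=3, repeat_index=1)
    c = make_folds(20, 5, seed=3, repeat_index=2)
    assert np.array_equal(a.assignments, b.assignments)
    assert not np.array_equal(a.assignments, c.assignments)


def test_make_folds_too_few_items_raises():
    with pytest.raises(ValueError):
        make_folds(3, 5, seed=0)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [{"epochs": 0}, {"batch_size": 0}, {"learning_rate": 0.0},
     {"aux_loss_weights": (1.5,)}],
)
def test_train_config_validation(kwargs):
    with pytest.raises(ValueError):
        TrainConfig(**kwargs)


def test_train_config_schedule():
    cfg = TrainConfig()
    assert (cfg.epochs, cfg.iterations_per_epoch, cfg.batch_size) == (1000, 250, 12)
    assert (cfg.learning_rate, cfg.optimizer_momentum) == (0.01, 0.1)
    assert cfg.total_steps == 250_000


_TINY_MODEL = dict(stages=2, base_channels=4, input_size=(64, 64), mode="unet",
                   depth=1, heads=1)


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_dataset(PhantomSpec(seed=21, noise_sd=0.0), 4, seed=21)


def test_initial_loss_is_chance_level(tiny_dataset):
    """With zero-initialised heads the first CE term is exactly ln(7)."""
    cfg = TrainConfig(learning_rate=3e-3, batch_size=2, seed=0)
    _, hist = train_model(tiny_dataset, VSTConfig(**_TINY_MODEL), cfg, steps=1)
    assert hist[0].l_ce == pytest.approx(np.log(7), abs=1e-5)
    recon = hist[0].l_dice + hist[0].l_ce + sum(
        w * l for w, l in zip(hist[0].aux_weights, hist[0].l_aux))
    assert hist[0].l_total == pytest.approx(recon, rel=1e-6)


def test_training_is_deterministic_and_loss_decreases(tiny_dataset):
    cfg = TrainConfig(learning_rate=3e-3, batch_size=2, seed=1)
    mcfg = VSTConfig(**_TINY_MODEL)
    m1, h1 = train_model(tiny_dataset, mcfg, cfg, steps=20)
    m2, h2 = train_model(tiny_dataset, mcfg, cfg, steps=20)
    assert [t.l_total for t in h1] == [t.l_total for t in h2]
    for p1, p2 in zip(m1.parameters(), m2.parameters()):
        np.testing.assert_array_equal(p1.data, p2.data)
    assert np.mean([t.l_total for t in h1[-5:]]) < h1[0].l_total


def test_train_model_requires_samples():
    with pytest.raises(ValueError):
        train_model([], VSTConfig(**_TINY_MODEL), TrainConfig())


def test_run_crossval_bookkeeping(tiny_dataset):
    samples = tiny_dataset + generate_dataset(PhantomSpec(seed=77, noise_sd=0.0),
                                              4, seed=77)
    cfg = TrainConfig(learning_rate=3e-3, batch_size=2, seed=0)
    report = run_crossval(samples, VSTConfig(**_TINY_MODEL), cfg,
                          k=4, repeats=2, steps=2)
    assert report["k"] == 4 and report["repeats"] == 2
    assert len(report["per_repeat"]) == 2
    repeat_means = []
    for rep in report["per_repeat"]:
        assign = np.asarray(rep["assignments"])
        # exact partition: every item in exactly one fold, sizes equal
        assert np.array_equal(np.sort(np.unique(assign)), np.arange(4))
        assert all((assign == f).sum() == 2 for f in range(4))
        fold_dscs = [f["val_dsc"] for f in rep["folds"]]
        assert rep["mean_dsc"] == pytest.approx(np.mean(fold_dscs), rel=1e-12)
        repeat_means.append(rep["mean_dsc"])
    assert report["mean_dsc"] == pytest.approx(np.mean(repeat_means), rel=1e-12)
    # different repeats use different partitions
    a0 = report["per_repeat"][0]["assignments"]
    a1 = report["per_repeat"][1]["assignments"]
    assert a0 != a1


def test_evaluate_dsc_perfect_oracle(tiny_dataset):
    images, masks, _ = prepare_inputs(tiny_dataset[:2], need_saliency=False)

    class Oracle:
        def predict_labels(self, img, sal=None):
            i = [np.array_equal(img[0], im) for im in images].index(True)
            return masks[i][None]

    assert evaluate_dsc(Oracle(), images, masks) == 1.0
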