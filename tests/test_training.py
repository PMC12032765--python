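"""Training-protocol semantics: loss, scheduling, early stopping,
checkpointing, and learning sanity on an easy phantom cohort."""

import numpy as np
import pytest

from fusionbench.fusion import FusionConfig, build_model
from fusionbench.nn.optim import one_cycle_lr
from fusionbench.training import (SliceSampler, TrainProtocol, TrainRecord,
                                  dice_loss, evaluate_pairs, fit,
                                  load_checkpoint, save_checkpoint,
                                  train_model, validation_loss)


class TestDiceLoss:
    def test_perfect_prediction_is_eps_order(self):
        t = np.array([1.0, 0.0, 1.0, 1.0])
        assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-5)

    def test_complement_prediction_is_near_one(self):
        t = np.array([1.0, 0.0, 0.0, 1.0])
        assert dice_loss(1 - t, t) == pytest.approx(1.0, abs=1e-4)

    def test_hand_evaluated_soft_dice(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        t = np.array([1.0, 0.0, 0.0, 0.0])
        want = 1.0 - (2.0 * 1.0 + 1e-5) / (2.0 + 1.0 + 1e-5)
        assert dice_loss(p, t, eps=1e-5) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(1 / 3, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros(3), np.zeros(4))


class _StubModel:
    """Tiny quadratic model exposing the trainable interface."""

    def __init__(self, n_params: int = 100):
        self.params = {"w": np.zeros(n_params)}

    def loss_and_grads(self, xr, xs, t):
        w = self.params["w"]
        return float((w ** 2).sum()) + 0.1, {"w": 2 * w}

    def get_params(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, p):
        self.params = {k: np.array(v) for k, v in p.items()}


def _dummy_batch(size):
    return None, None, None


class TestEarlyStopping:
    def test_constant_validation_loss_stops_at_batch_520(self):
        """First validation at batch 20 is best; no later improvement, so
        training stops when batch - best >= 500, i.e. exactly at 520."""
        protocol = TrainProtocol(total_batches=16_000, val_every=20,
                                 patience_batches=500)
        rec = fit(_StubModel(), _dummy_batch, protocol,
                  validate_fn=lambda m: 0.7)
        assert rec.stopped_early
        assert rec.best_batch == 20
        assert rec.history[-1][0] == 520
        assert len(rec.history) == 26

    def test_strictly_improving_runs_to_horizon(self):
        protocol = TrainProtocol(total_batches=200, val_every=20,
                                 patience_batches=100)
        losses = iter(np.linspace(1.0, 0.1, 10))
        rec = fit(_StubModel(), _dummy_batch, protocol,
                  validate_fn=lambda m: float(next(losses)))
        assert not rec.stopped_early
        assert rec.best_batch == 200

    def test_patience_equal_to_horizon_never_stops_early(self):
        protocol = TrainProtocol(total_batches=300, val_every=20,
                                 patience_batches=300)
        rec = fit(_StubModel(), _dummy_batch, protocol,
                  validate_fn=lambda m: 0.5)
        assert not rec.stopped_early
        assert rec.history[-1][0] == 300

    def test_best_batch_is_earliest_argmin_on_ties(self):
        protocol = TrainProtocol(total_batches=200, val_every=20,
                                 patience_batches=200)
        seq = iter([0.9, 0.3, 0.8, 0.3, 0.3, 0.7, 0.9, 0.9, 0.9, 0.9])
        rec = fit(_StubModel(), _dummy_batch, protocol,
                  validate_fn=lambda m: float(next(seq)))
        assert rec.best_batch == 40
        assert rec.best_val_loss == pytest.approx(0.3)

    def test_nan_validation_aborts(self):
        protocol = TrainProtocol(total_batches=100, val_every=20,
                                 patience_batches=100)
        with pytest.raises(RuntimeError, match="non-finite"):
            fit(_StubModel(), _dummy_batch, protocol,
                validate_fn=lambda m: float("nan"))

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            TrainProtocol(val_every=100, patience_batches=50)
        with pytest.raises(ValueError):
            TrainProtocol(total_batches=10, val_every=20)


def test_best_weights_are_restored_after_fit():
    """The model must hold the weights of the best validation step, not the
    last ones."""
    protocol = TrainProtocol(total_batches=100, val_every=20,
                             patience_batches=100)
    model = _StubModel(5)
    snaps = []
    seq = iter([0.5, 0.2, 0.6, 0.7, 0.8])

    def val(m):
        m.params["w"] += 1.0          # weights drift between validations
        snaps.append(m.get_params()["w"].copy())
        return float(next(seq))

    fit(model, _dummy_batch, protocol, validate_fn=val)
    np.testing.assert_array_equal(model.params["w"], snaps[1])


def test_one_cycle_schedule_shape():
    total, max_lr = 1000, 3e-3
    lrs = [one_cycle_lr(s, total, max_lr, warmup_frac=0.3)
           for s in range(total)]
    peak = int(np.argmax(lrs))
    assert peak == pytest.approx(300, abs=1)
    assert max(lrs) == pytest.approx(max_lr)
    assert lrs[0] == pytest.approx(max_lr / 25)
    assert lrs[-1] < max_lr / 100
    # monotone up then down
    assert all(np.diff(lrs[:peak]) >= 0)
    assert all(np.diff(lrs[peak:]) <= 0)


@pytest.fixture(scope="module")
def easy_cohort():
    """High-contrast, perfectly aligned phantoms: a segmentation task any
    working training loop must solve."""
    from fusionbench.phantom import PhantomParams, generate_pair
    from fusionbench.preprocess import preprocess_pair

    p = PhantomParams(deform_amplitude=0.0, interleave_shift=0.0, seed=1)
    return [preprocess_pair(generate_pair(
        p, f"s{i:02d}", "ses1", "control" if i % 2 else "t1d"))
        for i in range(14)]


def test_baseline_learns_easy_cohort(easy_cohort):
    """Learning sanity: the reference-modality baseline reaches validation
    Dice >= 0.8 within the desk budget on an easy cohort."""
    train, val, test = (easy_cohort[:10], easy_cohort[10:12],
                        easy_cohort[12:])
    model, record = train_model(FusionConfig(mode="baseline_ref"),
                                TrainProtocol.desk(seed=0), train, val,
                                seed=0)
    assert record.best_val_loss < 0.2          # validation Dice >= 0.8
    dices = evaluate_pairs(model, test)
    assert np.median(dices) >= 0.8


def test_checkpoint_roundtrip_reproduces_validation_loss(easy_cohort,
                                                         tmp_path):
    train, val = easy_cohort[:4], easy_cohort[4:6]
    protocol = TrainProtocol.desk(seed=0, total_batches=40)
    model, record = train_model(FusionConfig(mode="input_concat"), protocol,
                                train, val, seed=1)
    before = validation_loss(model, val)
    save_checkpoint(tmp_path / "ck.npz", model, record)
    again, rec2 = load_checkpoint(tmp_path / "ck.npz")
    assert rec2.to_json() == record.to_json()
    assert again.config == model.config
    assert abs(validation_loss(again, val) - before) <= 1e-6


def test_slice_sampler_is_seeded_and_batches_correctly(easy_cohort):
    s1 = SliceSampler(easy_cohort[:4], seed=3)
    s2 = SliceSampler(easy_cohort[:4], seed=3)
    a = s1.batch(2)
    b = s2.batch(2)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    assert a[0].shape == (2, 32, 32)


def test_train_model_rejects_empty_sets():
    with pytest.raises(ValueError):
        train_model(FusionConfig(mode="baseline_ref"),
                    TrainProtocol.desk(), [], [])
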