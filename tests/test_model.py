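"""Classifier construction, training protocol, and inference contracts.

Training-related tests run at 32x32 input with few epochs to stay cheap;
the full desk-scale training run lives in the acceptance suite.
"""

import numpy as np
import pytest

from ecgrpm.model import (NetworkSpec, TrainConfig, build_network,
                          gam_attention, load_checkpoint, predict_proba,
                          save_checkpoint, split_dataset, train)
from ecgrpm.nnet import ChannelGate, softmax

SMALL = NetworkSpec(num_classes=5, input_px=32, attention_reduction=8)


def _toy_images(rng, n_per_class=8, px=32, classes=5):
    """Class-separable toy images: each class lights its own band."""
    images, labels = [], []
    for c in range(classes):
        for _ in range(n_per_class):
            img = rng.integers(0, 40, size=(px, px))
            lo, hi = c * px // classes, (c + 1) * px // classes
            img[lo:hi, :] = rng.integers(180, 255, size=(hi - lo, px))
            images.append(img)
            labels.append("NLRAV"[c])
    return np.stack(images).astype(np.uint8), np.array(labels)


class TestBuildNetwork:
    def test_output_is_probability_vector_after_softmax(self, rng):
        net = build_network(SMALL, seed=0)
        net.set_training(False)
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        probs = softmax(net.forward(x))
        assert probs.shape == (2, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_attention_adds_parameters_only_at_sites(self):
        def n_params(spec):
            return sum(p.data.size for p in build_network(spec, 0).params())

        baseline = n_params(NetworkSpec(attention_sites=()))
        gated = n_params(NetworkSpec(attention_sites=(0, 1, 2, 3)))
        # each gate at stage with C channels adds 2*C*(C//16) weights + biases
        expected_extra = sum(
            c * h + h + h * c + c
            for c, h in ((64, 4), (128, 8), (256, 16), (512, 32)))
        assert gated - baseline == expected_extra

    def test_seeded_initialization_is_reproducible(self):
        a = build_network(SMALL, seed=9)
        b = build_network(SMALL, seed=9)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_invalid_attention_site_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(attention_sites=(4,))


class TestGamAttention:
    def test_shape_contract_3d_and_4d(self, rng):
        x3 = rng.standard_normal((8, 5, 5)).astype(np.float32)
        assert gam_attention(x3, r=4, rng=rng).shape == x3.shape
        x4 = rng.standard_normal((2, 8, 5, 5)).astype(np.float32)
        assert gam_attention(x4, r=4, rng=rng).shape == x4.shape

    def test_zero_mlp_gives_exact_1_5_scaling(self, rng):
        gate = ChannelGate(6, 2, rng=rng)
        for p in gate.params():
            p.data[...] = 0.0
        x = rng.standard_normal((6, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(gam_attention(x, gate=gate), 1.5 * x,
                                   rtol=1e-6)


class TestTrainingProtocol:
    def test_split_is_deterministic_and_stratified(self, rng):
        labels = np.repeat(list("NLRAV"), 20)
        cfg = TrainConfig(seed=3)
        s1 = split_dataset(100, labels, cfg)
        s2 = split_dataset(100, labels, cfg)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a, b)
        tr, val, te = s1
        assert len(te) == 20 and len(val) == 16 and len(tr) == 64
        assert not (set(tr) & set(te)) and not (set(val) & set(te))
        # stratification: every class appears in the test split
        assert set(labels[te]) == set("NLRAV")

    def test_overfits_separable_toy_data(self, rng):
        images, labels = _toy_images(rng)
        cfg = TrainConfig(seed=1, max_epochs=6, batch_size=16)
        net, hist, split = train(images, labels, SMALL, cfg)
        assert len(hist.train_loss) == 6
        assert hist.train_acc[-1] >= 0.95
        # loss mostly non-increasing on separable data
        drops = sum(b <= a + 1e-3 for a, b in
                    zip(hist.train_loss, hist.train_loss[1:]))
        assert drops >= 0.6 * (len(hist.train_loss) - 1)

    def test_memorizes_single_examples(self, rng):
        """Overfit sanity: after training, each training image's argmax is
        its own label."""
        images, labels = _toy_images(rng, n_per_class=6)
        # enough epochs for the batch-norm running statistics, which
        # eval-mode inference relies on, to settle
        cfg = TrainConfig(seed=2, max_epochs=16, batch_size=8)
        net, hist, split = train(images, labels, SMALL, cfg)
        probs = predict_proba(net, images[split["train"]], SMALL)
        pred = np.array(split["classes"])[probs.argmax(axis=1)]
        assert (pred == labels[split["train"]]).mean() >= 0.9

    def test_empty_class_after_split_is_reported(self, rng):
        images, labels = _toy_images(rng, n_per_class=2)
        labels[:] = "N"
        labels[0] = "V"    # a single V cannot reach every split
        cfg = TrainConfig(seed=0, max_epochs=1, class_stratified=False)
        with pytest.raises(ValueError, match="class"):
            train(images, labels, SMALL, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(test_fraction=0.0)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    images, labels = _toy_images(rng, n_per_class=6)
    net, _, _ = train(images, labels, SMALL,
                      TrainConfig(seed=0, max_epochs=2, batch_size=8))
    return net, images


class TestPredictProba:

    def test_rows_sum_to_one(self, trained):
        net, images = trained
        probs = predict_proba(net, images[:7], SMALL)
        assert probs.shape == (7, 5)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_inputs_get_identical_rows(self, trained):
        net, images = trained
        batch = np.stack([images[0], images[1], images[0]])
        probs = predict_proba(net, batch, SMALL)
        np.testing.assert_array_equal(probs[0], probs[2])

    def test_resolution_mismatch_rejected(self, trained):
        net, _ = trained
        with pytest.raises(ValueError, match="64x64"):
            predict_proba(net, np.zeros((1, 64, 64), dtype=np.uint8), SMALL)

    def test_checkpoint_round_trip(self, trained, tmp_path):
        net, images = trained
        save_checkpoint(net, SMALL, tmp_path / "model")
        net2, spec2 = load_checkpoint(tmp_path / "model.npz")
        assert spec2 == SMALL
        np.testing.assert_array_equal(predict_proba(net, images[:3], SMALL),
                                      predict_proba(net2, images[:3], SMALL))
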