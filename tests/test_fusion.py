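import numpy as np
import pytest

from reeffusion.datamodel import DEFAULT_LABELS, LabelSet
from reeffusion.fusion import (
    build_joint_features,
    predict_fused,
    train_fusion,
)


def _complementary_scores(rng, n_per_class=30):
    """Synthetic per-modality score vectors with complementary information.

    Modality A's 10 scores identify classes 0-4 only (flat noise for 5-9);
    modality B identifies classes 5-9 only.  The Bayes rule on the joint
    vector is near-perfect while each single modality tops out near 55%.
    """
    labels, a_scores, b_scores = [], [], []
    for cls in range(10):
        for _ in range(n_per_class):
            a = rng.normal(0, 0.3, 10)
            b = rng.normal(0, 0.3, 10)
            if cls < 5:
                a[cls] += 3.0
            else:
                b[cls] += 3.0
            labels.append(DEFAULT_LABELS[cls])
            a_scores.append(a)
            b_scores.append(b)
    return np.array(a_scores), np.array(b_scores), labels


class TestJointFeatures:
    def test_concatenation_order_and_length(self, toy_nets_and_patches):
        net_ref, net_flr, patches = toy_nets_and_patches
        joint = build_joint_features(net_ref, net_flr, patches)
        assert joint.shape == (len(patches), 20)
        swapped = build_joint_features(net_flr, net_ref, patches)
        # permuting the networks permutes the two halves exactly
        np.testing.assert_array_equal(joint[:, :10], swapped[:, 10:])
        np.testing.assert_array_equal(joint[:, 10:], swapped[:, :10])

    def test_zero_weight_networks_give_zero_vectors(self, toy_nets_and_patches):
        net_ref, net_flr, patches = toy_nets_and_patches
        for net in (net_ref, net_flr):
            for layer in net.layers:
                if hasattr(layer, "w"):
                    layer.w[:] = 0
                    layer.b[:] = 0
        joint = build_joint_features(net_ref, net_flr, patches)
        np.testing.assert_array_equal(joint, np.zeros_like(joint))


class TestTrainFusion:
    def test_separable_two_class_scores_fit_perfectly(self, rng):
        labelset = LabelSet(("a", "b"), ())
        x = np.vstack([rng.normal(-2, 0.1, (40, 4)), rng.normal(2, 0.1, (40, 4))])
        y = ["a"] * 40 + ["b"] * 40
        model = train_fusion(x, y, labelset)
        assert predict_fused(model, x) == y

    def test_fusion_beats_both_single_modalities(self, rng):
        a_tr, b_tr, y_tr = _complementary_scores(rng)
        a_te, b_te, y_te = _complementary_scores(rng)
        labelset = LabelSet()
        model = train_fusion(np.hstack([a_tr, b_tr]), y_tr, labelset)
        fused_pred = predict_fused(model, np.hstack([a_te, b_te]))
        acc = lambda pred: np.mean([p == t for p, t in zip(pred, y_te)])
        fused_acc = acc(fused_pred)
        argmax_a = [DEFAULT_LABELS[i] for i in a_te.argmax(1)]
        argmax_b = [DEFAULT_LABELS[i] for i in b_te.argmax(1)]
        assert fused_acc > acc(argmax_a)
        assert fused_acc > acc(argmax_b)
        assert fused_acc > 0.9

    def test_duplicating_training_data_keeps_decision_function(self, rng):
        a, b, y = _complementary_scores(rng, n_per_class=10)
        x = np.hstack([a, b])
        labelset = LabelSet()
        probe = rng.normal(0, 1.5, (50, 20))
        m1 = train_fusion(x, y, labelset, c_grid=(1.0,))
        m2 = train_fusion(np.vstack([x, x]), y + y, labelset, c_grid=(1.0,))
        assert predict_fused(m1, probe) == predict_fused(m2, probe)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_fusion(rng.normal(0, 1, (10, 20)), ["Acropora"] * 10)

    def test_standardization_uses_training_statistics(self, rng):
        a, b, y = _complementary_scores(rng, n_per_class=10)
        x = np.hstack([a, b])
        model = train_fusion(x, y, c_grid=(1.0,))
        scaler = model.pipeline.named_steps["scale"]
        np.testing.assert_allclose(scaler.mean_, x.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(
            scaler.var_, x.var(axis=0), atol=1e-9
        )


class TestPredictFused:
    def test_wrong_vector_length_rejected(self, rng):
        a, b, y = _complementary_scores(rng, n_per_class=5)
        model = train_fusion(np.hstack([a, b]), y, c_grid=(1.0,))
        with pytest.raises(ValueError):
            predict_fused(model, np.zeros(19))

    def test_batch_equals_elementwise_prediction(self, rng):
        a, b, y = _complementary_scores(rng, n_per_class=5)
        model = train_fusion(np.hstack([a, b]), y, c_grid=(1.0,))
        probe = rng.normal(0, 1, (20, 20))
        batch = predict_fused(model, probe)
        single = [predict_fused(model, row)[0] for row in probe]
        assert batch == single


@pytest.fixture(scope="module")
def toy_nets_and_patches():
    """Tiny trained 3- and 2-channel networks plus five-channel probe patches."""
    from reeffusion.cnn import NetworkSpec, train_network
    from reeffusion.patching import PatchTensor, slice_modality

    rng = np.random.default_rng(5)
    labelset = LabelSet()
    patches = []
    for i in range(40):
        cls = i % 10
        px = np.clip(
            0.05 + 0.09 * cls + rng.normal(0, 0.02, (32, 32, 5)), 0, 1
        )
        patches.append(PatchTensor(px, DEFAULT_LABELS[cls], ("t", i, 0)))
    spec_ref = NetworkSpec.reduced(3, epochs=3, batch_size=8, seed=0)
    spec_flr = NetworkSpec.reduced(2, epochs=3, batch_size=8, seed=1)
    net_ref = train_network(spec_ref, [slice_modality(p, "ref") for p in patches], labelset)
    net_flr = train_network(spec_flr, [slice_modality(p, "flr") for p in patches], labelset)
    return net_ref, net_flr, patches
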