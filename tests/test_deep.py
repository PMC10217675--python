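"""Layer-graph engine and CNN extractor contracts."""

import numpy as np
import pytest

from fundusfuse import (
    ArchitectureSpec,
    TrainConfig,
    build_graphnet,
    build_resnet50,
    count_layers,
    extract_backbone_features,
    extract_deep_features,
    train_cnn,
)
from fundusfuse import nn as ffnn


def make_two_class_blobs(n=200, size=32, seed=0):
    """Trivially separable image classes: bright vs dark central square."""
    rng = np.random.default_rng(seed)
    imgs, labels = [], []
    for i in range(n):
        c = i % 2
        img = rng.normal(120, 10, (size, size, 3))
        img[8 : size - 8, 8 : size - 8] += 80 if c else -80
        imgs.append(np.clip(img, 0, 255).astype(np.uint8))
        labels.append(c)
    return imgs, np.array(labels)


class TestArchitecture:
    def test_count_layers_counts_every_node(self):
        spec = ArchitectureSpec(
            [("in", "input"), ("c", "conv"), ("s", "softmax"), ("o", "classification-output")],
            [("in", "c"), ("c", "s"), ("s", "o")],
            4096,
            2,
        )
        assert count_layers(spec) == 4

    def test_shipped_graphnet_has_124_layers(self):
        model = build_graphnet(5, 64)
        assert count_layers(model.spec) == 124

    def test_count_is_additive_in_nodes(self):
        model = build_graphnet(5, 64)
        spec = model.spec
        bigger = ArchitectureSpec(
            spec.nodes + [("extra_drop", "dropout")], spec.edges, spec.fc1_width, spec.n_classes
        )
        assert count_layers(bigger) == count_layers(spec) + 1

    def test_spec_invariants_validated(self):
        with pytest.raises(ValueError, match="depth-concat"):
            ArchitectureSpec(
                [("in", "input"), ("f", "fully-connected"), ("o", "classification-output")],
                [],
                4096,
                2,
            ).validate()

    def test_graphnet_contains_branch_and_gap_before_fc1(self):
        model = build_graphnet(5, 64)
        kinds = dict(model.spec.nodes)
        assert kinds["b0_concat"] == "depth-concat"
        names = [n for n, _ in model.spec.nodes]
        assert names[names.index("fc1") - 1] == "gap" and kinds["gap"] == "pool"

    def test_min_classes_enforced(self):
        with pytest.raises(ValueError):
            build_graphnet(1, 64)


class TestForward:
    def test_fc1_width_is_4096(self):
        model = build_graphnet(5, 32, seed=0)
        x = np.random.default_rng(0).random((2, 3, 32, 32)).astype(np.float32)
        assert model.features(x, "FC-1").shape == (2, 4096)
        assert model.predict_proba(x).shape == (2, 5)

    def test_unknown_layer_error_lists_valid_names(self):
        model = build_graphnet(5, 32)
        with pytest.raises(ValueError, match="FC-1"):
            model.features(np.zeros((1, 3, 32, 32), dtype=np.float32), "FC-9")

    def test_same_seed_gives_identical_initial_weights(self):
        a = build_graphnet(5, 32, seed=3).graph.state_dict()
        b = build_graphnet(5, 32, seed=3).graph.state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_extraction_is_pure_function_of_weights_and_image(self, tiny_dataset):
        images, _, _ = tiny_dataset
        model = build_graphnet(5, 64, seed=1)
        f1 = extract_deep_features(model, images[:4], "FC-1")
        f2 = extract_deep_features(model, images[:4], "FC-1")
        assert np.array_equal(f1.values, f2.values)
        assert set(f1.block_tags) == {"graphnet"}

    def test_duplicated_image_identical_rows(self, tiny_dataset):
        images, _, _ = tiny_dataset
        model = build_graphnet(5, 64, seed=1)
        fm = extract_deep_features(model, [images[0], images[0]])
        assert np.array_equal(fm.values[0], fm.values[1])


class TestGradients:
    def test_finite_difference_gradcheck_on_tiny_graph(self):
        """Backprop through conv/BN/pool/concat/FC agrees with finite differences."""
        rng = np.random.default_rng(0)
        g = ffnn.GraphModel(seed=0)
        g.add("input", ffnn.Input(), [])
        g.add("c1", ffnn.Conv2d(1, 2, 3, rng=rng))
        g.add("bn", ffnn.BatchNorm2d(2))
        g.add("r1", ffnn.ReLU())
        g.add("c2", ffnn.Conv2d(1, 2, 3, rng=rng), ["input"])
        g.add("cat", ffnn.Concat(), ["r1", "c2"])
        g.add("pool", ffnn.MaxPool2d(2))
        g.add("gap", ffnn.GlobalAvgPool())
        g.add("fc", ffnn.Dense(4, 3, rng=rng))
        x = rng.random((4, 1, 8, 8)).astype(np.float32)
        y = np.array([0, 1, 2, 0])

        def loss_value():
            logits = g.forward_logits(x, training=True)
            return ffnn.softmax_cross_entropy(logits, y)[0]

        logits = g.forward_logits(x, training=True)
        _, dlogits = ffnn.softmax_cross_entropy(logits, y)
        g.backward(dlogits)
        checked = 0
        for node, pname, p, grad in g.parameters():
            flat = p.reshape(-1)
            gflat = grad.reshape(-1)
            for idx in (0, flat.size // 2):
                eps = 1e-2
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                # float32 forward passes limit central-difference precision
                assert numeric == pytest.approx(gflat[idx], rel=0.1, abs=3e-3), (node, pname)
                checked += 1
        assert checked >= 10


class TestTraining:
    def test_learns_separable_two_class_problem(self):
        imgs, labels = make_two_class_blobs()
        model = build_graphnet(2, 32, seed=0)
        cfg = TrainConfig(max_epochs=5, minibatch=16, initial_lr=0.01, seed=0)
        history = train_cnn(model, imgs, labels, cfg)
        assert history["accuracy"][-1] > 0.9
        assert len(history["loss"]) == 5 and np.isfinite(history["loss"]).all()

    def test_lr_drops_by_factor_ten_each_period(self):
        imgs, labels = make_two_class_blobs(n=40)
        model = build_graphnet(2, 32, seed=0)
        cfg = TrainConfig(max_epochs=3, lr_drop_period=1, initial_lr=0.01, minibatch=16, seed=0)
        history = train_cnn(model, imgs, labels, cfg)
        assert history["lr"] == pytest.approx([0.01, 0.001, 0.0001])

    def test_history_length_matches_epochs(self):
        imgs, labels = make_two_class_blobs(n=20)
        model = build_graphnet(2, 32, seed=0)
        history = train_cnn(model, imgs, labels, TrainConfig(max_epochs=2, minibatch=10, seed=0))
        assert len(history["accuracy"]) == 2

    def test_single_class_rejected(self):
        imgs, _ = make_two_class_blobs(n=10)
        with pytest.raises(ValueError, match="2 classes"):
            train_cnn(build_graphnet(2, 32), imgs, np.zeros(10, dtype=int), TrainConfig(max_epochs=1))

    def test_validation_recorded_every_50_iterations(self):
        imgs, labels = make_two_class_blobs(n=120)
        model = build_graphnet(2, 32, seed=0)
        cfg = TrainConfig(max_epochs=8, minibatch=16, validation_frequency=50, seed=0)
        history = train_cnn(model, imgs, labels, cfg, val=(imgs[:10], labels[:10]))
        # 8 epochs x ceil(120/16)=8 iterations = 64 iterations -> 1 validation
        assert [it for it, _ in history["val"]] == [50]


class TestBackbone:
    def test_resnet50_gap_width_2048(self, tiny_dataset):
        images, _, _ = tiny_dataset
        fm = extract_backbone_features(images[:2], input_size=64, seed=0)
        assert fm.values.shape == (2, 2048) and set(fm.block_tags) == {"resnet"}

    def test_different_seeds_same_shape_different_values(self, tiny_dataset):
        images, _, _ = tiny_dataset
        a = extract_backbone_features(images[:1], input_size=64, seed=0)
        b = extract_backbone_features(images[:1], input_size=64, seed=1)
        assert a.values.shape == b.values.shape
        assert not np.allclose(a.values, b.values)

    def test_unknown_backbone_rejected(self, tiny_dataset):
        images, _, _ = tiny_dataset
        with pytest.raises(ValueError, match="resnet50"):
            extract_backbone_features(images[:1], backbone="vgg16")

    def test_resnet_uses_addition_nodes(self):
        model = build_resnet50(seed=0)
        kinds = [k for _, k in model.spec.nodes]
        assert kinds.count("addition") == 16  # 3+4+6+3 bottlenecks
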