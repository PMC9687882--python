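"""Network contracts: shapes, determinism, parameter count, prediction modes."""

import numpy as np
import pytest

import panfat as pf
from panfat.errors import InvalidConfigError, InvalidInputError
from panfat.network import (NetworkConfig, UNetSegmenter, build_network,
                            evaluate_batch, predict_mask, train)
from panfat.network.checkpoint import load_model, save_model
from panfat.superpixel import _summaries
from panfat.types import SuperpixelMap


def quadrant_map(n):
    labels = np.zeros((n, n), dtype=np.int32)
    h = n // 2
    labels[:h, h:] = 1
    labels[h:, :h] = 2
    labels[h:, h:] = 3
    k, centers, sizes = _summaries(labels)
    return SuperpixelMap(labels=labels, K_actual=k, centers=centers, sizes=sizes)


class StubModel:
    """Fake per-pixel classifier: foreground wherever the image exceeds 0.5."""

    def predict_proba(self, x):
        return x[:, 0]


class TestBuildNetwork:
    def test_forward_shape_contract(self):
        net = build_network(NetworkConfig(depth=2, base_channels=8, input_size=128))
        out = net.forward(np.zeros((1, 1, 128, 128), np.float32), train=False)
        assert out.shape == (1, 2, 128, 128)

    def test_initial_weights_deterministic(self):
        a = build_network(NetworkConfig(seed=7))
        b = build_network(NetworkConfig(seed=7))
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_parameter_count_closed_form(self):
        # two 3x3 convs per encoder level and bottleneck, decoder blocks of
        # one 3x3 up-conv + two 3x3 convs after skip concat, 1x1 head
        def conv(cin, cout, k=3):
            return cin * cout * k * k + cout

        c, d = 8, 2
        expected = conv(1, c) + conv(c, c)               # encoder level 0
        expected += conv(c, 2 * c) + conv(2 * c, 2 * c)  # encoder level 1
        expected += conv(2 * c, 4 * c) + conv(4 * c, 4 * c)  # bottleneck
        expected += conv(4 * c, 2 * c) + conv(4 * c, 2 * c) + conv(2 * c, 2 * c)
        expected += conv(2 * c, c) + conv(2 * c, c) + conv(c, c)
        expected += conv(c, 2, k=1)
        net = build_network(NetworkConfig(depth=d, base_channels=c))
        assert net.n_params == expected

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(InvalidConfigError):
            NetworkConfig(depth=3, input_size=100)

    def test_transferred_encoder_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            build_network(NetworkConfig(encoder_init="transferred"))


class TestPredictMask:
    def test_centered_broadcasts_center_class(self):
        spmap = quadrant_map(16)
        img = np.zeros((16, 16), np.float32)
        img[:8, :8] = 1.0   # superpixel 0 foreground
        img[8:, 8:] = 1.0   # superpixel 3 foreground
        pred = predict_mask(StubModel(), img, spmap, mode="centered")
        assert np.array_equal(pred.mask, np.isin(spmap.labels, [0, 3]))

    def test_centered_mask_is_union_of_superpixels(self):
        spmap = quadrant_map(16)
        rng = np.random.default_rng(0)
        img = (rng.random((16, 16)) < 0.5).astype(np.float32)
        pred = predict_mask(StubModel(), img, spmap, mode="centered")
        for lab in range(spmap.K_actual):
            vals = np.unique(pred.mask[spmap.labels == lab])
            assert len(vals) == 1

    def test_all_background_centers_give_empty_mask(self):
        spmap = quadrant_map(16)
        pred = predict_mask(StubModel(), np.zeros((16, 16), np.float32),
                            spmap, mode="centered")
        assert not pred.mask.any()

    def test_centered_requires_matching_shapes(self):
        with pytest.raises(InvalidInputError):
            predict_mask(StubModel(), np.zeros((8, 8), np.float32),
                         quadrant_map(16), mode="centered")


class TestEvaluateBatch:
    def test_perfect_oracle_scores_one(self):
        gt = np.zeros((16, 16), bool)
        gt[2:9, 3:12] = True
        mean, rows = evaluate_batch(StubModel(),
                                    [(gt.astype(np.float32), gt)], mode="dense")
        assert mean == 1.0
        assert rows[0]["dsc"] == 1.0

    def test_mean_is_arithmetic_mean_of_rows(self):
        gt1 = np.zeros((16, 16), bool)
        gt1[:8] = True
        gt2 = np.zeros((16, 16), bool)
        gt2[:, :4] = True
        mean, rows = evaluate_batch(
            StubModel(),
            [(gt1.astype(np.float32), gt1), (gt1.astype(np.float32), gt2)],
            mode="dense")
        assert mean == pytest.approx(np.mean([r["dsc"] for r in rows]))


@pytest.fixture(scope="module")
def tiny_dataset():
    pairs = [pf.generate_slice_pair(shape=(64, 64), seed=s) for s in range(10)]
    return ([p.water.data for p in pairs], [p.gt_mask for p in pairs])


class TestTraining:
    def test_learns_bright_organ_and_records_history(self, tiny_dataset):
        X, y = tiny_dataset
        est = UNetSegmenter(depth=2, base_channels=8, input_size=64, epochs=8,
                            batch_size=4, seed=0)
        est.fit(X, y)
        assert len(est.history_) == 8
        assert est.history_.val_dice[-1] > 0.5
        assert est.score(X, y) > 0.5

    def test_checkpoint_round_trip(self, tiny_dataset, tmp_path):
        X, y = tiny_dataset
        est = UNetSegmenter(depth=2, base_channels=4, input_size=64, epochs=1,
                            batch_size=4, seed=1)
        est.fit(X[:4], y[:4])
        path = save_model(est.model_, tmp_path / "model.npz")
        clone = load_model(path)
        xb = np.stack(X[:2])[:, None].astype(np.float32)
        assert np.array_equal(clone.predict_proba(xb),
                              est.model_.predict_proba(xb))

    def test_empty_and_short_datasets_rejected(self):
        cfg = NetworkConfig(input_size=64)
        with pytest.raises(InvalidInputError):
            train(build_network(cfg), [], cfg)
        est = UNetSegmenter(input_size=64)
        with pytest.raises(InvalidInputError):
            est.fit([np.zeros((64, 64))], [np.zeros((64, 64), bool)])

    def test_seed_reproducible_fit(self, tiny_dataset):
        X, y = tiny_dataset
        runs = []
        for _ in range(2):
            est = UNetSegmenter(depth=2, base_channels=4, input_size=64,
                                epochs=2, batch_size=4, seed=5)
            est.fit(X[:6], y[:6])
            runs.append(est.history_.val_dice)
        assert runs[0] == runs[1]
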