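"""Architecture identities, training behavior, and transfer-mode semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoseq.datasets import LabeledSet
from thermoseq.model import (
    ModelConfig,
    TrainConfig,
    build,
    extract_representation,
    flatten_dim,
    load_model,
    predict,
    save_model,
    set_transfer_mode,
    train,
)
from thermoseq.records import ProteinRecord

TINY = dict(input_length=32, filters=8, kernel_size=3, pool_size=4,
            pool_stride=4, dense_sizes=(16,), dropout=0.1)


def make_set(rng, n=20, length=24, label_fn=None, name="t"):
    from thermoseq.records import ALPHABET

    records = []
    for i in range(n):
        seq = "".join(rng.choice(list(ALPHABET), size=length))
        label = float(label_fn(seq)) if label_fn else float(rng.uniform(20, 80))
        records.append(ProteinRecord(id=f"r{i}", sequence=seq, label=label))
    return LabeledSet(records, name=name)


class TestFlattenDim:
    def test_default_architecture_width(self):
        cfg = ModelConfig()  # 2000 input, 1 block, 512 filters, pool 50/50
        assert flatten_dim(cfg) == 20480

    def test_single_pooled_position(self):
        cfg = ModelConfig(input_length=100, filters=1, pool_size=100, pool_stride=1)
        assert flatten_dim(cfg) == 1

    def test_small_config_formula(self):
        cfg = ModelConfig(input_length=128, filters=16, pool_size=8, pool_stride=8)
        assert flatten_dim(cfg) == 16 * ((128 - 8) // 8 + 1) == 256

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(
        L=st.integers(16, 48),
        f=st.integers(1, 8),
        p=st.integers(2, 12),
        w=st.integers(1, 8),
        blocks=st.integers(1, 3),
    )
    def test_formula_matches_built_network(self, L, f, p, w, blocks):
        if p > L:
            p = L
        cfg = ModelConfig(input_length=L, filters=f, kernel_size=3,
                          pool_size=p, pool_stride=w, dense_sizes=(4,),
                          n_blocks=blocks, seed=0)
        model = build(cfg)
        rec = ProteinRecord(id="a", sequence="ACDEFGHIKLMNPQ"[: min(14, L)])
        reps = model.representations([rec])
        assert reps.shape == (1, flatten_dim(cfg))


class TestBuildValidation:
    @pytest.mark.parametrize("blocks", [0, 4])
    def test_block_count_bounds(self, blocks):
        with pytest.raises(ValueError, match="n_blocks"):
            build(ModelConfig(n_blocks=blocks, **TINY))

    def test_pool_larger_than_input(self):
        with pytest.raises(ValueError, match="pool"):
            build(ModelConfig(input_length=32, pool_size=64))


class TestTraining:
    def test_constant_labels_convergence(self, rng):
        """Training against a constant target drives predictions to it."""
        data = make_set(rng, n=100, length=24, label_fn=lambda s: 40.0)
        cfg = ModelConfig(seed=0, **TINY)
        tc = TrainConfig(learning_rate=1e-2, batch_size=32, epochs=50, seed=0)
        trained, history = train(build(cfg), data, tc)
        preds = predict(trained, data.records)
        assert np.mean(np.abs(preds - 40.0) <= 1.0) >= 0.9
        assert len(history) == 50

    def test_memorization_reduces_loss(self, rng):
        data = make_set(rng, n=20, length=24)
        cfg = ModelConfig(seed=1, **TINY)
        tc = TrainConfig(learning_rate=1e-2, batch_size=10, epochs=60, seed=1)
        _, history = train(build(cfg), data, tc)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_fixed_seed_reproducible_first_epoch(self, rng):
        data = make_set(rng, n=30, length=24)
        cfg = ModelConfig(seed=2, **TINY)
        tc = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=2, seed=5)
        _, h1 = train(build(cfg), data, tc)
        _, h2 = train(build(cfg), data, tc)
        assert h1[0]["train_loss"] == pytest.approx(h2[0]["train_loss"], rel=1e-6)

    def test_empty_data_errors(self):
        with pytest.raises(ValueError, match="empty"):
            train(build(ModelConfig(seed=0, **TINY)), LabeledSet([], name="e"),
                  TrainConfig())

    def test_overlong_sequence_names_offender(self, rng):
        data = make_set(rng, n=2, length=24)
        data.records[1] = ProteinRecord(id="toolong", sequence="A" * 40, label=1.0)
        with pytest.raises(ValueError, match="toolong"):
            train(build(ModelConfig(seed=0, **TINY)), data, TrainConfig())


def _groups_equal(a, b, tag=None):
    ga, gb = a.weight_groups(), b.weight_groups()
    for name in ga:
        if tag is not None and ga[name]["tag"] != tag:
            continue
        for x, y in zip(ga[name]["arrays"], gb[name]["arrays"]):
            if not np.array_equal(x, y):
                return False
        for x, y in zip(ga[name]["buffers"], gb[name]["buffers"]):
            if not np.array_equal(x, y):
                return False
    return True


@pytest.fixture(scope="module")
def pretrained():
    rng = np.random.default_rng(0)
    data = make_set(rng, n=40, length=24)
    cfg = ModelConfig(seed=3, **TINY)
    tc = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=3, seed=3)
    trained, _ = train(build(cfg), data, tc)
    return trained, data


@pytest.fixture(scope="module")
def model_and_records():
    rng = np.random.default_rng(1)
    model = build(ModelConfig(seed=4, **TINY))
    data = make_set(rng, n=8, length=24)
    return model, data.records


class TestTransferModes:
    def test_frozen_cnn_preserves_extractor_bitwise(self, pretrained):
        model, data = pretrained
        ft = set_transfer_mode(model, "frozen_cnn")
        tuned, _ = train(ft, data, TrainConfig(learning_rate=1e-3, epochs=3,
                                               batch_size=16, seed=9))
        assert _groups_equal(model, tuned, tag="pre_flatten")
        np.testing.assert_array_equal(
            extract_representation(model, data.records[:4]),
            extract_representation(tuned, data.records[:4]),
        )
        # the dense head did move
        assert not _groups_equal(model, tuned)

    def test_frozen_all_is_inert(self, pretrained):
        model, data = pretrained
        ft = set_transfer_mode(model, "frozen_all")
        tuned, _ = train(ft, data, TrainConfig(learning_rate=1e-2, epochs=2,
                                               batch_size=16, seed=4))
        assert _groups_equal(model, tuned)
        np.testing.assert_array_equal(
            predict(model, data.records[:5]), predict(tuned, data.records[:5])
        )

    def test_from_scratch_reinitializes(self, pretrained):
        model, _ = pretrained
        fresh = set_transfer_mode(model, "from_scratch")
        assert not _groups_equal(model, fresh)
        assert all(g["trainable"] for g in fresh.weight_groups().values())

    def test_tune_all_moves_extractor(self, pretrained):
        model, data = pretrained
        ft = set_transfer_mode(model, "tune_all")
        tuned, _ = train(ft, data, TrainConfig(learning_rate=1e-2, epochs=2,
                                               batch_size=16, seed=6))
        assert not _groups_equal(model, tuned, tag="pre_flatten")

    def test_unknown_mode_errors(self, pretrained):
        with pytest.raises(ValueError):
            set_transfer_mode(pretrained[0], "half_frozen")


class TestPredictionContracts:
    def test_duplicates_identical(self, model_and_records):
        model, records = model_and_records
        preds = predict(model, [records[0], records[0]])
        assert preds[0] == preds[1]

    def test_order_invariance(self, model_and_records):
        model, records = model_and_records
        fwd = predict(model, records)
        rev = predict(model, records[::-1])
        np.testing.assert_allclose(fwd, rev[::-1], rtol=1e-6)

    def test_identical_sequences_identical_representations(self, model_and_records):
        model, records = model_and_records
        twin = ProteinRecord(id="twin", sequence=records[0].sequence)
        reps = extract_representation(model, [records[0], twin])
        np.testing.assert_array_equal(reps[0], reps[1])

    def test_save_load_roundtrip(self, model_and_records, tmp_path):
        model, records = model_and_records
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(predict(model, records), predict(back, records))
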