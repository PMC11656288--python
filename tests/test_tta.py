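"""Unit tests for training and adaptation orchestration (tiny scale)."""

import numpy as np
import pytest

from wavtta.losses import ClassRatioPrior
from wavtta.metrics import binarize, dice_coefficient
from wavtta.models import RefineNetConfig, build_refine_model, build_wavnet
from wavtta.nn import Tensor
from wavtta.synthetic import PhantomSpec, generate_phantom
from wavtta.tta import (
    AdaptationError,
    SourceTrainingConfig,
    TTAConfig,
    UndertrainedSchedule,
    adapt_single_sample,
    generate_undertrained_segmentations,
    run_ablation,
    trace_to_frame,
    train_refine,
    train_source,
)

TINY = (16, 16, 16)


class IdentityRefine:
    def __call__(self, x):
        return x

    def eval(self):
        return self

    def parameters(self):
        return []


@pytest.fixture()
def tiny_data():
    pairs = [
        generate_phantom(PhantomSpec(extents=TINY, fg_range=(0.03, 0.15), seed=s))
        for s in range(2)
    ]
    return [v for v, _ in pairs], [l for _, l in pairs]


@pytest.fixture()
def tiny_model(tiny_config, db2):
    return build_wavnet(tiny_config, db2)


@pytest.fixture()
def tiny_refine():
    return build_refine_model(RefineNetConfig(channels=(2, 4, 4, 4)))


class TestConfigs:
    def test_batch_size_fixed_at_one(self):
        with pytest.raises(ValueError, match="batch size 1"):
            SourceTrainingConfig(batch_size=2)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            TTAConfig(iterations=-1)

    def test_schedule_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            UndertrainedSchedule((30, 30, 40)).validate(100)

    def test_schedule_within_training_length(self):
        with pytest.raises(ValueError, match="exceeds"):
            UndertrainedSchedule((30, 80)).validate(50)

    def test_default_schedule(self):
        assert UndertrainedSchedule().stop_epochs == (30, 40, 50, 60, 70, 80)


class TestTrainSource:
    def test_zero_epochs_keeps_initialization(self, tiny_model, tiny_data):
        volumes, labels = tiny_data
        before = tiny_model.state_dict()
        result = train_source(
            tiny_model, volumes, labels, SourceTrainingConfig(epochs=0)
        )
        for key, value in before.items():
            assert np.array_equal(result.state[key], value)
        assert 0 < result.prior.ratio < 1

    def test_prior_is_mean_of_label_fractions(self, tiny_model, tiny_data):
        volumes, labels = tiny_data
        result = train_source(tiny_model, volumes, labels, SourceTrainingConfig(epochs=0))
        expected = np.mean([l.mean() for l in labels])
        assert result.prior.ratio == pytest.approx(expected)

    def test_seeded_run_reproducible(self, tiny_config, db2, tiny_data):
        volumes, labels = tiny_data
        states = []
        for _ in range(2):
            model = build_wavnet(tiny_config, db2)
            result = train_source(
                model, volumes, labels,
                SourceTrainingConfig(epochs=2, learning_rate=0.05, seed=3),
            )
            states.append(result.state)
        for key in states[0]:
            assert np.array_equal(states[0][key], states[1][key])

    def test_empty_training_set_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="at least one"):
            train_source(tiny_model, [], [], SourceTrainingConfig(epochs=1))

    def test_loss_decreases_smoothed(self, source_artifacts):
        """Window-5 smoothed Dice-loss curve of the desk run is decreasing."""
        history = np.asarray(source_artifacts["history"])
        smoothed = np.convolve(history, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] < smoothed[0]
        assert np.all(np.diff(smoothed) < 0.02)  # monotone up to small jitter
        assert smoothed[-1] < 0.1


class TestUndertrained:
    def test_corpus_size_matches_schedule_times_samples(self, tiny_config, db2):
        # 15 training samples x 6 stop epochs -> 90 pairs
        pairs = [
            generate_phantom(PhantomSpec(extents=TINY, fg_range=(0.03, 0.15), seed=s))
            for s in range(15)
        ]
        volumes = [v for v, _ in pairs]
        labels = [l for _, l in pairs]
        model = build_wavnet(tiny_config, db2)
        schedule = UndertrainedSchedule((1, 2, 3, 4, 5, 6))
        config = SourceTrainingConfig(epochs=6, learning_rate=0.05, seed=0)
        corpus = generate_undertrained_segmentations(model, volumes, labels, schedule, config)
        assert len(corpus) == 90
        for noisy, label in corpus[:8]:
            assert noisy.shape == label.shape
            assert noisy.min() >= 0.0 and noisy.max() <= 1.0

    def test_single_stop_single_sample(self, tiny_model, tiny_data):
        volumes, labels = tiny_data
        corpus = generate_undertrained_segmentations(
            tiny_model, volumes[:1], labels[:1],
            UndertrainedSchedule((1,)),
            SourceTrainingConfig(epochs=1, learning_rate=0.05),
        )
        assert len(corpus) == 1

    def test_missing_snapshot_rejected(self, tiny_model, tiny_data):
        volumes, labels = tiny_data
        with pytest.raises(ValueError, match="no snapshots"):
            generate_undertrained_segmentations(
                tiny_model, volumes, labels,
                UndertrainedSchedule((2,)),
                SourceTrainingConfig(epochs=5),
                snapshots={1: tiny_model.state_dict()},
            )


class TestTrainRefine:
    def test_empty_corpus_rejected(self, tiny_refine):
        with pytest.raises(ValueError, match="empty"):
            train_refine(tiny_refine, [])

    def test_training_on_clean_pairs_reduces_loss(self, tiny_refine, tiny_data):
        from wavtta.losses import refine_loss

        _, labels = tiny_data
        corpus = [(l.astype(float), l.astype(float)) for l in labels]
        tiny_refine.eval()
        before = np.mean([refine_loss(n, tiny_refine).item() for n, _ in corpus])
        train_refine(tiny_refine, corpus, epochs=10, learning_rate=0.2, momentum=0.9)
        tiny_refine.eval()
        after = np.mean([refine_loss(n, tiny_refine).item() for n, _ in corpus])
        assert after < before


class TestAdaptSingleSample:
    def test_zero_iterations_reproduces_source_prediction(
        self, tiny_model, tiny_refine, tiny_data
    ):
        volumes, _ = tiny_data
        state = tiny_model.state_dict()
        expected = tiny_model.predict(volumes[0])
        result = adapt_single_sample(
            tiny_model, state, ClassRatioPrior(0.05), tiny_refine, volumes[0],
            TTAConfig(iterations=0),
        )
        assert np.array_equal(result.prediction, expected)
        assert result.trace == []

    def test_frozen_parameters_bit_identical(self, tiny_model, tiny_refine, tiny_data):
        from wavtta.models import partition_parameters

        volumes, _ = tiny_data
        state = tiny_model.state_dict()
        partition = partition_parameters(tiny_model)
        result = adapt_single_sample(
            tiny_model, state, ClassRatioPrior(0.05), tiny_refine, volumes[0],
            TTAConfig(iterations=3, learning_rate=0.01),
        )
        for name in partition.frozen:
            assert np.array_equal(result.adapted_state[f"param/{name}"], state[f"param/{name}"])
        changed = [
            name
            for name in partition.adaptable
            if not np.array_equal(result.adapted_state[f"param/{name}"], state[f"param/{name}"])
        ]
        assert changed

    def test_running_buffers_untouched(self, tiny_model, tiny_refine, tiny_data):
        volumes, _ = tiny_data
        state = tiny_model.state_dict()
        result = adapt_single_sample(
            tiny_model, state, ClassRatioPrior(0.05), tiny_refine, volumes[0],
            TTAConfig(iterations=2, learning_rate=0.01),
        )
        for key in state:
            if key.startswith("buffer/"):
                assert np.array_equal(result.adapted_state[key], state[key])

    def test_trace_consistency(self, tiny_model, tiny_refine, tiny_data):
        volumes, _ = tiny_data
        state = tiny_model.state_dict()
        result = adapt_single_sample(
            tiny_model, state, ClassRatioPrior(0.05), tiny_refine, volumes[0],
            TTAConfig(iterations=3),
        )
        assert len(result.trace) == 3
        for row in result.trace:
            expected = 0.5 * row["L_en"] + 1.0 * row["L_sh"] + row["L_re"]
            assert abs(row["L_total"] - expected) < 1e-12
        frame = trace_to_frame(result.trace)
        assert list(frame.columns) == ["iteration", "L_en", "L_sh", "L_re", "L_total"]

    def test_sample_independence(self, tiny_model, tiny_refine, tiny_data):
        volumes, _ = tiny_data
        state = tiny_model.state_dict()
        config = TTAConfig(iterations=2, learning_rate=0.01)
        prior = ClassRatioPrior(0.05)
        first = adapt_single_sample(tiny_model, state, prior, tiny_refine, volumes[0], config)
        adapt_single_sample(tiny_model, state, prior, tiny_refine, volumes[1], config)
        again = adapt_single_sample(tiny_model, state, prior, tiny_refine, volumes[0], config)
        assert np.array_equal(first.prediction, again.prediction)

    def test_identity_refine_makes_sh_re_equal_sh(self, tiny_model, tiny_data):
        volumes, _ = tiny_data
        state = tiny_model.state_dict()
        prior = ClassRatioPrior(0.05)
        identity = IdentityRefine()
        a = adapt_single_sample(
            tiny_model, state, prior, identity, volumes[0],
            TTAConfig(iterations=3, ablation="sh"),
        )
        b = adapt_single_sample(
            tiny_model, state, prior, identity, volumes[0],
            TTAConfig(iterations=3, ablation="sh+re"),
        )
        assert np.array_equal(a.prediction, b.prediction)

    def test_all_background_volume_stays_finite(self, tiny_model, tiny_refine):
        state = tiny_model.state_dict()
        result = adapt_single_sample(
            tiny_model, state, ClassRatioPrior(0.05), tiny_refine,
            np.zeros(TINY),
            TTAConfig(iterations=3),
        )
        for row in result.trace:
            assert all(np.isfinite(v) for v in row.values())

    def test_non_finite_loss_aborts_with_iteration(
        self, tiny_model, tiny_refine, tiny_data, monkeypatch
    ):
        volumes, _ = tiny_data

        def bad_total(*args, **kwargs):
            nan = float("nan")
            return Tensor(nan), {"L_en": nan, "L_sh": 0.0, "L_re": 0.0, "L_total": nan}

        monkeypatch.setattr("wavtta.losses.total_loss", bad_total)
        with pytest.raises(AdaptationError, match="iteration 0"):
            adapt_single_sample(
                tiny_model, tiny_model.state_dict(), ClassRatioPrior(0.05),
                tiny_refine, volumes[0], TTAConfig(iterations=1),
            )


class TestRunAblation:
    def test_table_has_six_rows_and_total_matches_direct_run(
        self, tiny_model, tiny_refine, tiny_data
    ):
        volumes, labels = tiny_data
        state = tiny_model.state_dict()
        prior = ClassRatioPrior(0.05)
        config = TTAConfig(iterations=2, learning_rate=0.01)
        table = run_ablation(
            tiny_model, state, prior, tiny_refine,
            [(volumes[0], labels[0])], config,
        )
        assert len(table) == 6
        assert set(table["combination"]) == {"en", "sh", "re", "en+sh", "sh+re", "total"}
        direct = adapt_single_sample(
            tiny_model, state, prior, tiny_refine, volumes[0],
            TTAConfig(iterations=2, learning_rate=0.01, ablation="total"),
        )
        expected = dice_coefficient(binarize(direct.prediction), labels[0]) * 100
        total_row = table[table["combination"] == "total"].iloc[0]
        assert total_row["dsc_mean"] == pytest.approx(expected)
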