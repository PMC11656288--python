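"""Shared fixtures.

The expensive artifacts (trained desk-scale source model, undertrained
corpus, trained refine model) are session-scoped and shared between the
TTA unit tests and the acceptance tests so training happens once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from wavtta.models import (
    NetworkConfig,
    RefineNetConfig,
    build_refine_model,
    build_wavnet,
)
from wavtta.synthetic import SHIFT_PRESETS, make_benchmark
from wavtta.tta import (
    SourceTrainingConfig,
    UndertrainedSchedule,
    generate_undertrained_segmentations,
    train_refine,
    train_source,
)
from wavtta.wavelet import WaveletFilters

DESK_EXTENTS = (32, 32, 16)
DESK_SCHEDULE = (4, 6, 9, 12, 16, 20)

TINY_EXTENTS = (16, 16, 16)


@pytest.fixture(scope="session")
def db2() -> WaveletFilters:
    return WaveletFilters.from_family("db2")


@pytest.fixture(scope="session")
def desk_config() -> NetworkConfig:
    return NetworkConfig(
        stages=4, encoder_channels=(4, 8, 16, 16), base_resolution=DESK_EXTENTS
    )


@pytest.fixture(scope="session")
def tiny_config() -> NetworkConfig:
    return NetworkConfig(
        stages=4, encoder_channels=(2, 4, 4, 4), base_resolution=TINY_EXTENTS,
        subband_channels=2,
    )


@pytest.fixture(scope="session")
def desk_bench():
    """Synthetic benchmark: 6 source phantoms, 10 strong-shift targets."""
    return make_benchmark(
        n_source=6,
        n_target=10,
        shift=SHIFT_PRESETS["strong"],
        seed=1,
        extents=DESK_EXTENTS,
    )


@pytest.fixture(scope="session")
def source_artifacts(desk_config, db2, desk_bench):
    """Trained desk source model (with undertrained snapshots) and prior."""
    model = build_wavnet(desk_config, db2)
    volumes = [v for v, _ in desk_bench.source]
    labels = [l for _, l in desk_bench.source]
    config = SourceTrainingConfig(epochs=60, learning_rate=0.05, momentum=0.9, seed=0)
    result = train_source(model, volumes, labels, config, snapshot_epochs=DESK_SCHEDULE)
    model.load_state_dict(result.state)
    return {
        "model": model,
        "config": config,
        "state": result.state,
        "prior": result.prior,
        "history": result.history,
        "snapshots": result.snapshots,
        "volumes": volumes,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def refine_artifacts(source_artifacts):
    """Refine model trained on the undertrained-segmentation corpus."""
    model = source_artifacts["model"]
    schedule = UndertrainedSchedule(DESK_SCHEDULE)
    corpus = generate_undertrained_segmentations(
        model,
        source_artifacts["volumes"],
        source_artifacts["labels"],
        schedule,
        source_artifacts["config"],
        snapshots=source_artifacts["snapshots"],
    )
    model.load_state_dict(source_artifacts["state"])
    refine = build_refine_model(RefineNetConfig(channels=(4, 8, 16, 16)))
    train_refine(refine, corpus, epochs=30, learning_rate=0.2, momentum=0.9, seed=0)
    return {"refine": refine, "corpus": corpus}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
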