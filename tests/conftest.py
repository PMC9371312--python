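from pathlib import Path

import numpy as np
import pytest

REPO_ROOT = Path(__file__).resolve().parents[1]
CONFIG_DIR = REPO_ROOT / "configs"

from ctgnet.backbone import BackboneConfig
from ctgnet.model import ClsConfig, FineConfig, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_model_cfg():
    """Smallest structurally complete model: 32x32 images, 4x4 feature grid."""
    return ModelConfig(
        image_size=32,
        backbone=BackboneConfig(kind="lightweight", channels=16,
                                widths=(4, 8, 8, 16), aspp_rates=(1, 2),
                                stride=8),
        cls=ClsConfig(d1=8, num_classes=2),
        fine=FineConfig(),
        decoder_widths=(8, 8, 4, 4),
    )


@pytest.fixture(scope="session")
def desk_runs(tmp_path_factory):
    """Three seeded desk-scale experiments (shared across tests).

    Conditions: 64x64 phantoms, 200 train / 50 val / 50 test, lightweight
    backbone, 20 epochs. Returns per-seed dicts with the training log and the
    held-out metrics row.
    """
    import pandas as pd

    from ctgnet.train import run_experiment

    base = tmp_path_factory.mktemp("desk_runs")
    runs = []
    for seed in (0, 1, 2):
        out = base / f"seed{seed}"
        metrics = run_experiment(CONFIG_DIR / "desk.yaml", out, seed=seed)
        log = pd.read_csv(out / "train_log.csv")
        runs.append({"seed": seed, "metrics": metrics.iloc[0], "log": log,
                     "dir": out})
    return runs
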