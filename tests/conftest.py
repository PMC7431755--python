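import numpy as np
import pandas as pd
import pytest

from hccapa import SimulationConfig
from hccapa.quantify import extract_features
from hccapa.segmentation import segment_field
from hccapa.synthgen import field_rng, render_field, sample_population


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def stable_field(sim_config):
    """One noisy stable-mode field plus its ground truth (seeded)."""
    rng = field_rng(101, "F1", 1)
    cells = sample_population(sim_config, "stable", 0.0, rng)
    field = render_field(cells, sim_config, rng, well_id="F1", field_index=1)
    return cells, field


@pytest.fixture(scope="session")
def stable_masks(stable_field, sim_config):
    _, field = stable_field
    return segment_field(field)


@pytest.fixture(scope="session")
def clean_field(sim_config):
    """Noise-free, damage-free stable field: exact-signal oracle fixture."""
    cfg = sim_config.replace(p_damaged=0.0, offtarget_amplitude=0.0)
    rng = field_rng(202, "C1", 1)
    cells = sample_population(cfg, "stable", 0.0, rng)
    field = render_field(cells, cfg, rng, noise=False)
    return cfg, cells, field


def collect_records(config, mode, n_fields, seed, concentration=0.0):
    """Render + segment + feature-extract a batch of fields."""
    frames = []
    for i in range(1, n_fields + 1):
        rng = field_rng(seed, "W", i)
        cells = sample_population(config, mode, concentration, rng)
        field = render_field(cells, config, rng, well_id="W", field_index=i)
        masks = segment_field(field)
        rec = extract_features(field, masks, "W", i, concentration)
        rec["bg_sd"] = masks.background["gfp"][1]
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def stable_records(sim_config):
    """~1200 segmented stable-mode cells with default damage rate."""
    return collect_records(sim_config, "stable", 20, 7)


@pytest.fixture(scope="session")
def transient_records(sim_config):
    """~1200 segmented transient-mode cells, damage off (gate fixture)."""
    cfg = sim_config.replace(p_damaged=0.0)
    return collect_records(cfg, "transient", 20, 11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
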