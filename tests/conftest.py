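import numpy as np
import pandas as pd
import pytest

from apicaltrack.genotype import annotate_dataset
from apicaltrack.dynamics import summarize
from apicaltrack.preprocess import preprocess_dataset
from apicaltrack.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small anterior-like mosaic movie with one scripted T1."""
    cfg = SyntheticConfig(n_cells=30, n_frames=40, seed=11,
                          scripted_t1_frames=[15])
    return simulate(cfg)


@pytest.fixture(scope="session")
def processed(small_sim):
    """small_sim run through the full preprocessing + annotation pipeline."""
    cfg = small_sim.config
    ec = cfg.embryo_config()
    ds = preprocess_dataset(small_sim.dataset, {cfg.movie: ec})
    cells, labels, flags = annotate_dataset(
        ds.cells, {cfg.movie: small_sim.adjacency}, {cfg.movie: ec})
    ds.cells = cells
    return summarize(ds, flags)


def make_track(track_id, n_frames, values, movie="m1", region="anterior"):
    """Minimal cell-table rows for one track with a given area series."""
    return pd.DataFrame({
        "region": region,
        "movie": movie,
        "track_id_cells": track_id,
        "minute": np.arange(1, n_frames + 1),
        "apical_area_pixels": np.asarray(values, dtype=float),
        "medial_actin": 100.0 + np.arange(n_frames, dtype=float),
        "junctional_actin": 100.0,
        "medial_Ncadherin": 100.0,
        "junctional_Ncadherin": 100.0,
        "medial_memBFP": 100.0,
        "junctional_memBFP": 100.0,
    })
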