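"""Filtering, smoothing, standardization, masking, unit conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apicaltrack.preprocess import (
    filter_tracks,
    mask_frames,
    preprocess_dataset,
    smooth_series,
    standardize_series,
    to_microns,
)
from apicaltrack.tables_io import Dataset, EmbryoConfig
from tests.conftest import make_track


@pytest.mark.parametrize("n_frames,kept", [(29, False), (30, True), (31, True)])
def test_cell_track_length_filter_boundary(n_frames, kept):
    ds = Dataset(cells=make_track(1, n_frames, np.full(n_frames, 50.0)))
    out = filter_tracks(ds)
    assert (len(out.cells) > 0) == kept


@pytest.mark.parametrize("n_frames,kept", [(14, False), (15, True)])
def test_junction_track_length_filter_boundary(n_frames, kept):
    jx = pd.DataFrame({
        "region": "anterior", "movie": "m", "track_id_junctions": "j1",
        "minute": np.arange(1, n_frames + 1),
        "vx_1_x": 0.0, "vx_1_y": 0.0, "vx_2_x": 1.0, "vx_2_y": 0.0,
    })
    out = filter_tracks(Dataset(junctions=jx))
    assert (len(out.junctions) > 0) == kept


def test_filter_empty_dataset_is_noop():
    out = filter_tracks(Dataset(cells=make_track(1, 5, np.ones(5)).iloc[0:0]))
    assert len(out.cells) == 0


def test_smooth_constant_and_ramp():
    assert np.allclose(smooth_series(np.full(20, 3.0)), 3.0)
    ramp = np.arange(20, dtype=float)
    sm = smooth_series(ramp)
    # interior frames of a linear ramp are unchanged by a centered mean
    np.testing.assert_allclose(sm[3:-3], ramp[3:-3])
    # first frame: truncated window covers frames 0..3 -> mean 1.5
    assert sm[0] == pytest.approx(1.5)


def test_smooth_requires_odd_window():
    with pytest.raises(ValueError):
        smooth_series(np.ones(10), window=4)


def test_smooth_masked_frames_excluded_and_stay_masked():
    v = np.arange(10, dtype=float)
    v[4] = np.nan
    sm = smooth_series(v)
    assert np.isnan(sm[4])
    # window at frame 2 covers 0..5 minus the masked frame 4
    assert sm[2] == pytest.approx(np.mean([0, 1, 2, 3, 5]))


def test_smooth_is_shift_equivariant():
    rng = np.random.default_rng(0)
    v = rng.normal(size=30)
    np.testing.assert_allclose(smooth_series(v + 7.5), smooth_series(v) + 7.5)


def test_standardize_simple_and_degenerate():
    out, deg = standardize_series(np.array([1.0, 2.0, 3.0]))
    assert not deg
    assert out.mean() == pytest.approx(0.0, abs=1e-12)
    assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    _, deg = standardize_series(np.full(10, 2.0))
    assert deg
    _, deg = standardize_series(np.array([1.0, np.nan]))
    assert deg


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60).filter(
    lambda v: np.std(v) > 1e-9))
def test_standardize_properties(values):
    """Mean 0 / s.d. 1 within 1e-9, and idempotence up to tolerance."""
    out, deg = standardize_series(np.array(values))
    assert not deg
    assert abs(np.nanmean(out)) < 1e-9
    assert abs(np.nanstd(out, ddof=1) - 1.0) < 1e-9
    twice, _ = standardize_series(out)
    np.testing.assert_allclose(twice, out, atol=1e-9)


def test_mask_frames_hits_fluorescence_not_geometry():
    n = 50
    cells = make_track(1, n, np.linspace(100, 50, n))
    cfg = EmbryoConfig(movie="m1", masked_frame_ranges=[(23, 45)])
    out = mask_frames(Dataset(cells=cells), {"m1": cfg})
    masked = out.cells["minute"].between(23, 45)
    assert out.cells.loc[masked, "medial_actin"].isna().all()
    assert out.cells.loc[masked, "apical_area_pixels"].notna().all()
    # empty mask list leaves the dataset unchanged
    out2 = mask_frames(Dataset(cells=cells), {"m1": EmbryoConfig(movie="m1")})
    pd.testing.assert_frame_equal(out2.cells, cells)


def test_masked_frames_excluded_from_smoothing_windows():
    n = 50
    cells = make_track(1, n, np.linspace(100, 50, n))
    cfg = EmbryoConfig(movie="m1", masked_frame_ranges=[(23, 45)])
    ds = preprocess_dataset(Dataset(cells=cells), {"m1": cfg})
    row22 = ds.cells[ds.cells["minute"] == 22].iloc[0]
    # window at frame 22 covers minutes 19..25; 23..25 are masked
    raw = cells.set_index("minute")["medial_actin"]
    expected = raw.loc[19:22].mean()
    assert row22["medial_actin_smoothed"] == pytest.approx(expected)
    masked = ds.cells["minute"].between(23, 45)
    assert ds.cells.loc[masked, "medial_actin_smoothed"].isna().all()
    assert ds.cells.loc[masked, "medial_actin_standardized"].isna().all()


@pytest.mark.parametrize("px,kind,scale,expected", [
    (100.0, "area", 0.5, 25.0),
    (10.0, "length", 0.5, 5.0),
    (42.0, "length", 1.0, 42.0),
])
def test_to_microns(px, kind, scale, expected):
    cfg = EmbryoConfig(microns_per_pixel=scale)
    assert to_microns(px, kind, cfg) == pytest.approx(expected)


def test_preprocess_fills_standardized_and_corrected_columns(processed):
    cells = processed.cells
    assert cells["apical_area_standardized"].notna().any()
    for (m, t), grp in cells.groupby(["movie", "track_id_cells"]):
        vals = grp["apical_area_standardized"].dropna()
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std(ddof=1) - 1.0) < 1e-9
    jx = processed.junctions
    assert (jx["length_corrected"] >= jx["length_micron"] - 1e-12).all()
    assert jx["orientation"].between(0, 90).all()
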