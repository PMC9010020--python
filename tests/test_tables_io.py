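"""Schema, round-trip, and invariant validation of the tracked tables."""

import numpy as np
import pandas as pd
import pytest

from apicaltrack.tables_io import (
    Dataset,
    EmbryoConfig,
    SchemaError,
    encode_vertices,
    parse_vertices,
    read_tables,
    validate,
    write_tables,
)


def test_write_read_round_trip(small_sim, tmp_path):
    """Writing then reading a validated dataset reproduces every value."""
    ds = small_sim.dataset
    write_tables(ds, tmp_path)
    back = read_tables(tmp_path)
    for (name, df1), (_, df2) in zip(ds.tables(), back.tables()):
        assert list(df1.columns) == list(df2.columns)
        for col in df1.columns:
            a, b = df1[col], df2[col]
            if a.dtype.kind == "f" or b.dtype.kind == "f":
                np.testing.assert_allclose(
                    a.astype(float), b.astype(float), rtol=0, atol=1e-9)
            else:
                assert a.astype(str).tolist() == b.astype(str).tolist(), col


def test_second_write_is_byte_identical(small_sim, tmp_path):
    """write -> read -> write is a fixed point of serialization."""
    ds = small_sim.dataset
    p1 = write_tables(ds, tmp_path / "a")
    back = read_tables(tmp_path / "a")
    p2 = write_tables(back, tmp_path / "b")
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes()


def test_missing_mandatory_column_is_schema_error(tmp_path):
    df = pd.DataFrame({"region": ["anterior"], "movie": ["m"], "minute": [1]})
    df.to_csv(tmp_path / "cell_surfaces.csv", index=False)
    with pytest.raises(SchemaError, match="track_id_cells"):
        read_tables(tmp_path)


def test_unparseable_cell_names_location(tmp_path):
    df = pd.DataFrame({
        "region": ["anterior"], "movie": ["m"], "track_id_cells": [1],
        "minute": [1], "apical_area_pixels": ["not-a-number"],
    })
    df.to_csv(tmp_path / "cell_surfaces.csv", index=False)
    with pytest.raises(SchemaError, match="apical_area_pixels"):
        read_tables(tmp_path)


def test_nan_serialized_as_empty_string(tmp_path):
    cells = pd.DataFrame({
        "region": ["anterior"], "movie": ["m"], "track_id_cells": [1],
        "minute": [1], "apical_area_pixels": [10.0],
        "medial_actin": [np.nan],
    })
    paths = write_tables(Dataset(cells=cells), tmp_path)
    text = paths["cell_surfaces"].read_text()
    last = text.strip().splitlines()[-1]
    assert last.endswith(",")  # trailing empty field, not "nan" or "0"
    back = read_tables(tmp_path)
    assert np.isnan(back.cells["medial_actin"].iloc[0])


def test_na_literal_accepted_on_read(tmp_path):
    (tmp_path / "cell_surfaces.csv").write_text(
        "region,movie,track_id_cells,minute,apical_area_pixels\n"
        "anterior,m,1,1,NA\n")
    back = read_tables(tmp_path)
    assert np.isnan(back.cells["apical_area_pixels"].iloc[0])


def test_misspelled_standardized_alias_normalized(tmp_path):
    (tmp_path / "cell_surfaces.csv").write_text(
        "region,movie,track_id_cells,minute,apical_area_standarized\n"
        "anterior,m,1,1,0.5\n")
    back = read_tables(tmp_path)
    assert "apical_area_standardized" in back.cells.columns


def test_unknown_extra_column_preserved_with_warning(tmp_path):
    (tmp_path / "cell_surfaces.csv").write_text(
        "region,movie,track_id_cells,minute,mystery\n"
        "anterior,m,1,1,42\n")
    with pytest.warns(UserWarning, match="mystery"):
        back = read_tables(tmp_path)
    assert back.cells["mystery"].iloc[0] == 42


def test_vertex_codec_round_trip():
    vx = np.array([[1.5, 2.0], [3.25, 4.0], [5.0, 6.75]])
    text = encode_vertices(vx)
    assert "#" in text and ":" in text
    np.testing.assert_allclose(parse_vertices(text), vx)


@pytest.mark.parametrize(
    "column,bad_value,expected",
    [
        ("orientation", 95.0, "orientation"),
        ("delta_z_micron", -1.0, "delta_z_micron"),
    ],
)
def test_validate_flags_junction_range_violations(column, bad_value, expected):
    jx = pd.DataFrame({
        "region": ["anterior"], "movie": ["m"], "track_id_junctions": ["j1"],
        "minute": [1], column: [bad_value],
    })
    report = validate(Dataset(junctions=jx))
    assert len(report) == 1
    assert expected in str(report)


def test_validate_flags_badly_standardized_series():
    n = 10
    vals = np.random.default_rng(0).normal(size=n)
    vals = (vals - vals.mean()) / vals.std(ddof=1) + 0.5  # mean 0.5
    cells = pd.DataFrame({
        "region": "anterior", "movie": "m", "track_id_cells": 1,
        "minute": np.arange(1, n + 1), "apical_area_standardized": vals,
    })
    report = validate(Dataset(cells=cells))
    assert len(report) == 1
    assert "mean" in str(report)


def test_validate_clean_on_generator_output(small_sim):
    assert validate(small_sim.dataset).ok


def test_embryo_config_yaml_round_trip(tmp_path):
    cfg = EmbryoConfig(movie="b", region="posterior", microns_per_pixel=0.4,
                       masked_frame_ranges=[(23, 45)],
                       genotype_overrides={7: "control"})
    cfg.to_yaml(tmp_path / "cfg.yaml")
    back = EmbryoConfig.from_yaml(tmp_path / "cfg.yaml")
    assert back.masked_frame_ranges == [(23, 45)]
    assert back.microns_per_pixel == 0.4


def test_embryo_config_rejects_bad_values():
    with pytest.raises(ValueError):
        EmbryoConfig(microns_per_pixel=0)
    with pytest.raises(ValueError):
        EmbryoConfig(masked_frame_ranges=[(10, 5)])
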