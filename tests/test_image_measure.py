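"""Domain splitting and intensity measurement on label images."""

import numpy as np
import pytest

from apicaltrack.image_measure import (
    LabelFrame,
    junction_pixels_and_z,
    mean_intensity,
    measure_cell,
    split_domains,
)


def square_frame():
    """One 5×5 cell (label 1) surrounded by a skeleton ring."""
    labels = np.zeros((9, 9), dtype=int)
    labels[2:7, 2:7] = 1
    return LabelFrame(labels=labels, channels={"c": np.ones((9, 9)) * 7.0})


def two_cell_frame():
    """Two cells separated by a 1-px vertical skeleton column."""
    labels = np.zeros((7, 9), dtype=int)
    labels[1:6, 1:4] = 1
    labels[1:6, 5:8] = 2
    chan = np.arange(63, dtype=float).reshape(7, 9)
    return LabelFrame(labels=labels, channels={"c": chan})


def test_medial_mask_of_square_is_interior():
    frame = square_frame()
    medial, junctional, degenerate = split_domains(frame, 1)
    assert not degenerate
    assert medial.sum() == 9  # 3×3 interior of a 5×5 square
    assert not (medial & junctional).any()
    assert measure_cell(frame, 1).apical_area_pixels == 9


def test_one_pixel_wide_cell_is_degenerate():
    labels = np.zeros((5, 7), dtype=int)
    labels[2, 1:6] = 1
    frame = LabelFrame(labels=labels, channels={"c": np.ones((5, 7))})
    medial, _, degenerate = split_domains(frame, 1)
    assert degenerate and medial.sum() == 0
    m = measure_cell(frame, 1)
    assert m.degenerate and np.isnan(m.medial_means["c"])


def test_missing_cell_raises():
    with pytest.raises(ValueError):
        split_domains(square_frame(), 99)


def test_mean_intensity_uniform_and_tiny():
    frame = square_frame()
    medial, junctional, _ = split_domains(frame, 1)
    assert mean_intensity(medial, frame.channels["c"]) == 7.0
    mask = np.zeros((2, 2), dtype=bool)
    mask[0, 0] = mask[0, 1] = True
    assert mean_intensity(mask, np.array([[1.0, 3.0], [9.0, 9.0]])) == 2.0


def test_mean_intensity_matches_pixel_loop_oracle():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, (20, 20)).astype(float)
    mask = rng.random((20, 20)) > 0.6
    total, count = 0.0, 0
    for y in range(20):
        for x in range(20):
            if mask[y, x]:
                total += img[y, x]
                count += 1
    assert mean_intensity(mask, img) == total / count


def test_uniform_channel_gives_equal_domain_means():
    m = measure_cell(square_frame(), 1)
    assert m.medial_means["c"] == m.junctional_means["c"] == 7.0


def test_junctional_masks_meet_on_shared_skeleton():
    frame = two_cell_frame()
    _, j1, _ = split_domains(frame, 1)
    _, j2, _ = split_domains(frame, 2)
    shared = j1 & j2
    ys, xs = np.nonzero(shared)
    assert set(xs) == {4}  # the separating column
    # 8-adjacency reaches one row beyond each cell end via the diagonals
    assert set(ys) == {0, 1, 2, 3, 4, 5, 6}


def test_junction_pixels_by_hand_enumeration():
    """Three cells meeting at a T: pairwise junction pixels exclude vertices."""
    labels = np.zeros((9, 9), dtype=int)
    labels[1:4, 1:4] = 1   # top-left
    labels[1:4, 5:8] = 2   # top-right
    labels[5:8, 1:8] = 3   # bottom
    frame = LabelFrame(labels=labels, channels={})
    pix12, _, _ = junction_pixels_and_z(frame, 1, 2)
    ys, xs = np.nonzero(pix12)
    # the 1|2 junction is the column x=4 alongside rows 0..3 (diagonal reach
    # at the top border); the pixel at (4, 4) touches cell 3 and is a vertex
    assert set(xs) == {4} and set(ys) == {0, 1, 2, 3}
    pix13, _, _ = junction_pixels_and_z(frame, 1, 3)
    ys, xs = np.nonzero(pix13)
    assert set(ys) == {4} and set(xs) == {0, 1, 2, 3}


def test_non_adjacent_pair_raises():
    labels = np.zeros((5, 11), dtype=int)
    labels[1:4, 1:4] = 1
    labels[1:4, 7:10] = 2
    frame = LabelFrame(labels=labels, channels={})
    with pytest.raises(ValueError, match="not adjacent"):
        junction_pixels_and_z(frame, 1, 2)


def six_cell_frame():
    """2 columns × 3 rows of cells; the middle junction has two interior
    vertices at (y=4, x=4) and (y=8, x=4)."""
    labels = np.zeros((13, 9), dtype=int)
    for row, y0 in enumerate((1, 5, 9)):
        labels[y0:y0 + 3, 1:4] = 2 * row + 1
        labels[y0:y0 + 3, 5:8] = 2 * row + 2
    return LabelFrame(labels=labels, channels={})


def test_z_lookup_argmax_and_delta():
    frame = six_cell_frame()
    stack = np.zeros((6, 13, 9))
    # bright voxels at different depths under the two vertices of the
    # junction between cells 3 and 4
    stack[1, 4, 4] = 10.0
    stack[4, 8, 4] = 10.0
    _, _, dz = junction_pixels_and_z(frame, 3, 4, z_stack=stack,
                                     z_step_micron=0.5)
    assert dz == pytest.approx((4 - 1) * 0.5)
    # identical depths -> delta 0; argmax ties resolve to smallest z
    stack2 = np.ones((6, 13, 9))
    _, _, dz2 = junction_pixels_and_z(frame, 3, 4, z_stack=stack2)
    assert dz2 == 0.0


def test_domain_partition_accounting(small_sim):
    """Medial areas + junctional belt + skeleton cover each cell's region."""
    from apicaltrack.synthetic import render_frames

    frames = render_frames(small_sim, [0])
    frame = frames[0]
    for cell in frame.cell_ids()[:10]:
        region = frame.labels == cell
        medial, junctional, _ = split_domains(frame, cell)
        assert not (medial & junctional).any()
        assert medial.sum() < region.sum()
        assert (medial <= region).all()
        assert not (junctional & (frame.labels > 0)).any()
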