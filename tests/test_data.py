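"""Data model: CSV dialects, confidence filtering, windowing, preprocessing,
labels and the dataset directory round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ethoclust as ec
from ethoclust.data import FormatError, apply_labels

from conftest import make_segments


# ---------------------------------------------------------------------------
# keypoint CSV readers

def write_dlc_csv(path, bodyparts, rows, drop_likelihood_for=None):
    coords = ["x", "y", "likelihood"]
    header1 = ["scorer"] + ["model"] * (len(bodyparts) * 3)
    header2 = ["bodyparts"] + [bp for bp in bodyparts for _ in coords]
    header3 = ["coords"] + coords * len(bodyparts)
    if drop_likelihood_for is not None:
        # corrupt header row 3: one keypoint loses its likelihood column
        i = 1 + 3 * drop_likelihood_for + 2
        header3[i] = "y"
    lines = [",".join(header1), ",".join(header2), ",".join(header3)]
    for r, row in enumerate(rows):
        lines.append(",".join([str(r)] + [f"{v}" for v in row]))
    path.write_text("\n".join(lines) + "\n")


def test_dlc_csv_parses_to_frame_table(tmp_path):
    p = tmp_path / "video.csv"
    rows = [[i + j / 10 for j in range(6)] for i in range(5)]
    write_dlc_csv(p, ["snout", "tail"], rows)
    table = ec.read_keypoint_csv(p, dialect="deeplabcut")
    assert table.values.shape == (5, 6)
    assert table.keypoint_names == ["snout", "tail"]
    assert table.has_likelihood
    np.testing.assert_allclose(table.values, np.array(rows))
    # coordinate block drops likelihoods, keypoint-major order preserved
    assert table.coord_values.shape == (5, 4)
    assert table.coord_names == ["snout_x", "snout_y", "tail_x", "tail_y"]


def test_plain_csv_parses(tmp_path):
    p = tmp_path / "features.csv"
    p.write_text("f1,f2,f3,f4\n1,2,3,4\n5,6,7,8\n9,10,11,12\n")
    table = ec.read_keypoint_csv(p, dialect="plain")
    assert table.values.shape == (3, 4)
    assert table.column_names == ["f1", "f2", "f3", "f4"]
    assert not table.has_likelihood


def test_dlc_missing_likelihood_is_format_error(tmp_path):
    p = tmp_path / "bad.csv"
    rows = [[0.0] * 6 for _ in range(3)]
    write_dlc_csv(p, ["snout", "tail"], rows, drop_likelihood_for=1)
    with pytest.raises(FormatError, match="likelihood"):
        ec.read_keypoint_csv(p, dialect="deeplabcut")


def test_ragged_rows_are_format_error(tmp_path):
    p = tmp_path / "ragged.csv"
    p.write_text("f1,f2\n1,2\n3,4,5,6,7\n")
    with pytest.raises(FormatError):
        ec.read_keypoint_csv(p, dialect="plain")


def test_unknown_dialect_rejected(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("a\n1\n")
    with pytest.raises(ValueError, match="dialect"):
        ec.read_keypoint_csv(p, dialect="hdf5")


# ---------------------------------------------------------------------------
# confidence filtering

def frame_table_with_likelihoods(likelihoods):
    """Two keypoints; coords constant, per-frame likelihoods as given."""
    R = len(likelihoods)
    values = np.zeros((R, 6))
    values[:, 2] = likelihoods  # snout likelihood
    values[:, 5] = likelihoods  # tail likelihood
    names = ["snout_x", "snout_y", "snout_likelihood",
             "tail_x", "tail_y", "tail_likelihood"]
    return ec.FrameTable(values, names, ["snout", "tail"], True)


def test_confidence_threshold_boundaries():
    table = frame_table_with_likelihoods([0.0, 0.5, 0.99, 1.0])
    _, mask0 = ec.filter_by_confidence(table, 0.0)
    assert mask0.all()  # threshold 0 -> every frame passes
    _, mask1 = ec.filter_by_confidence(table, 1.0)
    # threshold 1: the 0.99 frame fails
    np.testing.assert_array_equal(mask1, [False, False, False, True])
    with pytest.raises(ValueError):
        ec.filter_by_confidence(table, 1.5)


def test_segment_confidence_fraction_rule():
    """8 of 10 passing frames is below the default 0.9 minimum fraction."""
    lik = [1.0] * 8 + [0.1, 0.1]
    table = frame_table_with_likelihoods(lik)
    coords, mask = ec.filter_by_confidence(table, 0.9)
    segs = ec.fixed_window_segment(coords, 10, 10, pass_mask=mask,
                                   min_pass_fraction=0.9)
    assert len(segs) == 1
    assert not segs[0].confidence_ok


# ---------------------------------------------------------------------------
# fixed-window segmentation

def plain_table(R, F=4):
    vals = np.arange(R * F, dtype=float).reshape(R, F)
    return ec.FrameTable(vals, [f"f{i}" for i in range(F)])


def test_window_examples():
    segs = ec.fixed_window_segment(plain_table(35), 10, 10)
    assert len(segs) == 3
    assert [(s.start_frame, s.end_frame) for s in segs] == [(0, 9), (10, 19), (20, 29)]
    assert len(ec.fixed_window_segment(plain_table(10), 10, 10)) == 1
    with pytest.warns(UserWarning):
        assert ec.fixed_window_segment(plain_table(9), 10, 10) == []


@settings(max_examples=200, deadline=None)
@given(st.integers(1, 100).flatmap(
    lambda R: st.tuples(st.just(R), st.integers(1, R), st.integers(1, R))))
def test_window_count_matches_closed_form(Rws):
    R, window, stride = Rws
    segs = ec.fixed_window_segment(plain_table(R), window, stride)
    assert len(segs) == (R - window) // stride + 1
    for s in segs:
        assert s.n_frames == window


# ---------------------------------------------------------------------------
# preprocessing

def test_zscore_two_point_feature():
    ds = make_segments([[[0.0], [2.0]]])
    out, stats = ec.preprocess(ds, mode="zscore")
    np.testing.assert_allclose(out.segments[0].frames.ravel(), [-1.0, 1.0])
    assert stats.mean[0] == 1.0 and stats.std[0] == 1.0  # population std


def test_constant_feature_flagged_and_zeroed():
    ds = make_segments([[[3.0, 1.0], [3.0, 2.0]]])
    out, stats = ec.preprocess(ds)
    assert 0 in stats.constant_features
    np.testing.assert_allclose(out.segments[0].frames[:, 0], 0.0)


def test_mode_none_is_identity():
    ds = make_segments([[[1.0, 2.0], [3.0, 4.0]]])
    out, _ = ec.preprocess(ds, mode="none")
    np.testing.assert_array_equal(out.segments[0].frames, ds.segments[0].frames)


def test_double_preprocess_rejected_and_test_needs_stats():
    ds = make_segments([[[0.0], [2.0]]])
    out, stats = ec.preprocess(ds)
    with pytest.raises(ValueError, match="twice"):
        ec.preprocess(out)
    test = make_segments([[[1.0], [5.0]]], split="test")
    with pytest.raises(ValueError, match="train"):
        ec.preprocess(test)
    ok = ec.apply_preprocess(test, stats)
    np.testing.assert_allclose(ok.segments[0].frames.ravel(), [0.0, 4.0])


def test_zscore_inverse_recovers_input():
    rng = np.random.default_rng(0)
    ds = make_segments([rng.normal(size=(6, 4)) for _ in range(5)])
    out, stats = ec.preprocess(ds)
    back = ec.inverse_preprocess(out, stats)
    for a, b in zip(back.segments, ds.segments):
        np.testing.assert_allclose(a.frames, b.frames, atol=1e-10)


# ---------------------------------------------------------------------------
# labels

def test_labels_roundtrip(tmp_path):
    classes = ["walk", "rest", "groom"]
    labels = {f"s{i:03d}": i % 3 for i in range(5)}
    p = tmp_path / "labels.csv"
    ec.write_labels(labels, classes, p)
    assert ec.read_labels(p, classes) == labels


def test_unknown_class_lists_vocabulary(tmp_path):
    p = tmp_path / "labels.csv"
    p.write_text("segment_id,class_name\ns000,fly\n")
    with pytest.raises(FormatError, match="walk"):
        ec.read_labels(p, ["walk", "rest"])


def test_empty_labels_file(tmp_path):
    p = tmp_path / "labels.csv"
    p.write_text("segment_id,class_name\n")
    assert ec.read_labels(p, ["walk"]) == {}


def test_apply_labels_unknown_segment():
    ds = make_segments([[[0.0]]], class_names=["a"])
    with pytest.raises(FormatError, match="nope"):
        apply_labels(ds, {"nope": 0})


def test_label_outside_vocabulary_rejected():
    ds = make_segments([[[0.0]]], class_names=["a", "b"])
    with pytest.raises(ValueError, match="vocabulary"):
        ds.set_label(0, 5)


# ---------------------------------------------------------------------------
# domain type invariants and the directory round-trip

def test_segment_invariants():
    with pytest.raises(ValueError, match="bounds"):
        ec.KeypointSegment(np.zeros((5, 2)), "x", start_frame=0, end_frame=3)
    with pytest.raises(ValueError, match="finite"):
        ec.KeypointSegment(np.array([[np.nan]]), "x")
    with pytest.raises(ValueError):
        ec.SegmentDataset(
            [ec.KeypointSegment(np.zeros((2, 2)), "a"),
             ec.KeypointSegment(np.zeros((2, 3)), "b")],
            ["c0"],
        )


def test_dataset_roundtrip_bit_exact(tmp_path, tiny_dataset):
    train, _ = tiny_dataset
    ec.save_dataset(train, tmp_path / "ds")
    back = ec.load_dataset(tmp_path / "ds")
    assert back.class_names == train.class_names
    assert back.split == train.split
    np.testing.assert_array_equal(back.labeled_mask, train.labeled_mask)
    np.testing.assert_array_equal(back.labels, train.labels)
    for a, b in zip(back.segments, train.segments):
        assert a.segment_id == b.segment_id
        assert a.frames.dtype == b.frames.dtype
        assert np.array_equal(a.frames, b.frames)  # bit-exact


def test_padded_arrays_mask_matches_lengths(tiny_dataset):
    train, _ = tiny_dataset
    X, mask = train.padded_arrays()
    lengths = mask.sum(axis=1).astype(int)
    for i, s in enumerate(train.segments):
        assert lengths[i] == s.n_frames
        np.testing.assert_array_equal(X[i, : s.n_frames], s.frames)
        assert np.all(X[i, s.n_frames:] == 0)
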