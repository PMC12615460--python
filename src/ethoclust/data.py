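"""Domain types and I/O for keypoint-segment datasets.

A *segment* is a short clip of pose-tracking output: a T x F matrix with one
row per video frame and one column per feature.  For raw keypoints the
feature layout is keypoint-major, coordinate-minor (x1, y1[, z1], x2, y2,
...), matching the column order of the source CSV; for kinematic features
the columns are whatever the upstream feature extractor produced.

Readers cover the DeepLabCut CSV dialect (three header rows:
scorer / bodyparts / coords, with x, y, likelihood triplets per bodypart)
and plain single-header CSV.  Continuous recordings are cut into
fixed-duration windows; frames whose pose-estimation likelihood falls below
a confidence threshold can flag the enclosing segment as unreliable.

Datasets serialize to a directory (manifest.csv + meta.json + segments.npz)
and round-trip bit-exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "KeypointSegment",
    "SegmentDataset",
    "PreprocessStats",
    "FrameTable",
    "FormatError",
    "read_keypoint_csv",
    "filter_by_confidence",
    "fixed_window_segment",
    "preprocess",
    "apply_preprocess",
    "inverse_preprocess",
    "read_labels",
    "write_labels",
    "save_dataset",
    "load_dataset",
]


class FormatError(ValueError):
    """Malformed input file (bad header, ragged rows, unknown ids)."""


@dataclass
class KeypointSegment:
    """One temporal segment of keypoint or kinematic features.

    ``frames`` is a T x F float matrix (T >= 1 frames, F >= 1 features).
    ``label`` is a class index into the owning dataset's vocabulary, or None
    while the segment is unannotated.  ``confidence_ok`` records whether the
    segment passed the pose-confidence filter.
    """

    frames: np.ndarray
    segment_id: str
    source_video: str | None = None
    start_frame: int | None = None
    end_frame: int | None = None
    label: int | None = None
    confidence_ok: bool = True

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1 or self.frames.shape[1] < 1:
            raise ValueError(
                f"segment {self.segment_id!r}: frames must be T x F with T,F >= 1, "
                f"got shape {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError(f"segment {self.segment_id!r}: non-finite entries")
        if self.start_frame is not None and self.end_frame is not None:
            if self.start_frame < 0:
                raise ValueError(f"segment {self.segment_id!r}: negative start_frame")
            if self.end_frame - self.start_frame + 1 != self.n_frames:
                raise ValueError(
                    f"segment {self.segment_id!r}: frame bounds "
                    f"[{self.start_frame}, {self.end_frame}] inconsistent with "
                    f"T={self.n_frames}"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_features(self) -> int:
        return self.frames.shape[1]


@dataclass
class SegmentDataset:
    """Ordered collection of segments with a fixed class vocabulary.

    The label mask is derived: segment i is labeled iff segments[i].label is
    set.  The vocabulary is fixed at creation; labels arriving later (e.g.
    from annotation rounds) must use it.
    """

    segments: list[KeypointSegment]
    class_names: list[str]
    split: str = "train"
    preprocessed: bool = False
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")
        if self.segments:
            F = self.segments[0].n_features
            for s in self.segments:
                if s.n_features != F:
                    raise ValueError(
                        f"feature count mismatch: segment {s.segment_id!r} has "
                        f"F={s.n_features}, expected {F}"
                    )
        C = len(self.class_names)
        for s in self.segments:
            if s.label is not None and not (0 <= s.label < C):
                raise ValueError(
                    f"segment {s.segment_id!r}: label {s.label} outside [0, {C})"
                )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_features(self) -> int:
        if not self.segments:
            raise ValueError("empty dataset has no feature count")
        return self.segments[0].n_features

    @property
    def labeled_mask(self) -> np.ndarray:
        return np.array([s.label is not None for s in self.segments], dtype=bool)

    @property
    def labels(self) -> np.ndarray:
        """Label vector with -1 for unannotated segments."""
        return np.array(
            [-1 if s.label is None else s.label for s in self.segments], dtype=int
        )

    @property
    def segment_ids(self) -> list[str]:
        return [s.segment_id for s in self.segments]

    def set_label(self, index: int, label: int) -> None:
        if not (0 <= label < self.n_classes):
            raise ValueError(
                f"label {label} outside vocabulary [0, {self.n_classes}); "
                f"classes: {self.class_names}"
            )
        self.segments[index].label = label

    def without_labels(self) -> "SegmentDataset":
        """Copy with all labels removed (starting point for annotation)."""
        segs = [replace(s, label=None) for s in self.segments]
        return SegmentDataset(
            segs, list(self.class_names), self.split, self.preprocessed,
            list(self.feature_names) if self.feature_names else None,
        )

    def padded_arrays(self, max_length: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stack segments into (N, T_max, F) + validity mask (N, T_max)."""
        if not self.segments:
            raise ValueError("empty dataset")
        T = max(s.n_frames for s in self.segments)
        if max_length is not None:
            if max_length < T:
                raise ValueError(f"max_length {max_length} < longest segment {T}")
            T = max_length
        F = self.n_features
        X = np.zeros((len(self.segments), T, F))
        mask = np.zeros((len(self.segments), T))
        for i, s in enumerate(self.segments):
            X[i, : s.n_frames] = s.frames
            mask[i, : s.n_frames] = 1.0
        return X, mask


@dataclass
class PreprocessStats:
    """Per-feature normalization statistics computed on the train split."""

    mean: np.ndarray
    std: np.ndarray
    max_length: int
    mode: str = "zscore"
    constant_features: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if np.any(self.std <= 0):
            raise ValueError("std entries must be > 0 (constant features get std 1)")


# ---------------------------------------------------------------------------
# CSV readers

@dataclass
class FrameTable:
    """Per-video table of frame-wise features.

    For the DeepLabCut dialect, columns come in (x, y, likelihood) triplets
    per bodypart and ``keypoint_names`` is set; ``coord_values`` /
    ``likelihood_values`` give the keypoint-major coordinate block and the
    per-keypoint likelihoods.  For plain CSV all columns are features.
    """

    values: np.ndarray  # R x n_columns, file order
    column_names: list[str]
    keypoint_names: list[str] | None = None
    has_likelihood: bool = False

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def coord_values(self) -> np.ndarray:
        """Coordinate columns only (likelihoods dropped), keypoint-major."""
        if not self.has_likelihood:
            return self.values
        idx = [i for i, c in enumerate(self.column_names) if not c.endswith("likelihood")]
        return self.values[:, idx]

    @property
    def coord_names(self) -> list[str]:
        if not self.has_likelihood:
            return list(self.column_names)
        return [c for c in self.column_names if not c.endswith("likelihood")]

    @property
    def likelihood_values(self) -> np.ndarray:
        if not self.has_likelihood:
            raise ValueError("table has no likelihood columns")
        idx = [i for i, c in enumerate(self.column_names) if c.endswith("likelihood")]
        return self.values[:, idx]


def read_keypoint_csv(path: str | Path, dialect: str = "deeplabcut") -> FrameTable:
    """Read a per-video keypoint CSV.

    ``dialect='deeplabcut'`` expects the three-row header
    (scorer / bodyparts / coords) with x, y, likelihood per bodypart;
    ``dialect='plain'`` expects a single header row of feature names.
    Row index = 0-based frame number, in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "deeplabcut":
        return _read_dlc(path)
    if dialect == "plain":
        return _read_plain(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'deeplabcut' or 'plain'")


def _read_dlc(path: Path) -> FrameTable:
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except pd.errors.ParserError as e:
        raise FormatError(f"{path}: ragged or malformed rows: {e}") from e
    except ValueError as e:
        raise FormatError(f"{path}: malformed DeepLabCut header: {e}") from e
    if df.columns.nlevels != 3:
        raise FormatError(
            f"{path}: expected 3 header rows (scorer/bodyparts/coords), "
            f"got {df.columns.nlevels}"
        )
    bodyparts: list[str] = []
    for bp in (c[1] for c in df.columns):
        if bp not in bodyparts:
            bodyparts.append(bp)
    cols: list[str] = []
    order: list[tuple] = []
    for bp in bodyparts:
        coords = [c[2] for c in df.columns if c[1] == bp]
        if sorted(coords) != ["likelihood", "x", "y"]:
            raise FormatError(
                f"{path}: header row 3 for bodypart {bp!r} must contain "
                f"x, y, likelihood; found {coords}"
            )
        for coord in ("x", "y", "likelihood"):
            col = next(c for c in df.columns if c[1] == bp and c[2] == coord)
            order.append(col)
            cols.append(f"{bp}_{coord}")
    values = df[order].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values).all(axis=1))[0, 0])
        raise FormatError(f"{path}: non-numeric or missing value at data row {bad}")
    return FrameTable(values, cols, keypoint_names=bodyparts, has_likelihood=True)


def _read_plain(path: Path) -> FrameTable:
    try:
        df = pd.read_csv(path, header=0)
    except pd.errors.ParserError as e:
        raise FormatError(f"{path}: ragged or malformed rows: {e}") from e
    values = df.to_numpy(dtype=np.float64)
    if values.ndim != 2 or values.shape[1] < 1:
        raise FormatError(f"{path}: no feature columns found")
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values).all(axis=1))[0, 0])
        raise FormatError(f"{path}: non-numeric or missing value at data row {bad}")
    return FrameTable(values, [str(c) for c in df.columns])


def filter_by_confidence(
    table: FrameTable, threshold: float
) -> tuple[FrameTable, np.ndarray]:
    """Flag frames whose pose-estimation confidence is too low.

    A frame passes iff every keypoint's likelihood is >= ``threshold``.
    Returns a coordinates-only table plus the per-frame boolean pass mask;
    the mask feeds :func:`fixed_window_segment`, which marks a segment
    ``confidence_ok`` only when enough of its frames pass.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"confidence threshold must be in [0, 1], got {threshold}")
    if not table.has_likelihood:
        raise ValueError("frame table has no likelihood columns to filter on")
    passed = np.all(table.likelihood_values >= threshold, axis=1)
    coords = FrameTable(
        table.coord_values, table.coord_names, table.keypoint_names, False
    )
    return coords, passed


def fixed_window_segment(
    table: FrameTable,
    window: int,
    stride: int,
    pass_mask: np.ndarray | None = None,
    min_pass_fraction: float = 0.9,
    source_video: str | None = None,
) -> list[KeypointSegment]:
    """Cut a continuous recording into fixed-duration clips.

    Windows start at 0, stride, 2*stride, ...; each holds exactly ``window``
    frames and a trailing remainder shorter than the window is dropped, so
    R frames yield floor((R - window) / stride) + 1 segments.  If a
    per-frame confidence mask is given, a segment is ``confidence_ok`` iff
    the fraction of passing frames is >= ``min_pass_fraction``.
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be positive")
    R = table.n_frames
    if window > R:
        warnings.warn(
            f"window {window} exceeds recording length {R}; no segments produced"
        )
        return []
    values = table.coord_values if table.has_likelihood else table.values
    prefix = source_video or "video"
    out = []
    for j, start in enumerate(range(0, R - window + 1, stride)):
        end = start + window - 1
        ok = True
        if pass_mask is not None:
            frac = float(np.mean(pass_mask[start : end + 1]))
            ok = frac >= min_pass_fraction
        out.append(
            KeypointSegment(
                frames=values[start : end + 1],
                segment_id=f"{prefix}_{start:06d}",
                source_video=source_video,
                start_frame=start,
                end_frame=end,
                confidence_ok=ok,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Preprocessing

def preprocess(
    dataset: SegmentDataset, mode: str = "zscore"
) -> tuple[SegmentDataset, PreprocessStats]:
    """Normalize a train split and return the statistics for reuse on test.

    ``zscore`` subtracts the per-feature mean and divides by the population
    std over all frames of all segments; ``center`` subtracts the mean only;
    ``none`` is the identity.  Constant features get std 1 and are flagged.
    Re-preprocessing an already-preprocessed dataset is rejected.
    """
    if mode not in ("zscore", "center", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    if dataset.preprocessed:
        raise ValueError("dataset is already preprocessed; refusing to apply twice")
    if dataset.split != "train":
        raise ValueError(
            "statistics must be computed on the train split; use "
            "apply_preprocess(dataset, stats) for test data"
        )
    if not dataset.segments:
        raise ValueError("empty dataset")
    allf = np.concatenate([s.frames for s in dataset.segments], axis=0)
    mean = allf.mean(axis=0)
    std = allf.std(axis=0)  # population std
    constant = np.flatnonzero(std == 0.0)
    std = np.where(std == 0.0, 1.0, std)
    if mode == "none":
        mean = np.zeros_like(mean)
        std = np.ones_like(std)
    elif mode == "center":
        std = np.ones_like(std)
    stats = PreprocessStats(
        mean=mean,
        std=std,
        max_length=max(s.n_frames for s in dataset.segments),
        mode=mode,
        constant_features=constant,
    )
    return apply_preprocess(dataset, stats), stats


def apply_preprocess(dataset: SegmentDataset, stats: PreprocessStats) -> SegmentDataset:
    """Apply train-split statistics to any split (e.g. test)."""
    if dataset.preprocessed:
        raise ValueError("dataset is already preprocessed; refusing to apply twice")
    segs = [
        replace(s, frames=(s.frames - stats.mean) / stats.std)
        for s in dataset.segments
    ]
    return SegmentDataset(
        segs, list(dataset.class_names), dataset.split, True,
        list(dataset.feature_names) if dataset.feature_names else None,
    )


def inverse_preprocess(dataset: SegmentDataset, stats: PreprocessStats) -> SegmentDataset:
    """Undo :func:`apply_preprocess` given the same statistics."""
    if not dataset.preprocessed:
        raise ValueError("dataset is not preprocessed")
    segs = [
        replace(s, frames=s.frames * stats.std + stats.mean)
        for s in dataset.segments
    ]
    return SegmentDataset(
        segs, list(dataset.class_names), dataset.split, False,
        list(dataset.feature_names) if dataset.feature_names else None,
    )


# ---------------------------------------------------------------------------
# Labels

def read_labels(path: str | Path, class_names: list[str]) -> dict[str, int]:
    """Read annotations from a CSV with columns segment_id, class_name."""
    path = Path(path)
    df = pd.read_csv(path, header=0, dtype=str)
    if df.empty and list(df.columns) == []:
        return {}
    if list(df.columns) != ["segment_id", "class_name"]:
        raise FormatError(
            f"{path}: expected columns [segment_id, class_name], got {list(df.columns)}"
        )
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        cname = row["class_name"]
        if cname not in class_names:
            raise FormatError(
                f"{path}: unknown class {cname!r}; vocabulary is {class_names}"
            )
        out[row["segment_id"]] = class_names.index(cname)
    return out


def write_labels(labels: dict[str, int], class_names: list[str], path: str | Path) -> None:
    rows = [
        {"segment_id": sid, "class_name": class_names[ci]}
        for sid, ci in labels.items()
    ]
    pd.DataFrame(rows, columns=["segment_id", "class_name"]).to_csv(path, index=False)


def apply_labels(dataset: SegmentDataset, labels: dict[str, int]) -> int:
    """Attach annotations to segments by id; returns number applied."""
    index = {sid: i for i, sid in enumerate(dataset.segment_ids)}
    n = 0
    for sid, ci in labels.items():
        if sid not in index:
            raise FormatError(f"unknown segment_id {sid!r}")
        dataset.set_label(index[sid], ci)
        n += 1
    return n


# ---------------------------------------------------------------------------
# Dataset directory layout

def save_dataset(dataset: SegmentDataset, directory: str | Path) -> None:
    """Write a dataset directory: manifest.csv + meta.json + segments.npz.

    Frames are stored per segment as float64 arrays keyed by segment_id, so
    the round-trip through :func:`load_dataset` is bit-exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset.segments:
        rows.append(
            {
                "segment_id": s.segment_id,
                "source_video": s.source_video if s.source_video is not None else "",
                "start_frame": "" if s.start_frame is None else s.start_frame,
                "end_frame": "" if s.end_frame is None else s.end_frame,
                "label": "" if s.label is None else dataset.class_names[s.label],
                "confidence_ok": int(s.confidence_ok),
            }
        )
    pd.DataFrame(
        rows,
        columns=["segment_id", "source_video", "start_frame", "end_frame", "label", "confidence_ok"],
    ).to_csv(directory / "manifest.csv", index=False)
    meta = {
        "format_version": 1,
        "class_names": dataset.class_names,
        "split": dataset.split,
        "preprocessed": dataset.preprocessed,
        "feature_names": dataset.feature_names,
        "feature_layout": "keypoint-major, coordinate-minor (x1,y1[,z1],x2,y2,...)",
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    np.savez(
        directory / "segments.npz",
        **{s.segment_id: s.frames for s in dataset.segments},
    )


def load_dataset(directory: str | Path) -> SegmentDataset:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    manifest = pd.read_csv(
        directory / "manifest.csv",
        dtype={"segment_id": str, "source_video": str, "label": str},
    )
    class_names = meta["class_names"]
    with np.load(directory / "segments.npz") as npz:
        segs = []
        for _, row in manifest.iterrows():
            label = row["label"]
            label_idx = (
                None
                if (pd.isna(label) or label == "")
                else class_names.index(label)
            )
            sv = row["source_video"]
            segs.append(
                KeypointSegment(
                    frames=npz[row["segment_id"]],
                    segment_id=row["segment_id"],
                    source_video=None if pd.isna(sv) or sv == "" else sv,
                    start_frame=None if pd.isna(row["start_frame"]) else int(row["start_frame"]),
                    end_frame=None if pd.isna(row["end_frame"]) else int(row["end_frame"]),
                    label=label_idx,
                    confidence_ok=bool(int(row["confidence_ok"])),
                )
            )
    return SegmentDataset(
        segs,
        class_names,
        meta["split"],
        meta["preprocessed"],
        meta.get("feature_names"),
    )
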