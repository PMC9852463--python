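"""Trial sequence data model, readers/writers and preprocessing.

A trial is the tool-motion trace of one execution of a bimanual surgical
task: per video frame, the bounding-box centroids of the two instruments
(grasper and scissors), i.e. a ``T x 4`` matrix of pixel coordinates.
Frames in which the upstream detector found no tool are *missing*; they are
imputed by temporal interpolation before modelling.  Preprocessing follows
the assessment pipeline: gap filling, downsampling to a low frame rate,
min-max normalization of coordinates and z-normalization of the continuous
performance score, with normalization statistics fit on training trials
only to avoid leakage into held-out folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_FEATURES = ("grasper_x", "grasper_y", "scissors_x", "scissors_y")


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class InputError(IOError):
    """Raised when an input file is missing or unreadable."""


@dataclass
class TrialSequence:
    """One trial's tool-coordinate matrix plus metadata.

    ``coords`` is ``T x D`` in pixel units (D = 4 for pattern-cutting-style
    data: grasper x/y then scissors x/y).  ``missing_mask[j]`` is True when
    frame ``j`` had no detection in the raw input; after :func:`fill_gaps`
    the coordinates at those frames are imputed but the mask is preserved.
    """

    trial_id: str
    subject_id: str
    fps: float
    coords: np.ndarray
    missing_mask: np.ndarray
    label: str | None = None
    score: float | None = None
    feature_names: tuple[str, ...] = DEFAULT_FEATURES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.coords.ndim != 2:
            raise ValidationError(f"coords must be 2-D, got shape {self.coords.shape}")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.missing_mask.shape != (self.coords.shape[0],):
            raise ValidationError("missing_mask length must equal number of frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_features(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class SequenceDataset:
    """Ordered collection of trials with the label vocabulary."""

    trials: list[TrialSequence]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate trial_id(s): {dupes}")
        for t in self.trials:
            if t.label is not None and self.class_names and t.label not in self.class_names:
                raise ValidationError(
                    f"trial {t.trial_id} label {t.label!r} not in class_names"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialSequence]:
        return iter(self.trials)

    def __getitem__(self, trial_id: str) -> TrialSequence:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    def subset(self, trial_ids: Sequence[str]) -> "SequenceDataset":
        wanted = set(trial_ids)
        return SequenceDataset(
            [t for t in self.trials if t.trial_id in wanted], list(self.class_names)
        )

    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject_id, None)
        return list(seen)

    def map(self, fn) -> "SequenceDataset":
        return SequenceDataset([fn(t) for t in self.trials], list(self.class_names))


@dataclass
class NormalizationStats:
    """Per-feature min/max for coordinates and mean/std for scores."""

    feature_min: np.ndarray
    feature_max: np.ndarray
    score_mean: float = 0.0
    score_std: float = 0.0

    def __post_init__(self) -> None:
        self.feature_min = np.asarray(self.feature_min, dtype=float)
        self.feature_max = np.asarray(self.feature_max, dtype=float)
        if np.any(self.feature_max < self.feature_min):
            raise ValidationError("feature_max must be >= feature_min")
        if self.score_std < 0:
            raise ValidationError("score_std must be >= 0")


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _frames_to_trial(
    frame_idx: np.ndarray,
    values: np.ndarray,
    *,
    trial_id: str,
    subject_id: str,
    fps: float,
    label: str | None,
    score: float | None,
    feature_names: tuple[str, ...],
) -> TrialSequence:
    """Assemble a trial from (possibly gappy) frame rows.

    Rows are sorted by frame index; absent frame indices between the first
    and last observed frame become missing frames with NaN coordinates.
    """
    order = np.argsort(frame_idx, kind="stable")
    frame_idx = frame_idx[order]
    values = values[order]
    if len(np.unique(frame_idx)) != len(frame_idx):
        raise ValidationError(f"trial {trial_id}: duplicate frame indices")
    lo, hi = int(frame_idx[0]), int(frame_idx[-1])
    n = hi - lo + 1
    coords = np.full((n, values.shape[1]), np.nan)
    coords[frame_idx - lo] = values
    missing = np.any(np.isnan(coords), axis=1)
    return TrialSequence(
        trial_id=trial_id,
        subject_id=subject_id,
        fps=fps,
        coords=coords,
        missing_mask=missing,
        label=label,
        score=score,
        feature_names=feature_names,
    )


def read_trials(
    manifest_path: str | Path,
    format: str = "csv",
    column_map: Mapping[str, object] | None = None,
    fps: float = 30.0,
    class_names: Sequence[str] | None = None,
) -> SequenceDataset:
    """Read a trial manifest and its per-trial files into a dataset.

    The manifest is a CSV with columns ``trial_id,subject_id,file,label,score``
    (``label``/``score`` may be empty); ``file`` is resolved relative to the
    manifest.  ``format`` selects the per-trial file layout:

    ``csv``
        header ``frame,<feature columns>``; absent frame rows (or NaN cells)
        become missing frames.
    ``json``
        object of equal-length lists, ``{"frame": [...], "grasper_x": [...]}``.
    ``jigsaws_txt``
        whitespace-delimited numeric text, one row per sample at ``fps``;
        ``column_map`` maps feature names to 0-based column indices.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InputError(f"manifest not found: {manifest_path}")
    if format not in ("csv", "json", "jigsaws_txt"):
        raise ValidationError(f"unknown format {format!r}")
    manifest = pd.read_csv(manifest_path, dtype={"trial_id": str, "subject_id": str})
    required = {"trial_id", "subject_id", "file"}
    if not required.issubset(manifest.columns):
        raise ValidationError(f"manifest must have columns {sorted(required)}")

    if format == "jigsaws_txt":
        if not column_map:
            raise ValidationError("jigsaws_txt requires a column_map of feature->column index")
        feature_names = tuple(column_map)
    else:
        feature_names = tuple(column_map) if column_map else DEFAULT_FEATURES

    trials: list[TrialSequence] = []
    for row in manifest.itertuples(index=False):
        path = manifest_path.parent / str(row.file)
        if not path.exists():
            raise InputError(f"trial file not found: {path}")
        label = getattr(row, "label", None)
        if label is not None and (pd.isna(label) or label == ""):
            label = None
        score = getattr(row, "score", None)
        if score is not None:
            score = None if pd.isna(score) else float(score)

        if format == "jigsaws_txt":
            data = np.loadtxt(path, ndmin=2)
            cols = [int(column_map[name]) for name in feature_names]
            if max(cols) >= data.shape[1]:
                raise ValidationError(
                    f"{path}: column_map selects column {max(cols)} "
                    f"but file has {data.shape[1]} columns"
                )
            values = data[:, cols]
            frame_idx = np.arange(values.shape[0])
        else:
            if format == "csv":
                # round_trip parser: written floats must read back bit-identical
                table = pd.read_csv(path, float_precision="round_trip")
            else:
                with open(path) as fh:
                    table = pd.DataFrame(json.load(fh))
            if "frame" not in table.columns:
                raise ValidationError(f"{path}: no 'frame' column")
            source_cols = (
                [str(column_map[name]) for name in feature_names]
                if column_map
                else list(feature_names)
            )
            missing_cols = [c for c in source_cols if c not in table.columns]
            if missing_cols:
                raise ValidationError(f"{path}: missing columns {missing_cols}")
            frame_idx = table["frame"].to_numpy(dtype=int)
            values = table[source_cols].to_numpy(dtype=float)

        trials.append(
            _frames_to_trial(
                frame_idx,
                values,
                trial_id=str(row.trial_id),
                subject_id=str(row.subject_id),
                fps=fps,
                label=None if label is None else str(label),
                score=score,
                feature_names=feature_names,
            )
        )

    if class_names is None:
        class_names = sorted({t.label for t in trials if t.label is not None})
    return SequenceDataset(trials, list(class_names))


def write_trials(ds: SequenceDataset, out_dir: str | Path) -> Path:
    """Write a dataset as per-trial CSV files plus a manifest CSV.

    Every frame row is written, including imputed ones; frames that are
    still NaN round-trip as missing frames.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in ds:
        fname = f"{t.trial_id}.csv"
        table = pd.DataFrame(t.coords, columns=list(t.feature_names))
        table.insert(0, "frame", np.arange(t.n_frames))
        table.to_csv(out_dir / fname, index=False)
        rows.append(
            {
                "trial_id": t.trial_id,
                "subject_id": t.subject_id,
                "file": fname,
                "label": t.label if t.label is not None else "",
                "score": t.score if t.score is not None else "",
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def fill_gaps(seq: TrialSequence) -> TrialSequence:
    """Impute missing frames by temporal interpolation.

    An isolated missing frame becomes the mean of its two neighbours; a run
    of consecutive missing frames is filled by linear interpolation between
    the flanking observed frames (the two-point mean is its special case);
    missing frames before the first / after the last observation copy the
    nearest observed frame.  Observed coordinates are never altered and the
    missing mask is preserved, so the operation is idempotent.
    """
    missing = seq.missing_mask | np.any(np.isnan(seq.coords), axis=1)
    if missing.all():
        raise ValidationError(f"trial {seq.trial_id}: all frames missing")
    if not missing.any():
        return replace(seq, coords=seq.coords.copy(), missing_mask=seq.missing_mask.copy())
    idx = np.arange(seq.n_frames)
    obs = ~missing
    coords = seq.coords.copy()
    for d in range(seq.n_features):
        coords[missing, d] = np.interp(idx[missing], idx[obs], seq.coords[obs, d])
    return replace(seq, coords=coords, missing_mask=seq.missing_mask.copy())


def downsample(seq: TrialSequence, target_fps: float) -> TrialSequence:
    """Keep every (fps/target_fps)-th frame, starting at frame 0.

    Stride sampling (not block averaging) preserves the raw detections.
    Non-integer ratios fall back to nearest-index sampling.
    """
    if target_fps <= 0:
        raise ValidationError("target_fps must be positive")
    if target_fps > seq.fps:
        raise ValidationError("target_fps must not exceed the sequence fps")
    factor = seq.fps / target_fps
    positions = np.arange(0, seq.n_frames, factor)
    indices = np.unique(np.round(positions).astype(int))
    indices = indices[indices < seq.n_frames]
    return replace(
        seq,
        fps=float(target_fps),
        coords=seq.coords[indices].copy(),
        missing_mask=seq.missing_mask[indices].copy(),
    )


def fit_normalization(train: SequenceDataset) -> NormalizationStats:
    """Fit min-max coordinate stats and score mean/std on training trials only.

    Fitting on the training split of each cross-validation fold keeps
    held-out extrema from leaking into the transform.
    """
    if train.n_trials == 0:
        raise ValidationError("cannot fit normalization on an empty dataset")
    stacked = np.vstack([t.coords for t in train])
    if np.any(np.isnan(stacked)):
        raise ValidationError("fill gaps before fitting normalization")
    scores = np.array([t.score for t in train if t.score is not None], dtype=float)
    return NormalizationStats(
        feature_min=np.nanmin(stacked, axis=0),
        feature_max=np.nanmax(stacked, axis=0),
        score_mean=float(scores.mean()) if scores.size else 0.0,
        score_std=float(scores.std()) if scores.size else 0.0,
    )


def _normalize_coords(coords: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    span = stats.feature_max - stats.feature_min
    out = np.zeros_like(coords)
    ok = span > 0
    out[:, ok] = (coords[:, ok] - stats.feature_min[ok]) / span[ok]
    return out


def apply_normalization(ds: SequenceDataset, stats: NormalizationStats) -> SequenceDataset:
    """Map coordinates to [0, 1] (training extrema) and z-normalize scores.

    Constant features map to 0; a zero score spread maps scores to 0.
    """
    def tx(t: TrialSequence) -> TrialSequence:
        score = t.score
        if score is not None:
            score = (score - stats.score_mean) / stats.score_std if stats.score_std > 0 else 0.0
        return replace(t, coords=_normalize_coords(t.coords, stats), score=score)

    return ds.map(tx)


def invert_normalization(ds: SequenceDataset, stats: NormalizationStats) -> SequenceDataset:
    """Inverse of :func:`apply_normalization` where the span is non-zero."""
    span = stats.feature_max - stats.feature_min

    def tx(t: TrialSequence) -> TrialSequence:
        score = t.score
        if score is not None:
            score = denormalize_score(score, stats)
        return replace(t, coords=t.coords * span + stats.feature_min, score=score)

    return ds.map(tx)


def denormalize_score(value: float, stats: NormalizationStats) -> float:
    """Map a z-normalized score back to the original score scale."""
    return value * stats.score_std + stats.score_mean if stats.score_std > 0 else stats.score_mean


def encode_targets(ds: SequenceDataset) -> tuple[np.ndarray, np.ndarray]:
    """One-hot label matrix and balanced inverse-frequency class weights.

    weight(c) = N / (n_classes * N_c), so rare classes get proportionally
    larger gradient contributions during training.
    """
    if len(ds.class_names) < 2:
        raise ValidationError("need at least two classes to encode targets")
    labels = []
    for t in ds:
        if t.label is None:
            raise ValidationError(f"trial {t.trial_id} is unlabelled")
        labels.append(t.label)
    index = {c: i for i, c in enumerate(ds.class_names)}
    counts = np.zeros(len(ds.class_names))
    onehot = np.zeros((ds.n_trials, len(ds.class_names)))
    for row, lab in enumerate(labels):
        onehot[row, index[lab]] = 1.0
        counts[index[lab]] += 1
    if np.any(counts == 0):
        empty = [c for c, n in zip(ds.class_names, counts) if n == 0]
        raise ValidationError(f"class(es) with no trials: {empty}")
    weights = ds.n_trials / (len(ds.class_names) * counts)
    return onehot, weights
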