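"""Preprocessing: gap filling, downsampling, normalization, target encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from skillseq.sequences import (
    SequenceDataset,
    ValidationError,
    apply_normalization,
    downsample,
    encode_targets,
    fill_gaps,
    fit_normalization,
    invert_normalization,
    read_trials,
    write_trials,
)
from conftest import make_trial


class TestFillGaps:
    def test_isolated_gap_is_neighbour_mean(self):
        coords = np.array([[10, 20, 30, 40],
                           [np.nan] * 4,
                           [14, 24, 34, 44]], dtype=float)
        filled = fill_gaps(make_trial(coords))
        assert np.allclose(filled.coords[1], [12, 22, 32, 42])

    def test_run_of_gaps_linear_interpolation(self):
        coords = np.full((4, 4), np.nan)
        coords[0] = 10.0
        coords[3] = 40.0
        filled = fill_gaps(make_trial(coords))
        assert np.allclose(filled.coords[1], 20.0)
        assert np.allclose(filled.coords[2], 30.0)

    def test_boundary_gap_copies_nearest_observed(self):
        coords = np.array([[np.nan] * 4, [5.0] * 4, [7.0] * 4])
        filled = fill_gaps(make_trial(coords))
        assert np.allclose(filled.coords[0], 5.0)
        trailing = np.array([[5.0] * 4, [7.0] * 4, [np.nan] * 4])
        assert np.allclose(fill_gaps(make_trial(trailing)).coords[2], 7.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            fill_gaps(make_trial(np.full((3, 4), np.nan)))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent_and_preserves_observed(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(20, 4)) * 100
        missing = rng.random(20) < 0.3
        missing[rng.integers(20)] = False  # keep one observation
        coords[missing] = np.nan
        trial = make_trial(coords, missing=missing)
        once = fill_gaps(trial)
        twice = fill_gaps(once)
        assert np.array_equal(once.coords, twice.coords)
        assert np.array_equal(once.coords[~missing], coords[~missing])
        assert np.array_equal(once.missing_mask, missing)


class TestDownsample:
    def test_stride_indices(self):
        coords = np.arange(300 * 4, dtype=float).reshape(300, 4)
        out = downsample(make_trial(coords), 1.0)
        assert out.n_frames == 10
        assert np.array_equal(out.coords, coords[np.arange(0, 300, 30)])
        assert out.fps == 1.0

    def test_identity_when_target_equals_fps(self):
        coords = np.random.default_rng(0).normal(size=(17, 4))
        out = downsample(make_trial(coords), 30.0)
        assert np.array_equal(out.coords, coords)

    def test_partial_last_stride_kept(self):
        coords = np.zeros((305, 4))
        assert downsample(make_trial(coords), 1.0).n_frames == 11

    def test_mask_subsampled_identically(self):
        missing = np.zeros(90, bool)
        missing[30] = True
        out = downsample(make_trial(np.zeros((90, 4)), missing=missing), 1.0)
        assert out.missing_mask.tolist() == [False, True, False]

    def test_invalid_targets_rejected(self):
        trial = make_trial(np.zeros((10, 4)))
        with pytest.raises(ValidationError):
            downsample(trial, 0.0)
        with pytest.raises(ValidationError):
            downsample(trial, 60.0)

    def test_composition_equals_single_downsample(self):
        coords = np.random.default_rng(3).normal(size=(200, 4))
        trial = make_trial(coords, fps=30.0)
        via_3 = downsample(downsample(trial, 3.0), 1.0)
        direct = downsample(trial, 1.0)
        assert np.array_equal(via_3.coords, direct.coords)


class TestNormalization:
    def test_minmax_maps_extrema(self):
        t = make_trial(np.array([[0.0, 0, 0, 0], [5, 5, 5, 5], [10, 10, 10, 10]]))
        ds = SequenceDataset([t])
        out = apply_normalization(ds, fit_normalization(ds))
        assert np.allclose(out.trials[0].coords[:, 0], [0, 0.5, 1])

    def test_constant_feature_maps_to_zero(self):
        t = make_trial(np.full((2, 4), 7.0))
        ds = SequenceDataset([t])
        out = apply_normalization(ds, fit_normalization(ds))
        assert np.allclose(out.trials[0].coords, 0.0)

    def test_scores_z_normalized(self):
        trials = [make_trial(np.zeros((2, 4)) + i, trial_id=f"t{i}", score=s)
                  for i, s in enumerate([1.0, 2.0, 3.0])]
        ds = SequenceDataset(trials)
        out = apply_normalization(ds, fit_normalization(ds))
        z = np.array([t.score for t in out])
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            fit_normalization(SequenceDataset([]))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip_inverse(self, seed):
        rng = np.random.default_rng(seed)
        trials = [make_trial(rng.uniform(0, 640, size=(10, 4)), trial_id=f"t{i}",
                             score=float(rng.normal(100, 20)))
                  for i in range(3)]
        ds = SequenceDataset(trials)
        stats = fit_normalization(ds)
        back = invert_normalization(apply_normalization(ds, stats), stats)
        for orig, rec in zip(ds, back):
            assert np.allclose(rec.coords, orig.coords, rtol=1e-9, atol=1e-9)
            assert abs(rec.score - orig.score) < 1e-9


class TestEncodeTargets:
    def test_one_hot_rows(self):
        trials = [make_trial(np.zeros((2, 4)), trial_id="a", label="pass"),
                  make_trial(np.zeros((2, 4)), trial_id="b", label="fail")]
        onehot, _ = encode_targets(SequenceDataset(trials, ["pass", "fail"]))
        assert onehot.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_balanced_inverse_frequency_weights(self):
        trials = [make_trial(np.zeros((2, 4)), trial_id=f"p{i}", label="pass")
                  for i in range(90)]
        trials += [make_trial(np.zeros((2, 4)), trial_id=f"f{i}", label="fail")
                   for i in range(10)]
        _, weights = encode_targets(SequenceDataset(trials, ["pass", "fail"]))
        assert np.allclose(weights, [100 / 180, 5.0])

    def test_single_class_rejected(self):
        trials = [make_trial(np.zeros((2, 4)), trial_id="a", label="pass")]
        with pytest.raises(ValidationError):
            encode_targets(SequenceDataset(trials, ["pass", "fail"]))
        with pytest.raises(ValidationError):
            encode_targets(SequenceDataset(trials, ["pass"]))

    def test_unlabelled_trial_rejected(self):
        trials = [make_trial(np.zeros((2, 4)), trial_id="a", label="pass"),
                  make_trial(np.zeros((2, 4)), trial_id="b")]
        with pytest.raises(ValidationError):
            encode_targets(SequenceDataset(trials, ["pass", "fail"]))


class TestReadWrite:
    def _write_manifest(self, tmp_path, rows):
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
        return tmp_path / "manifest.csv"

    def test_complete_csv_round(self, tmp_path):
        for tid in ("a", "b"):
            pd.DataFrame({
                "frame": range(5),
                "grasper_x": np.arange(5.0), "grasper_y": np.arange(5.0),
                "scissors_x": np.arange(5.0), "scissors_y": np.arange(5.0),
            }).to_csv(tmp_path / f"{tid}.csv", index=False)
        manifest = self._write_manifest(tmp_path, [
            {"trial_id": "a", "subject_id": "s1", "file": "a.csv", "label": "pass", "score": 100.0},
            {"trial_id": "b", "subject_id": "s1", "file": "b.csv", "label": "fail", "score": 40.0},
        ])
        ds = read_trials(manifest, format="csv")
        assert ds.n_trials == 2
        assert not any(t.missing_mask.any() for t in ds)
        assert ds["a"].label == "pass" and ds["b"].score == 40.0

    def test_absent_frame_marks_missing(self, tmp_path):
        frames = [0, 1, 2, 3, 4, 6]
        pd.DataFrame({
            "frame": frames,
            "grasper_x": np.ones(6), "grasper_y": np.ones(6),
            "scissors_x": np.ones(6), "scissors_y": np.ones(6),
        }).to_csv(tmp_path / "a.csv", index=False)
        manifest = self._write_manifest(
            tmp_path, [{"trial_id": "A", "subject_id": "s", "file": "a.csv"}])
        trial = read_trials(manifest)["A"]
        assert trial.n_frames == 7
        assert trial.missing_mask.tolist() == [False] * 5 + [True, False]
        assert np.isnan(trial.coords[5]).all()

    def test_jigsaws_column_selection(self, tmp_path):
        data = np.arange(10 * 76, dtype=float).reshape(10, 76)
        np.savetxt(tmp_path / "k.txt", data)
        manifest = self._write_manifest(
            tmp_path, [{"trial_id": "j", "subject_id": "s", "file": "k.txt"}])
        ds = read_trials(manifest, format="jigsaws_txt",
                         column_map={"left_x": 0, "left_y": 1, "right_x": 38, "right_y": 39})
        trial = ds["j"]
        assert trial.coords.shape == (10, 4)
        assert np.array_equal(trial.coords[:, 2], data[:, 38])

    def test_duplicate_trial_id_rejected(self, tmp_path):
        pd.DataFrame({"frame": [0, 1], "grasper_x": [1.0, 2], "grasper_y": [1.0, 2],
                      "scissors_x": [1.0, 2], "scissors_y": [1.0, 2]}
                     ).to_csv(tmp_path / "a.csv", index=False)
        manifest = self._write_manifest(tmp_path, [
            {"trial_id": "a", "subject_id": "s", "file": "a.csv"},
            {"trial_id": "a", "subject_id": "s", "file": "a.csv"},
        ])
        with pytest.raises(ValidationError):
            read_trials(manifest)

    def test_missing_file_is_input_error(self, tmp_path):
        manifest = self._write_manifest(
            tmp_path, [{"trial_id": "a", "subject_id": "s", "file": "absent.csv"}])
        with pytest.raises(IOError, match="absent.csv"):
            read_trials(manifest)

    def test_write_read_round_trip_bit_identical(self, tmp_path, rng):
        coords = rng.uniform(0, 640, size=(12, 4))
        coords[3] = np.nan
        trials = [make_trial(coords, trial_id="x", label="pass", score=123.456)]
        ds = SequenceDataset(trials, ["pass", "fail"])
        manifest = write_trials(ds, tmp_path / "out")
        back = read_trials(manifest, class_names=["pass", "fail"])
        assert np.array_equal(back["x"].coords, coords, equal_nan=True)
        assert back["x"].missing_mask.tolist() == trials[0].missing_mask.tolist()
        assert back["x"].score == 123.456
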