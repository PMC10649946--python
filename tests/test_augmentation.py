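import numpy as np
import pytest

import mhdecg as m
from mhdecg.augmentation import (build_augmented_dataset,
                                 build_distortion_track, normalize_recording)
from mhdecg.mhd_extraction import TemplateDatabase
from mhdecg.signal_io import ValidationError, VcgRecording


@pytest.fixture
def template(template_db):
    return template_db[0]


class TestDistortionTrack:
    def test_no_peaks_gives_zero_track(self, template):
        track = build_distortion_track(template, np.array([], dtype=int),
                                       5000, 500.0)
        assert track.shape == (5000, 3)
        assert np.all(track == 0)

    def test_single_beat_placement(self, template):
        track = build_distortion_track(template, np.array([500]), 2000, 500.0)
        np.testing.assert_array_equal(track[438:688], template.window)
        assert np.all(track[:438] == 0) and np.all(track[688:] == 0)

    def test_beats_one_second_apart_do_not_overlap(self, template):
        track = build_distortion_track(template, np.array([500, 1000]),
                                       2000, 500.0)
        np.testing.assert_array_equal(track[438:688], template.window)
        np.testing.assert_array_equal(track[938:1188], template.window)

    def test_overlapping_windows_are_added(self, template):
        # 0.2 s apart: windows collide, overlap-add sums them
        track = build_distortion_track(template, np.array([500, 600]),
                                       2000, 500.0)
        expected = np.zeros_like(track)
        expected[438:688] += template.window
        expected[538:788] += template.window
        np.testing.assert_allclose(track, expected)

    def test_truncate_mode_cuts_at_rr_midpoint(self, template):
        track = build_distortion_track(template, np.array([500, 600]),
                                       2000, 500.0, overlap_mode="truncate")
        mid = 550  # windows are clipped at the RR midpoint on both sides
        np.testing.assert_array_equal(track[438:mid],
                                      template.window[:mid - 438])
        np.testing.assert_array_equal(track[mid:600],
                                      template.window[mid - 538:600 - 538])

    def test_edge_windows_clipped(self, template):
        track = build_distortion_track(template, np.array([10]), 1000, 500.0)
        np.testing.assert_array_equal(track[:198], template.window[52:])

    def test_fs_mismatch_rejected(self, template):
        with pytest.raises(ValidationError):
            build_distortion_track(template, np.array([10]), 1000, 257.0)


class TestAugmentRecording:
    def test_scale_zero_is_identity(self, clean_vcg, template):
        out = m.augment_recording(clean_vcg, template, scale=0.0)
        np.testing.assert_array_equal(out.signal, clean_vcg.signal)

    def test_difference_equals_scaled_track(self, clean_vcg, template):
        out = m.augment_recording(clean_vcg, template, scale=0.7)
        track = build_distortion_track(template, clean_vcg.r_peaks,
                                       clean_vcg.n_samples, clean_vcg.fs)
        np.testing.assert_allclose(out.signal - clean_vcg.signal, 0.7 * track)
        np.testing.assert_array_equal(out.r_peaks, clean_vcg.r_peaks)
        assert out.provenance == "augmented"


class TestAugmentedDataset:
    def make_recs(self, n, seed=0):
        return [m.synth_clean_ecg(m.BeatModel(seed=seed + i), duration=8.0,
                                  leads=3, subject_id=f"r{i}")
                for i in range(n)]

    def test_headline_count_identity(self, template_db):
        """75 recordings + 2 distinct templates each from a 150-template
        database = 225 recordings."""
        recs = self.make_recs(5)
        # 150-template database from tiling the fixture set
        db = TemplateDatabase(templates=(template_db.templates * 3)[:150])
        # count identity scales: (1 + per_rec) * n
        ds = m.build_augmented_dataset(recs, db, templates_per_recording=2,
                                       seed=0)
        assert len(ds) == 3 * len(recs)
        assert len(ds.originals) == len(recs)
        assert len(ds.augmented) == 2 * len(recs)

    def test_distinct_templates_without_replacement(self, template_db):
        recs = self.make_recs(3)
        db = TemplateDatabase(templates=template_db.templates[:6])
        ds = m.build_augmented_dataset(recs, db, templates_per_recording=2,
                                       seed=1)
        used = [v["template_index"] for v in ds.manifest["assignments"].values()]
        assert len(used) == 6 and len(set(used)) == 6

    def test_same_seed_same_manifest(self, template_db):
        recs = self.make_recs(3)
        a = m.build_augmented_dataset(recs, template_db, seed=7).manifest
        b = m.build_augmented_dataset(recs, template_db, seed=7).manifest
        assert a == b

    def test_annotations_preserved_and_recoverable(self, template_db):
        recs = self.make_recs(2)
        ds = m.build_augmented_dataset(recs, template_db, scale=0.5, seed=3)
        for orig, aug in zip(ds.originals, ds.augmented[::2]):
            np.testing.assert_array_equal(orig.r_peaks, aug.r_peaks)
            tmpl_idx = ds.manifest["assignments"][aug.subject_id]["template_index"]
            track = build_distortion_track(template_db[tmpl_idx], orig.r_peaks,
                                           orig.n_samples, orig.fs)
            np.testing.assert_allclose((aug.signal - orig.signal) / 0.5,
                                       track, atol=1e-12)

    def test_small_database_falls_back_with_replacement(self, template_db):
        recs = self.make_recs(4)
        db = TemplateDatabase(templates=template_db.templates[:3])
        ds = m.build_augmented_dataset(recs, db, templates_per_recording=2,
                                       seed=2)
        assert len(ds) == 12  # still completes, with replacement

    def test_normalization_bounds_carrier(self, clean_vcg):
        out = normalize_recording(clean_vcg)
        assert np.max(np.abs(out.signal)) == pytest.approx(1.0)

    def test_all_zero_carrier_rejected(self):
        rec = VcgRecording(signal=np.zeros((100, 3)), fs=500.0)
        with pytest.raises(ValidationError):
            normalize_recording(rec)
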