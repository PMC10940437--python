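"""Image pipeline: correction, splitting, registration, segmentation, ROI mapping."""

import numpy as np
import pytest

from stretchca import (CorrectionFrames, FrameStack, LabelMap, PhaseSchedule,
                       SceneSpec, SegmentationParams, SimilarityTransform,
                       Phenotype, correct_stack, estimate_phase_transform,
                       extract_traces, map_rois, register_drift, render_scene,
                       segment_cells, split_phases)
from stretchca.errors import (CorrectionError, RegistrationError,
                              TransformEstimationError)
from stretchca.synth import NoiseModel, vignette_profile


def _stack(frames, rate=10.0, t0=0.0, schedule=None):
    frames = np.asarray(frames)
    t = t0 + np.arange(len(frames)) / rate
    sch = schedule or PhaseSchedule(frame_rate=rate)
    return FrameStack(frames, t, np.clip(sch.phase_of(t), 0, None), 1.0 / rate)


class TestCorrectStack:
    def test_frame_equal_to_dark_becomes_zero(self):
        dark = np.full((8, 8), 100.0)
        stack = _stack(np.full((3, 8, 8), 100.0))
        out = correct_stack(stack, CorrectionFrames(dark, dark + 50.0))
        assert np.all(out.frames == 0.0)

    def test_vignetted_flat_is_fully_removed_from_uniform_frame(self):
        vign = vignette_profile((16, 16), 0.4)
        dark = np.full((16, 16), 10.0)
        frames = (200.0 * vign + 10.0)[None]
        out = correct_stack(_stack(frames), CorrectionFrames(dark, 1000.0 * vign + 10.0))
        assert np.ptp(out.frames[0]) < 1e-9
        assert out.frames[0].mean() == pytest.approx(200.0 * vign.mean())

    def test_correction_reduces_background_variation_on_synthetic_scene(self):
        spec = SceneSpec(n_cells=3, field_size=(128, 128), seed=13,
                         schedule=PhaseSchedule(frame_rate=1.0))
        b = render_scene(spec)
        stack = _stack(b.frames[:60], rate=1.0, schedule=spec.schedule)
        out = correct_stack(stack, CorrectionFrames(b.dark, b.flat))
        bg = b.label_map == 0
        # temporal mean suppresses shot noise, leaving the fixed-pattern
        # vignette; compare spatial CV of the dark-subtracted background
        pre = stack.frames.mean(axis=0)[bg] - b.dark[bg]
        post = out.frames.mean(axis=0)[bg]
        assert post.std() / post.mean() < pre.std() / pre.mean()

    def test_shape_mismatch_rejected(self):
        stack = _stack(np.zeros((2, 8, 8)))
        with pytest.raises(ValueError, match="shape"):
            correct_stack(stack, CorrectionFrames(np.zeros((4, 4)), np.ones((4, 4))))

    def test_nonpositive_flat_rejected(self):
        stack = _stack(np.zeros((2, 8, 8)))
        flat = np.ones((8, 8))
        flat[0, 0] = 0.0
        with pytest.raises(CorrectionError):
            correct_stack(stack, CorrectionFrames(np.zeros((8, 8)), flat))


class TestSplitPhases:
    def test_group_sizes_for_default_protocol(self):
        sch = PhaseSchedule()  # four 60-s phases at 10 fps
        stack = _stack(np.zeros((2400, 4, 4)), rate=10.0, schedule=sch)
        groups = split_phases(stack, sch)
        assert [len(groups[g]) for g in ("pre", "stretch", "release")] == [1200, 600, 600]

    def test_boundary_frame_goes_to_later_phase(self):
        sch = PhaseSchedule()
        stack = _stack(np.zeros((2400, 4, 4)), rate=10.0, schedule=sch)
        groups = split_phases(stack, sch)
        assert groups["stretch"].times[0] == pytest.approx(120.0)
        assert groups["pre"].times[-1] == pytest.approx(119.9)

    def test_zero_length_phase_yields_empty_group(self):
        sch = PhaseSchedule(starts=(0, 60, 120, 120), ends=(60, 120, 120, 180))
        stack = _stack(np.zeros((1800, 4, 4)), rate=10.0, schedule=sch)
        groups = split_phases(stack, sch)
        assert len(groups["stretch"]) == 0
        assert len(groups["pre"]) == 1200 and len(groups["release"]) == 600

    def test_schedule_longer_than_stack_rejected(self):
        sch = PhaseSchedule()
        stack = _stack(np.zeros((100, 4, 4)), rate=10.0, schedule=sch)
        with pytest.raises(ValueError, match="schedule"):
            split_phases(stack, sch)


class TestRegisterDrift:
    @staticmethod
    def _textured(shape=(64, 64), seed=0):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter
        return gaussian_filter(rng.uniform(0, 100, shape), 3.0)

    def test_aligned_stack_gives_identity_transforms(self):
        img = self._textured()
        stack = _stack(np.stack([img] * 4), rate=1.0)
        _, tfs = register_drift(stack)
        for tf in tfs:
            assert np.all(np.abs(tf.translation) < 0.1)

    def test_injected_translation_is_recovered(self):
        from scipy.ndimage import shift as ndshift
        img = self._textured()
        shifted = ndshift(img, (3.0, -3.0), order=1, mode="nearest")
        stack = _stack(np.stack([img, img, shifted]), rate=1.0)
        reg, tfs = register_drift(stack)
        assert np.allclose(tfs[2].translation, (-3.0, 3.0), atol=0.5)
        assert np.corrcoef(reg.frames[2].ravel(), img.ravel())[0, 1] > 0.98

    def test_featureless_frame_raises_named_error(self):
        img = self._textured()
        stack = _stack(np.stack([img, np.zeros_like(img)]), rate=1.0)
        with pytest.raises(RegistrationError, match="frame 1"):
            register_drift(stack)

    def test_pure_noise_frames_fail_registration(self):
        rng = np.random.default_rng(1)
        stack = _stack(rng.uniform(0, 100, (3, 64, 64)), rate=1.0)
        with pytest.raises(RegistrationError):
            register_drift(stack)


class TestSegmentCells:
    def test_blank_stack_has_zero_labels(self):
        stack = _stack(np.zeros((5, 32, 32)), rate=1.0)
        with pytest.warns(UserWarning):
            lm = segment_cells(stack)
        assert lm.ids.size == 0

    def test_two_touching_cells_with_distinct_maxima_split(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = (200.0 * np.exp(-((yy - 32) ** 2 + (xx - 22) ** 2) / (2 * 36.0))
               + 160.0 * np.exp(-((yy - 32) ** 2 + (xx - 42) ** 2) / (2 * 36.0)))
        stack = _stack(img[None], rate=1.0)
        lm = segment_cells(stack, SegmentationParams(min_distance=7, min_area=10))
        assert lm.ids.size == 2

    def test_synthetic_scene_recall_and_label_connectivity(self):
        spec = SceneSpec(n_cells=12, field_size=(256, 256), seed=17,
                         schedule=PhaseSchedule(frame_rate=1.0))
        b = render_scene(spec)
        sel = b.phase_tags == 2
        stack = _stack(b.frames[sel], rate=1.0, t0=120.0, schedule=spec.schedule)
        lm = segment_cells(stack)
        matched = 0
        for tid in np.unique(b.label_map)[1:]:
            tmask = b.label_map == tid
            best = 0.0
            for cid in np.unique(lm.labels[tmask]):
                if cid == 0:
                    continue
                cmask = lm.labels == cid
                best = max(best, (tmask & cmask).sum() / (tmask | cmask).sum())
            matched += best >= 0.5
        assert matched >= 11

    def test_permutation_of_frame_order_does_not_change_labels(self):
        spec = SceneSpec(n_cells=5, field_size=(128, 128), seed=23,
                         schedule=PhaseSchedule(frame_rate=1.0))
        b = render_scene(spec)
        sel = np.where(b.phase_tags == 2)[0]
        frames = b.frames[sel]
        lm1 = segment_cells(_stack(frames, rate=1.0))
        rng = np.random.default_rng(0)
        lm2 = segment_cells(_stack(frames[rng.permutation(len(frames))], rate=1.0))
        assert np.array_equal(lm1.labels, lm2.labels)


class TestPhaseTransform:
    @staticmethod
    def _cells_image(shape=(160, 160), seed=2):
        rng = np.random.default_rng(seed)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        img = np.full(shape, 20.0)
        for _ in range(8):
            y, x = rng.uniform(40, shape[0] - 40, 2)
            img += 200.0 * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * 16.0))
        return img

    def test_identity_for_equal_images(self):
        img = self._cells_image()
        tf = estimate_phase_transform(img, img)
        assert tf.scale == pytest.approx(1.0, abs=0.01)
        assert np.all(np.abs(tf.translation) < 0.5)

    def test_recovers_isotropic_scale(self):
        from stretchca.imaging import _warp_scale
        img = self._cells_image()
        center = (np.asarray(img.shape, float) - 1) / 2
        target = _warp_scale(img, 1.15, center)
        tf = estimate_phase_transform(img, target)
        assert tf.scale == pytest.approx(1.15, abs=0.01)

    def test_recovers_pure_translation(self):
        from scipy.ndimage import shift as ndshift
        img = self._cells_image()
        target = ndshift(img, (5.0, 0.0), order=1, mode="nearest")
        tf = estimate_phase_transform(img, target)
        assert tf.scale == pytest.approx(1.0, abs=0.01)
        assert tf.translation[0] == pytest.approx(5.0, abs=0.5)
        assert tf.translation[1] == pytest.approx(0.0, abs=0.5)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(TransformEstimationError):
            estimate_phase_transform(np.ones((32, 32)), np.ones((32, 32)))


def _disc_labels(shape=(120, 120), center=(60, 60), radius=20):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    lab = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2).astype(np.int32)
    return LabelMap(lab, coordinate_frame="stretch")


class TestMapRois:
    def test_identity_transform_preserves_map(self):
        lm = _disc_labels()
        tf = SimilarityTransform(scale=1.0, center=(59.5, 59.5))
        mapped, dropped = map_rois(lm, tf)
        assert dropped == []
        assert np.array_equal(mapped.labels, lm.labels)

    def test_down_scaling_shrinks_area_quadratically(self):
        lm = _disc_labels()
        tf = SimilarityTransform(scale=1 / 1.15, center=(59.5, 59.5))
        mapped, _ = map_rois(lm, tf)
        ratio = mapped.labels.sum() / lm.labels.sum()
        assert ratio == pytest.approx(1 / 1.3225, rel=0.03)

    def test_label_translated_outside_field_is_dropped(self):
        lm = _disc_labels(center=(20, 20), radius=10)
        tf = SimilarityTransform(scale=1.0, translation=(-200.0, 0.0))
        mapped, dropped = map_rois(lm, tf)
        assert dropped == [1]
        assert mapped.labels.max() == 0

    def test_round_trip_recovers_labelled_pixels(self):
        lm = _disc_labels()
        for scale in (0.85, 1.0, 1.2):
            tf = SimilarityTransform(scale=scale, translation=(2.0, -3.0),
                                     center=(59.5, 59.5))
            there, _ = map_rois(lm, tf)
            back, _ = map_rois(there, tf.inverse())
            overlap = ((back.labels == 1) & (lm.labels == 1)).sum()
            assert overlap / (lm.labels == 1).sum() >= 0.98


class TestExtractTraces:
    def test_uniform_cell_yields_constant_trace(self):
        sch = PhaseSchedule(starts=(0, 1, 2, 3), ends=(1, 2, 3, 4), frame_rate=2.0)
        frames = np.full((8, 20, 20), 10.0)
        frames[:, 5:10, 5:10] = 100.0
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:10, 5:10] = 1
        stack = _stack(frames, rate=2.0, schedule=sch)
        groups = split_phases(stack, sch)
        lms = {g: LabelMap(lab, g) for g in groups}
        traces, incomplete = extract_traces(groups, lms, sch)
        assert incomplete == set()
        assert len(traces) == 1
        assert np.allclose(traces[0].values, 100.0)
        assert len(traces[0]) == 8

    def test_cell_missing_from_one_group_is_incomplete(self):
        sch = PhaseSchedule(starts=(0, 1, 2, 3), ends=(1, 2, 3, 4), frame_rate=2.0)
        frames = np.full((8, 20, 20), 50.0)
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:10, 5:10] = 1
        stack = _stack(frames, rate=2.0, schedule=sch)
        groups = split_phases(stack, sch)
        lms = {g: LabelMap(lab, g) for g in groups}
        lms["release"] = LabelMap(np.zeros((20, 20), dtype=np.int32), "release")
        traces, incomplete = extract_traces(groups, lms, sch)
        assert incomplete == {1}
        assert traces[0].time_s.max() < 3.0  # no release samples

    def test_no_cells_no_error(self):
        sch = PhaseSchedule(starts=(0, 1, 2, 3), ends=(1, 2, 3, 4), frame_rate=2.0)
        stack = _stack(np.zeros((8, 10, 10)), rate=2.0, schedule=sch)
        groups = split_phases(stack, sch)
        lms = {g: LabelMap(np.zeros((10, 10), dtype=np.int32), g) for g in groups}
        traces, incomplete = extract_traces(groups, lms, sch)
        assert traces == [] and incomplete == set()
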