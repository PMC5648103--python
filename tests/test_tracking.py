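import numpy as np
import pytest

from ethotrack.core import FrameSequence, TrackPoint
from ethotrack.registration import register_arena
from ethotrack.synth import BehaviorProgram, generate_arena_frames, render_frame
from ethotrack.tracking import (
    Blob,
    NoAnimalFoundError,
    TrackerParams,
    extract_track_point,
    init_background,
    segment_foreground,
    track_roi,
    update_background,
)


@pytest.fixture(scope="module")
def registered(tube_video, tube_template):
    seq, gt = tube_video
    _, rois = register_arena(seq.frames[0], tube_template)
    return seq, gt, rois[0]


def test_background_init_is_pixelwise_median(tube_template):
    """With the fly at one spot in fewer than half the init frames, the
    median excludes it (per-pixel median oracle)."""
    frames = [render_frame(tube_template, [(0, 5.0 + 4 * i, 0.0, 0.0)], noise_sd=0.0) for i in range(5)]
    seq = FrameSequence(np.stack(frames), np.arange(5.0))
    _, rois = register_arena(frames[0], tube_template)
    roi = rois[0]
    model = init_background(seq, roi, n_init=5)
    oracle = np.median(np.stack([roi.crop(f) for f in frames]).astype(float), axis=0)
    np.testing.assert_array_equal(model.image, oracle)
    empty = roi.crop(render_frame(tube_template, [], noise_sd=0.0)).astype(float)
    assert np.abs(model.image - empty).max() < 1  # no fly ghost survives


def test_background_init_requires_frames(registered):
    seq, _, roi = registered
    with pytest.raises(ValueError):
        init_background(seq, roi, n_init=0)


def test_update_alpha_extremes():
    model = init_like = None
    base = np.full((10, 10), 100.0)
    from ethotrack.tracking import BackgroundModel

    m0 = BackgroundModel(image=base.copy(), alpha=0.0)
    m1 = BackgroundModel(image=base.copy(), alpha=1.0)
    frame = np.full((10, 10), 130.0)
    np.testing.assert_array_equal(update_background(m0, frame).image, base)
    np.testing.assert_array_equal(update_background(m1, frame).image, frame)


def test_selective_update_preserves_parked_fly(tube_template):
    """A fly parked for >> 1/alpha frames stays segmentable under the
    selective update, while a naive full-frame update absorbs it."""
    from ethotrack.tracking import BackgroundModel
    from scipy import ndimage as ndi

    empty = render_frame(tube_template, [], noise_sd=0.0)
    parked = render_frame(tube_template, [(0, 12.0, 0.0, 0.0)], noise_sd=0.0)
    _, rois = register_arena(empty, tube_template)
    roi = rois[0]
    crop_empty = roi.crop(empty).astype(float)
    crop_parked = roi.crop(parked).astype(float)
    alpha = 0.05
    selective = BackgroundModel(image=crop_empty.copy(), alpha=alpha)
    naive = BackgroundModel(image=crop_empty.copy(), alpha=alpha)
    min_area = TrackerParams().min_area_px(roi.mm_per_px)
    for _ in range(int(10 / alpha)):
        blobs = segment_foreground(selective, crop_parked, 60.0, min_area)
        exclude = None
        if blobs:
            m = np.zeros_like(crop_empty, dtype=bool)
            for b in blobs:
                m[b.mask_indices] = True
            exclude = ndi.binary_dilation(m, iterations=3)
        selective = update_background(selective, crop_parked, exclude)
        naive = update_background(naive, crop_parked, None)
    assert len(segment_foreground(selective, crop_parked, 60.0, min_area)) == 1
    assert len(segment_foreground(naive, crop_parked, 60.0, min_area)) == 0


def test_segment_empty_when_frame_equals_model(registered):
    seq, _, roi = registered
    model = init_background(seq, roi, n_init=5)
    assert segment_foreground(model, model.image, 30.0, 10.0) == []


def test_segment_single_fly_centroid(tube_template):
    """One rendered ellipse on a converged background: exactly one blob with
    centroid within 0.5 px of the truth (image-moment oracle)."""
    from ethotrack.synth import fly_px_position
    from ethotrack.tracking import BackgroundModel

    empty = render_frame(tube_template, [], noise_sd=0.0)
    frame = render_frame(tube_template, [(0, 9.0, 0.2, 30.0)], noise_sd=0.0)
    _, rois = register_arena(empty, tube_template)
    roi = rois[0]
    model = BackgroundModel(image=roi.crop(empty).astype(float), alpha=0.05)
    blobs = segment_foreground(model, roi.crop(frame).astype(float), 60.0, 20.0)
    assert len(blobs) == 1
    x0, y0, _, _ = roi.bbox
    expect = fly_px_position(tube_template, 0, 9.0, 0.2) - [max(x0, 0), max(y0, 0)]
    assert np.hypot(blobs[0].centroid[0] - expect[0], blobs[0].centroid[1] - expect[1]) < 0.5


def test_segment_reports_two_blobs(tube_template):
    from ethotrack.tracking import BackgroundModel

    empty = render_frame(tube_template, [], noise_sd=0.0)
    # two well-separated ellipses in the same tube (constructed fixture)
    frame = render_frame(tube_template, [(0, 5.0, 0.0, 0.0)], noise_sd=0.0)
    frame2 = render_frame(tube_template, [(0, 20.0, 0.0, 0.0)], noise_sd=0.0)
    both = np.minimum(frame, frame2)
    _, rois = register_arena(empty, tube_template)
    roi = rois[0]
    model = BackgroundModel(image=roi.crop(empty).astype(float), alpha=0.05)
    blobs = segment_foreground(model, roi.crop(both).astype(float), 60.0, 20.0)
    assert len(blobs) == 2


def test_moment_ellipse_axes_and_angle(tube_template):
    """A 2.5 x 1 mm ellipse at 0.1 mm/px is 25 x 10 px; moments must recover
    axes within 10% and the angle within 3 degrees."""
    from ethotrack.tracking import BackgroundModel

    empty = render_frame(tube_template, [], noise_sd=0.0)
    frame = render_frame(tube_template, [(0, 12.0, 0.0, 30.0)], noise_sd=0.0)
    _, rois = register_arena(empty, tube_template)
    roi = rois[0]
    model = BackgroundModel(image=roi.crop(empty).astype(float), alpha=0.05)
    (blob,) = segment_foreground(model, roi.crop(frame).astype(float), 60.0, 20.0)
    assert blob.w == pytest.approx(25.0, rel=0.10)
    assert blob.h == pytest.approx(10.0, rel=0.10)
    assert blob.phi == pytest.approx(30.0, abs=3.0)


def test_carry_forward_when_no_blob(registered):
    _, _, roi = registered
    prev = TrackPoint(t=1.0, x=50.0, y=20.0, x_mm=2.0, w=25.0, h=10.0, phi=0.0)
    pt = extract_track_point([], prev, 2.0, roi, (0.0, 0.0))
    assert pt.is_inferred and pt.x == 50.0 and pt.y == 20.0


def test_no_blob_and_no_history_is_an_error(registered):
    _, _, roi = registered
    with pytest.raises(NoAnimalFoundError):
        extract_track_point([], None, 1.0, roi, (0.0, 0.0))


def test_nearest_blob_selected(registered):
    _, _, roi = registered
    a = Blob(area=100, centroid=(10.0, 10.0), w=20, h=8, phi=0.0)
    b = Blob(area=200, centroid=(60.0, 10.0), w=20, h=8, phi=0.0)
    prev = TrackPoint(t=1.0, x=12.0, y=9.0, x_mm=1.0, w=20, h=8, phi=0.0)
    pt = extract_track_point([a, b], prev, 2.0, roi, (0.0, 0.0))
    assert pt.x == a.centroid[0]  # nearest, despite b being larger
    pt0 = extract_track_point([a, b], None, 1.0, roi, (0.0, 0.0))
    assert pt0.x == b.centroid[0]  # largest when no history


def test_track_roi_accuracy_and_timestamps(registered):
    seq, gt, roi = registered
    traj = track_roi(seq, roi)
    assert len(traj) == len(seq)
    np.testing.assert_array_equal(traj.t, seq.timestamps)  # dropped-frame clock preserved
    g = gt.for_roi(0)
    xy = traj.xy_global_px
    err_px = np.hypot(xy[:, 0] - g["x_px"], xy[:, 1] - g["y_px"])
    assert np.median(err_px) < 1.0


def test_immobile_fly_positional_noise_floor(tube_template):
    prog = BehaviorProgram(segments=[(60.0, "immobile")])
    seq, _ = generate_arena_frames(tube_template, {0: prog}, 60.0, fps_model=(4.0, 0.0), seed=21, noise_sd=3.0)
    _, rois = register_arena(seq.frames[0], tube_template)
    traj = track_roi(seq, rois[0])
    from ethotrack.behavior import compute_velocity

    v = compute_velocity(traj, dt_nominal=0.25)["v_corr"]
    assert (v < 1.0).all()


def test_empty_roi_raises_no_animal(tube_template):
    frames = [render_frame(tube_template, [], noise_sd=2.0, seed=i) for i in range(12)]
    seq = FrameSequence(np.stack(frames), np.arange(12.0))
    _, rois = register_arena(seq.frames[0], tube_template)
    with pytest.raises(NoAnimalFoundError):
        track_roi(seq, rois[0], TrackerParams(n_grace=10))
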