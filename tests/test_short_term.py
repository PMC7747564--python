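"""Clip geometry, SDR, preprocessing, schedule and the tiny backbone."""

import numpy as np
import pytest

from phaseflow.ontology import AnnotationTrack
from phaseflow.short_term import (
    BackboneSpec,
    ClipSpec,
    FrameCase,
    PreprocessConfig,
    ProbabilitySequence,
    ShortTermTrainConfig,
    clip_frame_indices,
    compute_sdr,
    detect_out_of_body,
    lr_at,
    predict_probability_sequence,
    preprocess_clip,
    resized_dims,
    train_short_term,
    training_samples_seen,
    trim_bounds,
)
from phaseflow.synthetic import (
    PHASE_COLORS,
    SimulationConfig,
    generate_truth_track,
    render_phase_frames,
)

TINY_PREP = PreprocessConfig(resize_short_side=24, crop=16)


def test_clip_spec_frame_count_consistency():
    assert ClipSpec().n_frames == 64  # 2.56 s at 25 FPS
    with pytest.raises(ValueError):
        ClipSpec(n_frames=60)


def test_clip_indices_are_centered_on_anchor():
    spec = ClipSpec()
    a = 40 * 25 + 12
    idx = clip_frame_indices(40, 12, 100, spec)
    assert idx.tolist() == list(range(a - 32, a + 32))


def test_clip_indices_clamp_at_video_start():
    idx = clip_frame_indices(0, 0, 100)
    assert len(idx) == 64
    assert idx[0] == 0 and (idx[:33] == 0).sum() == 33  # edge frame repeated
    assert (np.diff(idx) >= 0).all()


def test_clip_indices_always_64_and_in_range():
    spec = ClipSpec()
    for second, frame, length in [(0, 24, 1), (99, 24, 100), (50, 0, 51)]:
        idx = clip_frame_indices(second, frame, length, spec)
        assert len(idx) == spec.n_frames
        assert idx.min() >= 0 and idx.max() < length * spec.fps
        assert (np.diff(idx) >= 0).all()
    with pytest.raises(ValueError):
        clip_frame_indices(100, 0, 100)


@pytest.mark.parametrize(
    "second, length, expected",
    [(0, 1800, 0.0), (900, 1800, 0.5), (1799, 1800, 1799 / 1800)],
)
def test_sdr_is_the_progress_quotient(second, length, expected):
    assert compute_sdr(second, length) == pytest.approx(expected)


def test_sdr_is_strictly_increasing_and_bounded():
    vals = [compute_sdr(s, 50) for s in range(50)]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert vals[0] >= 0 and vals[-1] < 1
    with pytest.raises(ValueError):
        compute_sdr(0, 0)


def test_resize_preserves_aspect_ratio():
    assert resized_dims(360, 480, 256) == (256, 341)
    assert resized_dims(480, 360, 256) == (341, 256)


def test_preprocess_shapes_and_standardization():
    cfg = PreprocessConfig(resize_short_side=32, crop=24)
    frames = np.full((3, 36, 48, 3), 128, dtype=np.uint8)
    out = preprocess_clip(frames, train_mode=False, config=cfg)
    assert out.shape == (3, 24, 24, 3)
    # a constant frame equal to the channel mean standardizes to zero
    gray = (np.array(cfg.channel_mean) * 255).astype(np.uint8)
    frames = np.broadcast_to(gray, (2, 32, 32, 3)).astype(np.uint8)
    out = preprocess_clip(frames, train_mode=False, config=cfg)
    assert np.abs(out).max() < 0.02  # uint8 quantization only


def test_eval_preprocessing_is_deterministic(rng):
    cfg = PreprocessConfig(resize_short_side=32, crop=24)
    frames = rng.integers(0, 255, size=(2, 40, 50, 3)).astype(np.uint8)
    a = preprocess_clip(frames, train_mode=False, config=cfg)
    b = preprocess_clip(frames, train_mode=False, config=cfg)
    np.testing.assert_array_equal(a, b)


def test_crop_cannot_exceed_resized_short_side():
    with pytest.raises(ValueError, match="crop"):
        PreprocessConfig(resize_short_side=8, crop=16)


@pytest.mark.parametrize(
    "validation_iter, expected",
    [(0, 0.01), (9, 0.01), (10, 0.001), (19, 0.001), (20, 1e-4), (25, 1e-5), (26, 1e-5)],
)
def test_lr_schedule(validation_iter, expected):
    assert lr_at(validation_iter) == pytest.approx(expected)


def test_lr_is_non_increasing_with_three_drops():
    vals = [lr_at(v) for v in range(31)]
    assert all(b <= a for a, b in zip(vals, vals[1:]))
    assert len(set(vals)) == 4  # initial value plus exactly three drops


@pytest.mark.parametrize(
    "iters, per, expected",
    [(10, 250_000, 2_500_000), (20, 250_000, 5_000_000),
     (25, 250_000, 6_250_000), (30, 250_000, 7_500_000), (0, 250_000, 0)],
)
def test_training_sample_schedule(iters, per, expected):
    assert training_samples_seen(iters, per) == expected


def test_unordered_lr_drops_are_rejected():
    with pytest.raises(ValueError):
        ShortTermTrainConfig(lr_drop_after_validations=(20, 10, 25))


def test_probability_sequence_validates_rows(rng):
    with pytest.raises(ValueError, match="sum to 1"):
        ProbabilitySequence("v", np.full((4, 7), 0.5))


# ---------------------------------------------------------------------------
# Training / inference on rendered synthetic frames
# ---------------------------------------------------------------------------


def _frame_cases(n, seed, scale=0.02):
    cfg = SimulationConfig(seed=seed).scaled(scale)
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        t = generate_truth_track(cfg, rng, video_id=f"v{i}")
        frames = render_phase_frames(t, fps=25, size=(24, 24), rng=rng)
        cases.append(FrameCase(video_id=t.video_id, frames=frames, labels=t.labels))
    return cases


@pytest.fixture(scope="module")
def trained_tiny_model():
    cases = _frame_cases(5, seed=0)
    config = ShortTermTrainConfig(
        stop_after_validations=3, lr_drop_after_validations=(1, 2), seed=0,
        sdr_enabled=True,
    )
    model = train_short_term(
        cases[:4], cases[4:], BackboneSpec(sdr_concat_at_head=True), config,
        preprocess=TINY_PREP,
    )
    return model, cases


def test_training_loss_decreases(trained_tiny_model):
    model, _ = trained_tiny_model
    losses = [h["train_loss"] for h in model.history]
    assert len(losses) == 3
    assert losses[-1] < losses[0]


def test_checkpoints_saved_per_validation(trained_tiny_model):
    model, _ = trained_tiny_model
    assert all("checkpoint" in h and h["samples_seen"] > 0 for h in model.history)


def test_trained_model_overfits_training_video(trained_tiny_model):
    """Near-separable color-coded frames are classified above 90%."""
    model, cases = trained_tiny_model
    probs = predict_probability_sequence(model, cases[0])
    acc = np.mean(probs.argmax_track().labels == cases[0].labels)
    assert acc > 0.9


def test_predicted_sequence_shape_and_determinism(trained_tiny_model):
    model, cases = trained_tiny_model
    a = predict_probability_sequence(model, cases[4])
    b = predict_probability_sequence(model, cases[4])
    assert a.rows.shape == (cases[4].length_s, 7)
    np.testing.assert_allclose(a.rows.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(a.rows, b.rows)


def test_identical_seeds_give_identical_training(trained_tiny_model):
    _, cases = trained_tiny_model
    config = ShortTermTrainConfig(
        stop_after_validations=1, lr_drop_after_validations=(), seed=7
    )
    m1 = train_short_term(cases[:2], [], BackboneSpec(), config, preprocess=TINY_PREP)
    m2 = train_short_term(cases[:2], [], BackboneSpec(), config, preprocess=TINY_PREP)
    for k in m1.net.params:
        np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])


def test_empty_training_set_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        train_short_term([], [], BackboneSpec(), ShortTermTrainConfig())


# ---------------------------------------------------------------------------
# Out-of-body trimming
# ---------------------------------------------------------------------------


def test_trim_bounds_all_in_body():
    assert trim_bounds(np.ones(10, dtype=bool)) == (0, 10)


def test_trim_bounds_longest_run():
    mask = np.array([False, False, True, True, True, False])
    assert trim_bounds(mask) == (2, 5)


def test_trim_bounds_requires_in_body_frames():
    with pytest.raises(ValueError, match="no in-body"):
        trim_bounds(np.zeros(5, dtype=bool))


def test_out_of_body_heuristic_recovers_body_span(rng):
    """Dark gray leader + red-tinted body + gray trailer."""
    L = 30
    frames = np.zeros((L, 16, 16, 3), dtype=np.uint8)
    frames[:5] = 20  # dark out-of-body leader
    frames[5:25] = PHASE_COLORS[2]  # red-dominant in-body span
    frames[25:] = np.array([90, 90, 90], dtype=np.uint8)  # gray trailer
    frames = np.clip(
        frames.astype(int) + rng.normal(0, 5, frames.shape).astype(int), 0, 255
    ).astype(np.uint8)
    mask = detect_out_of_body(frames)
    start, end = trim_bounds(mask)
    assert abs(start - 5) <= 1 and abs(end - 25) <= 1
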