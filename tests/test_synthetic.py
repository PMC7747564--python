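"""Structure and statistics of the synthetic generator."""

import numpy as np
import pytest

from phaseflow.ontology import segments_from_track
from phaseflow.synthetic import (
    EmissionConfig,
    SimulationConfig,
    _assign_groups,
    emit_probability_sequence,
    generate_dataset,
    generate_truth_track,
    render_phase_frames,
)

SHORT = 0.05

NOISELESS = EmissionConfig(
    adjacent_confusion=0.0,
    distant_error_rate=0.0,
    boundary_jitter_sd_s=0.0,
    concentration=np.inf,
)


def _deterministic_config(**kw):
    base = dict(
        p_skip_phase0=0.0, p_skip_phase1=0.0, p_skip_phase5=0.0,
        p_alternate_23=0.0, p_reorder_56=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base).scaled(SHORT)


def test_track_is_nondecreasing_without_skips_or_reorders(rng):
    track = generate_truth_track(_deterministic_config(), rng)
    assert (np.diff(track.labels) >= 0).all()
    assert set(np.unique(track.labels)) == set(range(7))


def test_forced_skip_removes_phase(rng):
    cfg = _deterministic_config(p_skip_phase1=1.0)
    for _ in range(10):
        assert 1 not in generate_truth_track(cfg, rng).labels


def test_mandatory_phases_always_present(rng):
    cfg = SimulationConfig(
        p_skip_phase0=1.0, p_skip_phase1=1.0, p_skip_phase5=1.0,
        p_alternate_23=1.0, p_reorder_56=1.0,
    ).scaled(SHORT)
    track = generate_truth_track(cfg, rng)
    assert {2, 3, 4, 6}.issubset(set(np.unique(track.labels)))


def test_reorder_places_packaging_after_final_inspection(rng):
    cfg = _deterministic_config(p_reorder_56=1.0)
    seg = segments_from_track(generate_truth_track(cfg, rng))
    phases = [s.phase for s in seg.segments]
    assert phases.index(5) > phases.index(6)


def test_alternation_inserts_dissection_after_division(rng):
    cfg = _deterministic_config(p_alternate_23=1.0)
    seg = segments_from_track(generate_truth_track(cfg, rng))
    phases = [s.phase for s in seg.segments]
    i3 = phases.index(3)
    assert phases[i3 : i3 + 3] == [3, 2, 3]


def test_skip_frequency_matches_binomial_rate():
    """Phase-1 presence over 200 tracks stays in a 95% binomial band."""
    cfg = SimulationConfig(p_skip_phase1=0.4).scaled(SHORT)
    rng = np.random.default_rng(7)
    present = np.mean(
        [1 in generate_truth_track(cfg, rng).labels for _ in range(200)]
    )
    assert abs(present - 0.6) < 0.07


def test_noiseless_emission_recovers_truth(rng):
    track = generate_truth_track(_deterministic_config(), rng)
    probs = emit_probability_sequence(track, NOISELESS, rng)
    assert np.array_equal(probs.argmax_track().labels, track.labels)


def test_rows_are_distributions(rng):
    track = generate_truth_track(_deterministic_config(), rng)
    probs = emit_probability_sequence(track, EmissionConfig(), rng)
    assert probs.rows.min() >= 0 and probs.rows.max() <= 1
    np.testing.assert_allclose(probs.rows.sum(axis=1), 1.0, atol=1e-9)


def test_sdr_attenuation_suppresses_late_phase_errors_early():
    """With SDR attenuation, distant phase-6 errors in the first 10% of
    the video are rarer than without it (Monte Carlo over 100 tracks)."""
    cfg = _deterministic_config()
    counts = {}
    for attenuate in (True, False):
        ecfg = EmissionConfig(
            adjacent_confusion=0.0, distant_error_rate=0.3,
            boundary_jitter_sd_s=0.0, sdr_attenuation=attenuate,
        )
        rng = np.random.default_rng(42)
        n6 = 0
        for _ in range(100):
            track = generate_truth_track(cfg, rng)
            probs = emit_probability_sequence(track, ecfg, rng)
            head = slice(0, max(1, track.length_s // 10))
            pred = probs.argmax_track().labels[head]
            n6 += int(np.sum((pred == 6) & (track.labels[head] != 6)))
        counts[attenuate] = n6
    assert counts[True] < counts[False]


@pytest.mark.parametrize("knob", ["adjacent_confusion", "distant_error_rate"])
def test_emission_noise_is_monotone(knob):
    """Mean argmax accuracy over 50 tracks is non-increasing in each noise knob."""
    cfg = _deterministic_config()
    accs = []
    for level in (0.0, 0.2, 0.5):
        kw = dict(adjacent_confusion=0.0, distant_error_rate=0.0,
                  boundary_jitter_sd_s=0.0)
        kw[knob] = level
        ecfg = EmissionConfig(**kw)
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(50):
            t = generate_truth_track(cfg, rng)
            p = emit_probability_sequence(t, ecfg, rng)
            vals.append(np.mean(p.argmax_track().labels == t.labels))
        accs.append(np.mean(vals))
    assert accs[0] >= accs[1] >= accs[2]


def test_dataset_is_deterministic_under_seed():
    cfg = SimulationConfig(n_videos=4, seed=5).scaled(SHORT)
    a, b = generate_dataset(cfg), generate_dataset(cfg)
    for ca, cb in zip(a, b):
        assert ca.truth == cb.truth
        assert np.array_equal(ca.probs.rows, cb.probs.rows)
        assert ca.meta == cb.meta


def test_centers_come_from_configured_set():
    cases = generate_dataset(SimulationConfig(n_videos=10, n_centers=2, seed=0).scaled(SHORT))
    assert {c.meta.medical_center for c in cases} <= {"MC1", "MC2"}


def test_skewed_center_assignment_matches_multinomial():
    """1000 draws with skew weights land within 3 sd of expectation per center."""
    weights = (0.80, 0.07, 0.06, 0.04, 0.02, 0.01)
    labels = _assign_groups(1000, 6, weights, np.random.default_rng(0), "MC")
    for i, w in enumerate(weights):
        n = labels.count(f"MC{i + 1}")
        sd = np.sqrt(1000 * w * (1 - w))
        assert abs(n - 1000 * w) <= 3 * sd


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(p_skip_phase1=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_centers=0)
    with pytest.raises(ValueError):
        EmissionConfig(concentration=0.0)
    with pytest.raises(ValueError):
        generate_dataset(SimulationConfig(n_videos=0))


def test_rendered_frames_are_phase_separable(rng):
    track = generate_truth_track(_deterministic_config(), rng)
    frames = render_phase_frames(track, fps=5, size=(8, 8), rng=rng)
    assert frames.shape == (track.length_s * 5, 8, 8, 3)
    assert frames.dtype == np.uint8
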