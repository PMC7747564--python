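"""Accuracy metrics, confusion matrix, transition table, group breakdowns."""

import itertools

import numpy as np
import pytest

from phaseflow.ontology import AnnotationTrack, CaseMetadata, segments_from_track
from phaseflow.evaluation import (
    DEFAULT_TAUS,
    VideoScore,
    confusion_matrix,
    group_accuracy,
    mean_phase_accuracy,
    per_second_accuracy,
    percentile_filter,
    row_normalize,
    transition_accuracy,
    transition_offsets,
)


def _t(labels, vid="v"):
    return AnnotationTrack(vid, np.array(labels))


def test_per_second_accuracy_basic_cases():
    assert per_second_accuracy(_t([1, 2, 3]), _t([1, 2, 3])) == 1.0
    assert per_second_accuracy(_t([0, 0]), _t([1, 1])) == 0.0
    assert per_second_accuracy(_t([0, 2, 2, 2]), _t([0, 0, 2, 2])) == 0.75
    with pytest.raises(ValueError, match="length mismatch"):
        per_second_accuracy(_t([0]), _t([0, 0]))


def test_mean_phase_accuracy_averages_recalls():
    assert mean_phase_accuracy(_t([1, 2]), _t([1, 2])) == 1.0
    # truth has phases {0, 1}; recall(0)=1, recall(1)=0
    assert mean_phase_accuracy(_t([0, 0, 0, 0]), _t([0, 0, 0, 1])) == 0.5


def test_mean_phase_accuracy_excludes_absent_phases():
    """Matches a per-phase oracle over all 2-phase tracks of length <= 4."""
    for length in range(1, 5):
        for truth in itertools.product([2, 5], repeat=length):
            for pred in itertools.product([2, 5], repeat=length):
                t, p = np.array(truth), np.array(pred)
                expected = np.mean(
                    [np.mean(p[t == c] == c) for c in (2, 5) if (t == c).any()]
                )
                got = mean_phase_accuracy(_t(pred), _t(truth))
                assert got == pytest.approx(expected)


def test_confusion_matrix_tallies_and_normalizes():
    cm = confusion_matrix([(_t([2, 3]), _t([2, 2]))])
    assert cm.counts[2, 2] == 1 and cm.counts[2, 3] == 1
    assert cm.total == 2
    perfect = confusion_matrix([(_t([0, 1, 1]), _t([0, 1, 1]))])
    assert np.array_equal(np.diag(perfect.counts)[:2], [1, 2])
    norm = row_normalize(perfect)
    assert norm[0, 0] == 1.0 and norm[1, 1] == 1.0
    assert norm[6].sum() == 0.0  # empty truth row stays zero


def test_accuracy_equals_confusion_trace(rng):
    pairs = [
        (_t(rng.integers(0, 7, 40)), _t(rng.integers(0, 7, 40))) for _ in range(5)
    ]
    cm = confusion_matrix(pairs)
    pooled = np.trace(cm.counts) / cm.total
    direct = np.mean(
        np.concatenate([(p.labels == t.labels) for p, t in pairs])
    )
    assert pooled == pytest.approx(direct)


def test_accuracy_is_support_weighted_recall_mean(rng):
    pred, truth = _t(rng.integers(0, 7, 100)), _t(rng.integers(0, 7, 100))
    acc = per_second_accuracy(pred, truth)
    weighted = sum(
        np.mean(pred.labels[truth.labels == c] == c) * np.mean(truth.labels == c)
        for c in range(7)
        if (truth.labels == c).any()
    )
    assert acc == pytest.approx(weighted)


# ---------------------------------------------------------------------------
# Transition accuracy
# ---------------------------------------------------------------------------


def _seg(labels, vid="v"):
    return segments_from_track(_t(labels, vid))


def test_perfect_prediction_is_100_at_every_tau():
    truth = _seg([0] * 50 + [1] * 50 + [2] * 50)
    table = transition_accuracy((truth, truth))
    assert table.taus == DEFAULT_TAUS
    assert all(p == 100.0 for p in table.percent_within)
    # two-argument form is equivalent
    assert transition_accuracy(truth, truth).percent_within == table.percent_within


def test_uniform_20s_shift_splits_at_tau_30():
    """Every phase start late by 20 s: 0% within 15 s, 100% within >= 30 s."""
    truth = _t([1] * 100 + [2] * 100 + [3] * 100)
    # a leading phase absent from truth delays every truth phase by 20 s
    pred = _t([0] * 20 + [1] * 100 + [2] * 100 + [3] * 80)
    table = transition_accuracy((segments_from_track(pred), segments_from_track(truth)))
    by_tau = dict(zip(table.taus, table.percent_within))
    assert by_tau[15] == 0.0
    assert all(by_tau[t] == 100.0 for t in table.taus if t >= 30)


def test_phase_absent_from_prediction_is_a_miss():
    truth = _t([1] * 100 + [2] * 100)
    pred = _t([1] * 200)
    table = transition_accuracy(
        (segments_from_track(pred), segments_from_track(truth)),
        taus=list(DEFAULT_TAUS) + [10_000],
    )
    assert all(p < 100.0 for p in table.percent_within)
    # hand tally: phase 1 within every tau, phase 2 never -> 50% throughout
    assert set(table.percent_within) == {50.0}


def test_transition_accuracy_is_monotone_in_tau(rng):
    pairs = []
    for i in range(5):
        truth = _t(np.repeat(rng.permutation(7)[:4], rng.integers(20, 60, 4)), f"v{i}")
        pred = _t(rng.integers(0, 7, truth.length_s), f"v{i}")
        pairs.append((segments_from_track(pred), segments_from_track(truth)))
    table = transition_accuracy(pairs)
    pw = table.percent_within
    assert all(b >= a for a, b in zip(pw, pw[1:]))


def test_at_video_length_tau_equals_presence_fraction():
    truth = _t([0] * 60 + [3] * 60 + [5] * 60)
    pred = _t([0] * 120 + [5] * 60)  # phase 3 never predicted
    table = transition_accuracy(
        (segments_from_track(pred), segments_from_track(truth)), taus=[180]
    )
    assert table.percent_within[0] == pytest.approx(100 * 2 / 3)


def test_repeated_phase_uses_first_segment_start():
    truth = _t([5] * 10 + [6] * 10 + [5] * 10)  # Packaging recurs
    pred = _t([5] * 12 + [6] * 10 + [5] * 8)
    offsets = dict(transition_offsets(segments_from_track(pred), segments_from_track(truth)))
    assert offsets[5] == 0  # first-segment starts compared
    assert offsets[6] == 2


# ---------------------------------------------------------------------------
# Percentile subsets and group breakdowns
# ---------------------------------------------------------------------------


def _scores(accs, center="MC1"):
    return [
        VideoScore(f"v{i}", a, CaseMetadata(f"v{i}", medical_center=center, surgeon="s1"))
        for i, a in enumerate(accs)
    ]


def test_percentile_filter_is_strictly_above():
    kept = percentile_filter(_scores([0.8, 0.9, 1.0]), 50)
    assert [s.accuracy for s in kept] == [1.0]
    kept = percentile_filter(_scores([0.8, 0.9, 1.0]), 0)
    assert sorted(s.accuracy for s in kept) == [0.9, 1.0]
    assert percentile_filter(_scores([0.7, 0.7, 0.7]), 50) == []
    with pytest.raises(ValueError):
        percentile_filter([], 50)


def test_group_boxplot_statistics():
    stats = group_accuracy(_scores([0.6, 0.8, 1.0]), "medical_center", min_n=2)
    s = stats["MC1"]
    assert (s.median, s.q1, s.q3) == (0.8, pytest.approx(0.7), pytest.approx(0.9))
    assert s.n == 3 and s.outliers == ()


def test_small_groups_are_excluded():
    assert group_accuracy(_scores([0.6, 0.8, 1.0]), "medical_center", min_n=3) == {}
    with pytest.raises(ValueError, match="unknown group key"):
        group_accuracy(_scores([0.5]), "hospital")


def test_far_outlier_is_excluded_from_whisker():
    accs = [0.80, 0.81, 0.82, 0.83, 0.84, 0.85, 0.86, 0.87, 0.88, 0.89, 1.0]
    stats = group_accuracy(_scores(accs), "medical_center", min_n=10)["MC1"]
    q1, q3 = np.percentile(accs, [25, 75])
    assert 1.0 > q3 + 1.5 * (q3 - q1)  # construction: beyond the fence
    assert stats.outliers == (1.0,)
    assert stats.whisker_hi == 0.89


def test_metrics_are_permutation_invariant(rng):
    pairs = [
        (_t(rng.integers(0, 7, 30), f"v{i}"), _t(rng.integers(0, 7, 30), f"v{i}"))
        for i in range(6)
    ]
    cm1 = confusion_matrix(pairs)
    cm2 = confusion_matrix(list(reversed(pairs)))
    np.testing.assert_array_equal(cm1.counts, cm2.counts)
    seg_pairs = [(segments_from_track(p), segments_from_track(t)) for p, t in pairs]
    t1 = transition_accuracy(seg_pairs)
    t2 = transition_accuracy(list(reversed(seg_pairs)))
    assert t1.percent_within == t2.percent_within
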