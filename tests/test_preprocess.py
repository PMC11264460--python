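import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armgait.config import SynthConfig, TrimConfig
from armgait.preprocess import (TrimError, detect_walk_end, detect_walk_start,
                                median_filter3, preprocess_trace)
from armgait.synth_gait import simulate_trial

from conftest import make_trace, standing_pose


def brute_force_median3(x):
    x = np.asarray(x, float)
    if len(x) < 3:
        return x.copy()
    padded = np.concatenate(([x[0]], x, [x[-1]]))
    return np.array([sorted(padded[i:i + 3])[1] for i in range(len(x))])


def brute_force_end(lost):
    """Earliest start of a run of >2 consecutive lost frames, any landmark."""
    T, L = lost.shape
    best = T
    for j in range(L):
        for t in range(T - 2):
            if lost[t, j] and lost[t + 1, j] and lost[t + 2, j]:
                best = min(best, t)
                break
    return best


# -- median filter ---------------------------------------------------------

def test_spike_removed():
    assert np.array_equal(median_filter3([0, 0, 100, 0, 0]), [0, 0, 0, 0, 0])


def test_constant_series_unchanged():
    assert np.array_equal(median_filter3([7.0] * 10), [7.0] * 10)


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=80))
def test_median3_matches_brute_force(xs):
    assert np.allclose(median_filter3(xs), brute_force_median3(xs))


def test_median3_idempotent_on_monotone():
    x = np.linspace(0, 5, 51)
    once = median_filter3(x)
    assert np.allclose(once, x)
    assert np.allclose(median_filter3(once), once)


def test_random_series_length51_matches_oracle():
    x = np.random.default_rng(4).normal(size=51)
    assert np.allclose(median_filter3(x), brute_force_median3(x))


# -- walk end --------------------------------------------------------------

def _trace_with_lost(lost):
    T = lost.shape[0]
    xy = standing_pose(T=T)
    lik = np.where(lost, 0.1, 0.99)
    return make_trace(xy, lik)


def test_three_consecutive_lost_cuts_at_run_start():
    lost = np.zeros((200, 8), dtype=bool)
    lost[120:123, 5] = True
    assert detect_walk_end(_trace_with_lost(lost)) == 120


def test_two_consecutive_lost_is_kept():
    """Two is not 'more than two': the trace survives to its end."""
    lost = np.zeros((200, 8), dtype=bool)
    lost[120:122, 5] = True
    assert detect_walk_end(_trace_with_lost(lost)) == 200


def test_nonfinite_coordinates_count_as_lost():
    xy = standing_pose(T=50)
    xy[30:34, 2, 0] = np.nan
    assert detect_walk_end(make_trace(xy)) == 30


def test_walk_end_matches_exhaustive_scan_on_random_dropout():
    rng = np.random.default_rng(12)
    for _ in range(500):
        T = int(rng.integers(5, 60))
        lost = rng.random((T, 8)) < 0.08
        trace = _trace_with_lost(lost)
        assert detect_walk_end(trace) == brute_force_end(lost)


# -- walk start ------------------------------------------------------------

def _scale_schedule_trace(n_flat=50, growth=0.01, n_grow=60):
    """Constant-scale frames then multiplicative per-frame scale growth."""
    base = standing_pose(T=1)[0]
    center = base.mean(axis=0)
    T = n_flat + n_grow
    xy = np.empty((T, 8, 2))
    for t in range(T):
        s = (1 + growth) ** max(0, t - n_flat + 1)
        xy[t] = center + (base - center) * s
    return make_trace(xy)


def test_clean_growth_start_within_closed_form_window():
    """5%/frame threshold on 1%/frame growth: onset in [50, 50 + 5 + C]."""
    cfg = TrimConfig(rise_fraction=0.05, confirm_frames=3, baseline_window=10)
    start = detect_walk_start(_scale_schedule_trace(), cfg)
    assert 50 <= start <= 50 + 5 + cfg.confirm_frames


def test_growth_from_frame_zero_detected_within_baseline_window():
    """With no stationary prefix the onset lands inside the baseline window:
    the detector cannot flag a rise before its baseline exists."""
    cfg = TrimConfig(baseline_window=10)
    trace = _scale_schedule_trace(n_flat=1, growth=0.02, n_grow=80)
    assert detect_walk_start(trace, cfg) <= cfg.baseline_window + cfg.confirm_frames


def test_constant_scale_never_starts():
    with pytest.raises(TrimError, match="no walking onset"):
        detect_walk_start(make_trace(standing_pose(T=80)))


def test_constant_scale_fallback_to_zero():
    cfg = TrimConfig(fallback_start_at_zero=True)
    assert detect_walk_start(make_trace(standing_pose(T=80)), cfg) == 0


def test_synthetic_onset_recovered_with_tolerance():
    """Detector finds the scripted onset: never early, within 1.5 s after."""
    cfg = SynthConfig()
    for seed, sev in [(1, 0), (2, 2), (3, 4)]:
        trace, truth = simulate_trial(cfg, "P", 1, seed, sev, "L")
        start = detect_walk_start(trace)
        assert truth.onset_frame <= start <= truth.onset_frame + 45
        assert detect_walk_end(trace) == truth.blackout_frame


# -- composition -----------------------------------------------------------

def test_preprocess_composes_detectors_and_filters():
    cfg = SynthConfig()
    trace, truth = simulate_trial(cfg, "P", 1, 21, 3, "R")
    out, trim = preprocess_trace(trace)
    assert trim.end_frame == detect_walk_end(trace)
    assert trim.start_frame == detect_walk_start(trace)
    assert out.n_frames == trim.end_frame - trim.start_frame
    assert trim.reason_start == "distance_rise"
    assert trim.reason_end == "landmark_lost"
    # output is a contiguous slice of the original frames
    assert np.array_equal(out.frame_index,
                          np.arange(trim.start_frame, trim.end_frame))
    # likelihoods untouched, coordinates filtered
    assert np.array_equal(out.likelihood,
                          trace.likelihood[trim.start_frame:trim.end_frame])
    assert np.allclose(out.xy[:, 0, 0],
                       median_filter3(trace.xy[trim.start_frame:trim.end_frame, 0, 0]))


def test_clean_full_length_walk_keeps_everything():
    trace = _scale_schedule_trace(n_flat=1, growth=0.01, n_grow=80)
    out, trim = preprocess_trace(trace, TrimConfig(baseline_window=10))
    assert trim.reason_end == "trace_end"
    assert trim.end_frame == trace.n_frames


def test_all_lost_trace_errors():
    xy = standing_pose(T=60)
    lik = np.full((60, 8), 0.1)
    with pytest.raises(TrimError):
        preprocess_trace(make_trace(xy, lik))


def test_short_retained_segment_errors():
    lost = np.zeros((40, 8), dtype=bool)
    lost[10:40, 3] = True  # only 10 frames retained
    trace = _trace_with_lost(lost)
    with pytest.raises(TrimError, match="shorter than"):
        preprocess_trace(trace, TrimConfig(fallback_start_at_zero=True,
                                           min_retained_frames=20))
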