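"""Thresholding, merging, matching and episode statistics, each against an
independent brute-force oracle where the spec of the operation allows one."""

import itertools

import numpy as np
import pandas as pd
import pytest

from swdkit import (
    DetectionConfig,
    EventAnnotation,
    SeizureCandidate,
    SimConfig,
    SWDDetector,
    ThresholdSpec,
    episode_statistics,
    evaluate_detection,
    simulate_recording,
)
from swdkit.config import FEATURES, FeatureThreshold
from swdkit.detection import compute_thresholds, flag_epochs, merge_candidates


def _table(values: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(values)


def _random_feature_table(rng, n=500):
    return _table({f: rng.normal(size=n) for f in FEATURES})


class TestComputeThresholds:
    def test_absolute_passthrough(self, rng):
        spec = ThresholdSpec({f: FeatureThreshold("absolute", 7.0) for f in FEATURES})
        thr = compute_thresholds(_random_feature_table(rng), spec)
        assert all(v == 7.0 for v in thr.values())

    def test_mad_zero_guard(self):
        vals = np.ones(1000)
        vals[500] = 100.0
        spec = ThresholdSpec({f: FeatureThreshold("robust_z", 3.0) for f in FEATURES})
        thr = compute_thresholds(_table({f: vals for f in FEATURES}), spec)
        # median 1, MAD 0 -> scale floored at 1e-9 * median
        assert thr["rms"] == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_tail_mass(self):
        # z = 3 robust threshold on Gaussian data leaves ~0.13% above
        exceed = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=20000)
            spec = ThresholdSpec({f: FeatureThreshold("robust_z", 3.0) for f in FEATURES})
            thr = compute_thresholds(_table({f: vals for f in FEATURES}), spec)
            exceed.append(np.mean(vals > thr["rms"]))
        assert np.mean(exceed) == pytest.approx(0.0013, abs=0.001)

    def test_too_few_epochs_directs_to_absolute(self, rng):
        with pytest.raises(ValueError, match="absolute"):
            compute_thresholds(_random_feature_table(rng, n=50), ThresholdSpec())


class TestFlagEpochs:
    def test_and_semantics(self):
        row = {f: np.array([1.0]) for f in FEATURES}
        thr = {f: 0.5 for f in FEATURES}
        assert flag_epochs(_table(row), thr)[0]
        row["band_ratio"] = np.array([0.4])  # one feature below
        assert not flag_epochs(_table(row), thr)[0]

    def test_matches_per_epoch_brute_force(self, rng):
        table = _random_feature_table(rng, n=300)
        thr = {f: float(rng.normal()) for f in FEATURES}
        flags = flag_epochs(table, thr)
        for i in range(len(table)):
            expect = all(table[f].iloc[i] > thr[f] for f in FEATURES)
            assert flags[i] == expect

    def test_strictly_greater(self):
        table = _table({f: np.array([0.5]) for f in FEATURES})
        assert not flag_epochs(table, {f: 0.5 for f in FEATURES})[0]


def _merge_oracle(flags, epoch_length, max_gap, min_duration):
    """Independent interval construction by linear scan."""
    intervals = []
    current = None
    gap = 0
    for i, f in enumerate(flags):
        if f:
            if current is None:
                current = [i, i]
            elif gap <= max_gap:
                current[1] = i
            else:
                intervals.append(current)
                current = [i, i]
            gap = 0
        elif current is not None:
            gap += 1
    if current is not None:
        intervals.append(current)
    out = []
    for lo, hi in intervals:
        dur = (hi - lo + 1) * epoch_length
        if dur >= min_duration:
            out.append((lo * epoch_length, (hi + 1) * epoch_length))
    return out


class TestMergeCandidates:
    def test_gap_bridging_example(self):
        cands = merge_candidates(np.array([1, 1, 0, 1, 1], bool), 0.5, 1, 1.0)
        assert len(cands) == 1
        assert cands[0].n_epochs == 5
        assert cands[0].duration == pytest.approx(2.5)

    def test_min_duration_filter(self):
        cands = merge_candidates(np.array([1, 0, 0, 1], bool), 0.5, 1, 1.0)
        assert cands == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle_on_random_flags(self, seed):
        rng = np.random.default_rng(seed)
        flags = rng.random(60) < 0.3
        max_gap = int(rng.integers(0, 3))
        min_dur = float(rng.choice([0.5, 1.0, 1.5]))
        got = merge_candidates(flags, 0.5, max_gap, min_dur)
        expect = _merge_oracle(flags, 0.5, max_gap, min_dur)
        assert [(c.start, c.end) for c in got] == expect

    def test_candidates_never_overlap(self, rng):
        flags = rng.random(200) < 0.5
        cands = merge_candidates(flags, 0.5, 1, 1.0)
        for a, b in zip(cands, cands[1:]):
            assert b.start >= a.end

    def test_peak_features_reported(self, rng):
        table = _random_feature_table(rng, n=6)
        flags = np.array([1, 1, 1, 0, 0, 0], bool)
        (cand,) = merge_candidates(flags, 0.5, 1, 1.0, table=table)
        assert cand.peak_rms == table["rms"][:3].max()


class TestEpisodeStatistics:
    def test_rate_arithmetic(self):
        cands = [SeizureCandidate("c", i * 10.0, i * 10.0 + 4.0, 8) for i in range(10)]
        st = episode_statistics(cands, 3.0)
        assert st.episodes_per_hour == pytest.approx(10 / 3.0)

    def test_equal_durations_zero_sem(self):
        cands = [SeizureCandidate("c", s, s + 4.0, 8) for s in (0.0, 10.0, 20.0)]
        st = episode_statistics(cands, 1.0)
        assert st.mean_duration == pytest.approx(4.0)
        assert st.sem_duration == pytest.approx(0.0)

    def test_sem_hand_computed(self):
        cands = [
            SeizureCandidate("c", 0.0, 3.5, 7),
            SeizureCandidate("c", 10.0, 14.0, 8),
            SeizureCandidate("c", 20.0, 24.5, 9),
        ]
        st = episode_statistics(cands, 3.0)
        assert st.mean_duration == pytest.approx(4.0)
        assert st.sem_duration == pytest.approx(0.5 / np.sqrt(3), abs=1e-4)

    def test_single_event_sem_undefined(self):
        st = episode_statistics([SeizureCandidate("c", 0.0, 4.0, 8)], 1.0)
        assert not st.sem_defined

    def test_zero_hours_rejected(self):
        with pytest.raises(ValueError):
            episode_statistics([], 0.0)


def _matching_oracle(cands, truth, tol):
    """Exhaustive maximum one-to-one matching on small instances."""
    eligible = [
        [(t.start - tol <= 0.5 * (c.start + c.end) <= t.end + tol) for t in truth]
        for c in cands
    ]
    best = 0
    idx_t = range(len(truth))
    for r in range(min(len(cands), len(truth)), 0, -1):
        for cs in itertools.combinations(range(len(cands)), r):
            for ts in itertools.permutations(idx_t, r):
                if all(eligible[c][t] for c, t in zip(cs, ts)):
                    best = max(best, r)
                    break
            if best == r:
                break
        if best:
            break
    return best


class TestEvaluateDetection:
    def test_perfect_candidates(self):
        truth = [EventAnnotation("c", 10.0, 14.0), EventAnnotation("c", 30.0, 34.0)]
        cands = [SeizureCandidate("c", t.start, t.end, 8) for t in truth]
        acc = evaluate_detection(cands, truth)
        assert acc.sensitivity == 1.0
        assert acc.false_discovery_rate == 0.0
        assert acc.mean_onset_error == 0.0

    def test_no_candidates_fdr_undefined(self):
        acc = evaluate_detection([], [EventAnnotation("c", 1.0, 2.0)])
        assert acc.sensitivity == 0.0
        assert np.isnan(acc.false_discovery_rate)

    @pytest.mark.parametrize("seed", range(25))
    def test_matched_count_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_c = int(rng.integers(1, 7)), int(rng.integers(0, 7))
        truth = []
        t0 = 0.0
        for _ in range(n_t):
            t0 += rng.uniform(1, 20)
            truth.append(EventAnnotation("c", t0, t0 + rng.uniform(1, 5)))
            t0 = truth[-1].end
        cands = []
        for _ in range(n_c):
            s = rng.uniform(0, t0 + 5)
            cands.append(SeizureCandidate("c", s, s + rng.uniform(0.5, 6), 4))
        acc = evaluate_detection(cands, truth, match_tolerance=2.0)
        assert acc.n_matched == _matching_oracle(cands, truth, 2.0)

    def test_channels_matched_independently(self):
        truth = [EventAnnotation("a", 10.0, 14.0)]
        cands = [SeizureCandidate("b", 10.0, 14.0, 8)]
        acc = evaluate_detection(cands, truth)
        assert acc.n_matched == 0


class TestEndToEnd:
    def test_monotonicity_of_thresholds(self, rng):
        """Raising any single threshold never increases flagged epochs."""
        table = _random_feature_table(rng, n=400)
        base = {f: float(rng.normal()) for f in FEATURES}
        n_base = flag_epochs(table, base).sum()
        for _ in range(50):
            feat = rng.choice(FEATURES)
            raised = dict(base)
            raised[feat] += float(rng.uniform(0, 2))
            assert flag_epochs(table, raised).sum() <= n_base

    def test_conjunction_is_restrictive(self, rng):
        table = _random_feature_table(rng, n=400)
        thr = {f: float(rng.normal()) for f in FEATURES}
        joint = flag_epochs(table, thr).sum()
        for f in FEATURES:
            assert joint <= (table[f].to_numpy() > thr[f]).sum()

    def test_detect_recovers_injected_events(self, short_benchmark):
        _, recording, truth = short_benchmark
        results = SWDDetector(recording).fit()
        acc = results.evaluate(truth)
        assert acc.sensitivity >= 0.75
        for c in results.candidates:
            assert any(t.start - 2 <= c.midpoint <= t.end + 2 for t in truth)

    def test_detect_is_deterministic(self, short_benchmark):
        _, recording, _ = short_benchmark
        r1 = SWDDetector(recording).fit()
        r2 = SWDDetector(recording).fit()
        assert r1.candidates == r2.candidates
        assert r1.features.equals(r2.features)

    def test_pure_gain_leaves_candidates_unchanged(self, short_benchmark):
        """Doubling the signal rescales the robust thresholds, so the
        candidate set is identical."""
        _, recording, _ = short_benchmark
        doubled = recording.copy()
        doubled.samples *= 2.0
        c1 = SWDDetector(recording).fit().candidates
        c2 = SWDDetector(doubled).fit().candidates
        assert [(c.channel, c.start, c.end) for c in c1] == [
            (c.channel, c.start, c.end) for c in c2
        ]

    def test_results_summary_and_frame(self, short_benchmark):
        _, recording, _ = short_benchmark
        results = SWDDetector(recording).fit()
        text = results.summary()
        assert "Candidates" in text and "thresholds" in text
        frame = results.candidates_frame
        assert list(frame["start_s"]) == [c.start for c in results.candidates]

    def test_background_only_recording_is_quiet(self):
        from swdkit import SWDParams

        cfg = SimConfig(duration=900.0, seed=33, swd=SWDParams(rate=0.0))
        rec, truth = simulate_recording(cfg)
        assert truth == []
        results = SWDDetector(rec).fit()
        assert len(results.candidates) == 0
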