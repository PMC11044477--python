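import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calsa.features import (
    CrackleEvent,
    FeatureConfig,
    UndefinedRatioError,
    analyze_recording,
    crackle_counts,
    detect_crackles,
    detect_wheezes,
    ei_ratios,
    score_crackle_detection,
)
from calsa.io_audio import Cycle, CycleAnnotation
from calsa.preprocess import ComponentPair, denoise, separate_stationary_nonstationary
from calsa.synthetic import SimulationSpec, simulate_recording

ANN = CycleAnnotation((Cycle(0.5, 1.5, 3.0), Cycle(3.5, 4.5, 6.0)))


class TestEIRatios:
    def test_identical_signal_in_both_phases_gives_unity(self):
        rng = np.random.default_rng(0)
        fs = 8000
        x = np.zeros(7 * fs)
        burst = rng.normal(0, 0.2, fs)  # same 1 s noise in every phase slot
        for start in (0.5, 1.5, 3.5, 4.5):
            x[int(start * fs) : int(start * fs) + fs] = burst
        ann = CycleAnnotation((Cycle(0.5, 1.5, 2.5), Cycle(3.5, 4.5, 5.5)))
        comp = ComponentPair(x, np.zeros_like(x), fs, 1)
        r = ei_ratios(comp, ann, noise_correction=False)
        # filter ringing at the abrupt burst edges costs a little symmetry
        for v in r.as_tuple():
            assert v == pytest.approx(1.0, rel=0.02)

    def test_half_amplitude_expiration_quarters_ratio(self):
        spec = SimulationSpec(
            seed=41,
            insp_gain=(1.0, 0.85, 0.42, 0.21),
            exp_gain=(0.5, 0.425, 0.21, 0.105),
        )
        rec, truth = simulate_recording(spec)
        comp = separate_stationary_nonstationary(denoise(rec))
        r = ei_ratios(comp, truth.annotation)
        for v in r.as_tuple():
            assert v == pytest.approx(0.25, rel=0.10)

    def test_silent_expiration_gives_zero_ratio(self):
        rng = np.random.default_rng(1)
        fs = 8000
        x = np.zeros(7 * fs)
        for start in (0.5, 3.5):  # inspirations only
            x[int(start * fs) : int((start + 1) * fs)] = rng.normal(0, 0.2, fs)
        comp = ComponentPair(x, np.zeros_like(x), fs, 1)
        r = ei_ratios(comp, ANN, noise_correction=False)
        # true-zero expiration: only band-filter ringing leaks across
        for v in r.as_tuple():
            assert v <= 0.01

    def test_zero_inspiratory_power_flagged_undefined(self):
        comp = ComponentPair(np.zeros(8000 * 7), np.zeros(8000 * 7), 8000, 1)
        with pytest.raises(UndefinedRatioError):
            ei_ratios(comp, ANN)

    def test_global_scaling_leaves_ratios_unchanged(self, default_pair):
        comp, truth = default_pair
        r1 = ei_ratios(comp, truth.annotation)
        scaled = ComponentPair(
            comp.stationary * 4.2, comp.nonstationary * 4.2, comp.sample_rate, 1
        )
        r2 = ei_ratios(scaled, truth.annotation)
        assert np.allclose(r1.as_tuple(), r2.as_tuple(), rtol=1e-9)


class TestCrackleDetection:
    def test_injected_crackles_recovered_with_timing(self):
        # ground-truth oracle: every injected event, +-5 ms
        spec = SimulationSpec(
            seed=42, n_cycles=4, crackles_per_insp=2.0, crackles_per_exp=1.0,
            crackle_snr_db=(14.0, 18.0), ambient_snr_db=20.0,
        )
        rec, truth = simulate_recording(spec)
        comp = separate_stationary_nonstationary(denoise(rec))
        events = detect_crackles(comp, truth.annotation)
        true_t = truth.crackle_times()
        assert len(true_t) >= 8
        f = score_crackle_detection(np.array([e.time for e in events]), true_t, 0.010)
        assert f >= 0.95
        offsets = [np.abs(e.time - true_t).min() for e in events]
        assert np.median(offsets) <= 0.005

    def test_clean_breath_has_at_most_one_spurious_event(self, clean_pair):
        comp, truth = clean_pair
        events = detect_crackles(comp, truth.annotation)
        assert len(events) <= 1

    def test_silence_yields_no_events(self):
        comp = ComponentPair(np.zeros(8000 * 12), np.zeros(8000 * 12), 8000, 1)
        assert detect_crackles(comp, ANN) == []

    def test_events_respect_phase_assignment(self, default_pair):
        comp, truth = default_pair
        for e in detect_crackles(comp, truth.annotation):
            assert truth.annotation.phase_of(e.time) == e.phase
            assert e.duration <= 0.025


class TestCrackleCounts:
    def test_mean_per_cycle_arithmetic(self):
        events = [CrackleEvent(0.6 + 0.05 * i, "inspiration", 1.0, 0.005) for i in range(8)]
        events += [CrackleEvent(1.6 + 0.05 * i, "expiration", 1.0, 0.005) for i in range(4)]
        ann = CycleAnnotation(tuple(Cycle(i * 2 + 0.5, i * 2 + 1.5, i * 2 + 2.4) for i in range(4)))
        c = crackle_counts(events, ann)
        assert (c.inspiration, c.expiration, c.full_cycle) == (2.0, 1.0, 3.0)

    def test_zero_events(self):
        c = crackle_counts([], ANN)
        assert (c.full_cycle, c.inspiration, c.expiration) == (0.0, 0.0, 0.0)

    @given(
        n_insp=st.integers(0, 40),
        n_exp=st.integers(0, 40),
        n_cycles=st.integers(2, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_full_cycle_is_exact_sum(self, n_insp, n_exp, n_cycles):
        cycles = tuple(Cycle(i * 3 + 0.2, i * 3 + 1.2, i * 3 + 2.8) for i in range(n_cycles))
        ann = CycleAnnotation(cycles)
        events = [CrackleEvent(0.5, "inspiration", 1.0, 0.005)] * n_insp
        events += [CrackleEvent(1.5, "expiration", 1.0, 0.005)] * n_exp
        c = crackle_counts(events, ann)
        assert c.full_cycle == pytest.approx(c.inspiration + c.expiration, abs=1e-9)

    def test_single_cycle_rejected(self):
        ann = CycleAnnotation((Cycle(0.5, 1.5, 3.0),))
        with pytest.raises(ValueError):
            crackle_counts([], ann)


class TestWheezes:
    def test_constant_tone_half_of_expiration(self):
        # 400 Hz tone over the first half of every expiration: detected
        # segments at 400 Hz should occupy ~50% of expiratory time
        spec = SimulationSpec(seed=21, n_cycles=6, ambient_snr_db=20.0)
        rec, truth = simulate_recording(spec)
        fs = rec.sample_rate
        x = rec.samples.copy()
        for c in truth.annotation.cycles:
            half = (c.exp_end - c.insp_end) / 2
            i0, i1 = int(c.insp_end * fs), int((c.insp_end + half) * fs)
            x[i0:i1] += 0.25 * np.sin(2 * np.pi * 400.0 * np.arange(i1 - i0) / fs)
        rec = rec.with_samples(0.9 * x / np.max(np.abs(x)))
        comp = separate_stationary_nonstationary(denoise(rec))
        segs = detect_wheezes(comp, truth.annotation)
        tonal = [s for s in segs if abs(s.mean_frequency - 400.0) < 10.0]
        assert len(tonal) >= 5  # one per expiration, possibly merged/fragmented
        assert sum(s.occupation_rate for s in tonal) == pytest.approx(50.0, abs=5.0)
        other = sum(s.occupation_rate for s in segs if s not in tonal)
        assert other <= 5.0

    def test_breath_noise_alone_yields_no_segments(self, clean_pair):
        comp, truth = clean_pair
        assert detect_wheezes(comp, truth.annotation) == []

    def test_two_wheezes_of_different_lengths_distinct_occupation(self):
        spec = SimulationSpec(
            seed=44, n_cycles=6, exp_duration=2.0, ambient_snr_db=20.0,
            wheezes=(("expiration", 420.0, 1.4, 0.6), ("expiration", 620.0, 0.6, 0.6)),
        )
        rec, truth = simulate_recording(spec)
        assert len(truth.wheezes) == 2
        comp = separate_stationary_nonstationary(denoise(rec))
        segs = detect_wheezes(comp, truth.annotation)
        occ = {}
        for w in truth.wheezes:
            match = [s for s in segs if abs(s.mean_frequency - w.f0) < 60]
            assert match, f"wheeze at {w.f0} Hz not detected"
            occ[w.f0] = sum(s.occupation_rate for s in match)
        assert occ[420.0] > occ[620.0]  # longer wheeze occupies more

    def test_quartiles_ordered_and_occupation_bounded(self, default_pair):
        comp, truth = default_pair
        for s in detect_wheezes(comp, truth.annotation):
            assert s.f25 <= s.f50 <= s.f75
            assert 0 < s.occupation_rate <= 100


class TestAnalyzeRecording:
    def test_full_pipeline_feature_row(self, default_recording):
        rec, truth = default_recording
        row = analyze_recording(rec)
        assert row.n_cycles >= 2
        assert row.ei is not None
        assert row.crackles.full_cycle == pytest.approx(
            row.crackles.inspiration + row.crackles.expiration, abs=1e-9
        )
        d = row.to_dict()
        assert set(d) >= {
            "subject_id", "assessment_id", "location", "n_cycles",
            "ei_100_200", "ei_200_400", "ei_400_800", "ei_800_1600",
            "crackles_full", "crackles_insp", "crackles_exp",
            "n_wheezes", "wheeze_occupation_total", "quality_flags",
        }
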