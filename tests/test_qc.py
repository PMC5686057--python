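"""Threshold QC: per-device thresholds, occupancy rules, window rejection
with padding, artifact classification, and rejection statistics."""

import numpy as np
import pytest

from mobiqc import (
    baseline_viewing_design,
    partition_conditions,
    classify_artifacts,
    inject_artifact,
    load_headset_profile,
    qc_report,
    reject_channels,
    reject_windows,
    simulate_session,
    thresholds_for,
)
from mobiqc.recording import overlapping_labels
from mobiqc.segment import Epoch, slide_windows
from mobiqc.synth import ArtifactPlanItem

from conftest import make_recording


class TestThresholds:
    @pytest.mark.parametrize("name,lower", [
        ("M32", 2.9), ("M4S", 2.9), ("SS", 0.5), ("BPD", 0.5), ("BPG", 1.0),
    ])
    def test_lower_is_ten_times_resolution(self, name, lower):
        """Per-device lower thresholds (the published 3 uV for M32/M4S is
        the rounded value of 10 x 0.29)."""
        upper, low = thresholds_for(load_headset_profile(name))
        assert upper == 300.0
        assert low == pytest.approx(lower)

    def test_custom_multiplier(self, m4s):
        _, low = thresholds_for(m4s, lower_multiplier=20)
        assert low == pytest.approx(5.8)


class TestChannelRejection:
    def test_constant_zero_rejected_for_lower(self):
        rec = make_recording(np.vstack([np.zeros(1000),
                                        np.full(1000, 50.0) *
                                        np.sin(np.arange(1000))]))
        decisions = reject_channels(rec, 300.0, 3.0)
        assert not decisions[0].keep
        assert decisions[0].reason == "lower"
        assert decisions[1].keep

    def test_square_wave_duty_above_occupancy_rejected_upper(self):
        fs = 100.0
        x = np.zeros(int(10 * fs))
        x[: int(2.5 * fs)] = 400.0  # 25% duty above 300 uV
        x[int(2.5 * fs):] = 50.0
        rec = make_recording([x], fs=fs)
        (d,) = reject_channels(rec, 300.0, 3.0)
        assert not d.keep and d.reason == "upper"
        assert d.upper_fraction == pytest.approx(0.25)

    def test_ordinary_sinusoid_kept(self):
        fs = 256.0
        t = np.arange(int(10 * fs)) / fs
        rec = make_recording([50.0 * np.sin(2 * np.pi * 10 * t)], fs=fs)
        (d,) = reject_channels(rec, 300.0, 3.0)
        assert d.keep and d.reason == "none"
        assert d.upper_fraction == 0.0

    def test_upper_takes_precedence(self):
        # above 300 uV for 30% of the time, near zero otherwise: both rules hit
        x = np.concatenate([np.full(300, 400.0), np.zeros(700)])
        (d,) = reject_channels(make_recording([x]), 300.0, 3.0)
        assert d.reason == "upper"

    def test_occupancy_monotonicity(self, rng):
        """Raising the occupancy requirement never rejects more channels."""
        rec = make_recording(rng.standard_normal((6, 4000)) * 150.0, fs=100.0,
                             labels=[f"C{i}" for i in range(6)])
        rejected = []
        for occ in (0.05, 0.2, 0.5):
            d = reject_channels(rec, 300.0, 3.0, occupancy=occ)
            rejected.append({x.channel for x in d if not x.keep})
        assert rejected[2] <= rejected[1] <= rejected[0]

    def test_empty_recording_rejected(self):
        rec = make_recording(np.empty((1, 0)))
        with pytest.raises(ValueError):
            reject_channels(rec, 300.0, 3.0)


class TestWindowRejection:
    def windows(self, duration=60.0):
        return slide_windows(Epoch("baseline", "baseline", None, 0.0,
                                   duration))

    def test_spike_padding_rejects_intersecting_windows(self, noise_recording):
        rec = noise_recording.copy()
        rec.signal[1, rec.time_to_sample(10.0)] = 400.0
        mask = reject_windows(rec, self.windows(), 300.0)
        # dilated bad region is [9.5, 10.5]; windows are [start, start+4)
        for w, keep in zip(mask.windows, mask.keep):
            overlaps = w.start_s < 10.5 and w.end_s > 9.5
            assert keep != overlaps

    def test_clean_recording_keeps_everything(self, noise_recording):
        mask = reject_windows(noise_recording, self.windows(), 300.0)
        assert mask.n_rejected == 0

    def test_spike_at_start_clips_dilation(self, noise_recording):
        rec = noise_recording.copy()
        rec.signal[0, 0] = 500.0
        mask = reject_windows(rec, self.windows(), 300.0)
        rejected = [w for w, k in zip(mask.windows, mask.keep) if not k]
        assert all(w.start_s < 0.5 for w in rejected)
        assert len(rejected) == 1  # only the first window touches [0, 0.5]

    def test_lower_threshold_monotonicity(self, rng):
        """Lowering the upper threshold never un-rejects windows."""
        rec = make_recording(rng.standard_normal((2, 256 * 60)) * 120.0)
        wins = self.windows()
        r_strict = set()
        prev = set()
        for upper in (500.0, 350.0, 250.0):
            mask = reject_windows(rec, wins, upper)
            cur = {i for i, k in enumerate(mask.keep) if not k}
            assert prev <= cur
            prev = cur


class TestClassification:
    def test_injected_artifacts_recovered(self, m4s):
        plan = (
            ArtifactPlanItem("pop", spans=((30.0, 30.4),), channels=("Fp1",)),
            ArtifactPlanItem("wireless_loss", spans=((80.0, 82.0),)),
            ArtifactPlanItem("flat", spans=((100.0, 106.0),),
                             channels=("Fp2",)),
            ArtifactPlanItem("digitization", spans=((50.0, 60.0),),
                             channels=("AFp1",)),
        )
        design = baseline_viewing_design(m4s, seed=4, viewing_s=60.0,
                                         artifact_plan=plan)
        rec, _, truth = simulate_session(design)
        found = classify_artifacts(rec, m4s)

        def typed(kind):
            return [l for l in found if l.type == kind]

        pops = overlapping_labels(typed("pop"), 29.5, 31.0)
        assert len(pops) == 1 and pops[0].channels == ("Fp1",)
        wl = overlapping_labels(typed("wireless_loss"), 79.5, 82.5)
        assert len(wl) == 1
        assert wl[0].start_s == pytest.approx(80.0, abs=0.1)
        fl = [l for l in typed("flat") if l.covers_channel("Fp2")]
        assert overlapping_labels(fl, 100.0, 106.0)
        dg = [l for l in typed("digitization") if l.covers_channel("AFp1")]
        assert overlapping_labels(dg, 50.0, 60.0)

    def test_session_long_flat_channel(self, noise_recording):
        rec = noise_recording.copy()
        rec.signal[3, :] = 1.0
        labels = classify_artifacts(rec, load_headset_profile("SS"))
        fl = [l for l in labels if l.type == "flat"
              and l.covers_channel("P4")]
        assert len(fl) == 1
        assert fl[0].start_s == 0.0
        assert fl[0].end_s == pytest.approx(rec.duration_s)

    def test_poor_contact_from_repeated_excursions(self, noise_recording):
        rec = noise_recording
        for start in (10.0, 12.0, 14.0, 16.0):
            rec, _ = inject_artifact(rec, "pop", ("F3",),
                                     (start, start + 0.3), seed=1)
        labels = classify_artifacts(rec, load_headset_profile("SS"))
        pc = [l for l in labels if l.type == "poor_contact"
              and l.covers_channel("F3")]
        assert len(pc) == 1
        assert pc[0].start_s == pytest.approx(10.0, abs=0.5)
        assert pc[0].end_s == pytest.approx(16.3, abs=0.5)

    def test_labels_non_overlapping_per_channel_and_type(self, m4s):
        design = baseline_viewing_design(
            m4s, seed=9, viewing_s=120.0,
            artifact_plan=(ArtifactPlanItem("pop", rate_per_min=2.0),
                           ArtifactPlanItem("flat", rate_per_min=1.0)))
        rec, _, _ = simulate_session(design)
        labels = classify_artifacts(rec, m4s)
        by_key = {}
        for l in labels:
            chans = l.channels if l.channels != "ALL" else ("ALL",)
            for c in chans:
                by_key.setdefault((l.type, c), []).append((l.start_s, l.end_s))
        for spans in by_key.values():
            spans.sort()
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                assert b0 >= a1 - 1e-9


class TestReport:
    def test_zero_rejections_give_zero_rates(self, noise_recording):
        decisions = reject_channels(noise_recording, 300.0, 0.5)
        wins = slide_windows(Epoch("baseline", "baseline", None, 0.0, 60.0))
        mask = reject_windows(noise_recording, wins, 300.0)
        rep = qc_report(decisions, mask)
        assert rep.channel_rejection_rate == 0.0
        assert rep.data_rejection_rate == 0.0

    def test_rates_are_simple_fractions(self, rng):
        sig = rng.standard_normal((32, 10000)) * 10.0
        sig[:8] = 0.0  # 8 flat channels
        rec = make_recording(sig, fs=100.0,
                             labels=[f"C{i}" for i in range(32)])
        decisions = reject_channels(rec, 300.0, 3.0)
        assert sum(not d.keep for d in decisions) == 8
        retained = rec.pick([d.channel for d in decisions if d.keep])
        retained.signal[0, 5000] = 400.0
        wins = slide_windows(Epoch("baseline", "baseline", None, 0.0, 100.0))
        mask = reject_windows(retained, wins, 300.0)
        rep = qc_report(decisions, mask)
        assert rep.channel_rejection_rate == pytest.approx(8 / 32)
        assert rep.data_rejection_rate == pytest.approx(
            mask.n_rejected / len(wins))
        assert mask.n_rejected == 3  # spike at 50 s, windows 46/48/50 s


class TestDetectionPerformance:
    def test_sensitivity_and_false_rejection(self, m4s):
        """Window rejection catches injected supra-300 uV artifacts and
        spares clean sessions (small-sample version of the 20-seed check)."""
        hits = trials = 0
        false_rej = []
        for seed in range(5):
            plan = (ArtifactPlanItem("pop", rate_per_min=1.0),)
            rec, track, truth = simulate_session(
                baseline_viewing_design(m4s, seed=seed, viewing_s=120.0,
                                        artifact_plan=plan))
            wins = [w for e in partition_conditions(rec, track)
                    for w in slide_windows(e)]
            mask = reject_windows(rec, wins, 300.0)
            for lab in truth:
                # the burst peak sits at the span center and exceeds 300 uV
                center = (lab.start_s + lab.end_s) / 2
                idx = [i for i, w in enumerate(wins)
                       if w.start_s <= center < w.end_s]
                if not idx:
                    continue  # artifact fell outside any analysis window
                trials += 1
                if all(not mask.keep[i] for i in idx):
                    hits += 1
            clean, track2, _ = simulate_session(
                baseline_viewing_design(m4s, seed=seed + 100,
                                        viewing_s=120.0))
            wins2 = [w for e in partition_conditions(clean, track2)
                     for w in slide_windows(e)]
            mask2 = reject_windows(clean, wins2, 300.0)
            false_rej.append(mask2.n_rejected / len(wins2))
        assert trials > 0
        assert hits / trials >= 0.95
        assert np.mean(false_rej) <= 0.05
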