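"""Generator contracts: determinism, label consistency, node-model behavior."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from atriakit.recording import ATRIAL, Recording
from atriakit.synth import (CohortDesign, NodeModelParams, OutcomeSpec,
                            SignalModelParams, StimulationSchedule,
                            decremental_schedule, generate_burst_trial,
                            generate_cohort, generate_sinus_recording,
                            s1s2_schedule, simulate_programmed_stimulation,
                            snrt_schedule)


class TestSinusRecording:
    def test_expected_beat_count_at_male_rr(self, male_params):
        rec = generate_sinus_recording(male_params, 10.0)
        qrs = rec.annotations.query("kind == 'qrs'")
        # 10 s at a 182.2-ms cycle -> ~55 beats
        assert 53 <= len(qrs) <= 56

    def test_zero_farfield_gain_leaves_pure_atrial_channel(self):
        p = dataclasses.replace(SignalModelParams(seed=1),
                                ventricular_farfield_gain=0.0,
                                noise_sd=0.0, wander_amplitude=0.0)
        rec = generate_sinus_recording(p, 5.0)
        atr = rec.channel(ATRIAL)
        # energy only around the annotated atrial deflections
        mask = np.zeros(rec.n_samples, bool)
        for t in rec.annotations.query("kind == 'atrial'")["time_s"]:
            i = rec.index_at(t)
            mask[max(0, i - 20): i + 20] = True
        assert np.abs(atr[~mask]).max() < 1e-9
        assert np.abs(atr[mask]).max() > 0.5

    def test_deterministic_under_identical_seed(self, male_params):
        a = generate_sinus_recording(male_params, 4.0)
        b = generate_sinus_recording(male_params, 4.0)
        assert np.array_equal(a.signals, b.signals)

    def test_different_seed_differs(self, male_params):
        p2 = dataclasses.replace(male_params, seed=99)
        a = generate_sinus_recording(male_params, 4.0)
        b = generate_sinus_recording(p2, 4.0)
        assert not np.array_equal(a.signals, b.signals)

    def test_too_short_duration_rejected(self, male_params):
        with pytest.raises(ValueError):
            generate_sinus_recording(male_params, 0.2)
        with pytest.raises(ValueError):
            generate_sinus_recording(male_params, -1.0)


class TestBurstTrial:
    def test_layout_and_truth_bookkeeping(self, male_params, af_outcome):
        tr = generate_burst_trial(male_params, af_outcome)
        assert tr.burst_start_s == pytest.approx(5.0)
        assert tr.burst_end_s == pytest.approx(6.0)
        assert tr.truth_duration_s == pytest.approx(6.0)
        stim = tr.recording.annotations.query("kind == 'stim'")
        assert len(stim) == 100          # 1 s at 10-ms CL

    @pytest.mark.parametrize("kind", ["af", "regular_svt", "sinus"])
    def test_truth_activations_satisfy_outcome_invariants(self, male_params,
                                                          kind):
        if kind == "af":
            outcome = OutcomeSpec("af", 8.0, af_mean_interval=45.0,
                                  af_interval_cv=0.25)
        elif kind == "regular_svt":
            outcome = OutcomeSpec("regular_svt", 8.0, svt_cl=70.0, svt_cv=0.01)
        else:
            outcome = OutcomeSpec("sinus")
        tr = generate_burst_trial(male_params, outcome)
        ep = tr.truth_atrial_times
        ep = ep[(ep > tr.burst_end_s) & (ep < tr.episode_end_s)]
        iv = np.diff(ep) * 1000.0
        if kind == "af":
            assert np.median(iv) < 55.0
            assert np.all(iv >= 15.0)
            assert np.std(iv) / np.mean(iv) > 0.05
        elif kind == "regular_svt":
            assert np.median(iv) > 60.0
            assert np.std(iv) / np.mean(iv) <= 0.05
        else:
            assert len(ep) == 0

    def test_sinus_outcome_with_duration_rejected(self):
        with pytest.raises(ValueError):
            OutcomeSpec("sinus", episode_duration=2.0)

    def test_outcome_interval_invariants_enforced(self):
        with pytest.raises(ValueError):
            OutcomeSpec("regular_svt", 5.0, svt_cl=55.0)
        with pytest.raises(ValueError):
            OutcomeSpec("af", 5.0, af_mean_interval=60.0)


class TestNodeSimulator:
    def test_s2_capture_thresholds(self):
        node = NodeModelParams(atrial_erp=30.0)
        for coupling, expect in [(40.0, True), (28.0, False), (30.0, False),
                                 (32.0, True)]:
            log = simulate_programmed_stimulation(
                node, s1s2_schedule(120.0, coupling), seed=0)
            s2 = log.events[log.events["type"] == "S2"].iloc[0]
            assert bool(s2["atrial_captured"]) is expect, coupling

    def test_capture_monotone_in_coupling(self):
        node = NodeModelParams(atrial_erp=28.0)
        captured = []
        for c in np.arange(20.0, 46.0, 2.0):
            log = simulate_programmed_stimulation(
                node, s1s2_schedule(120.0, c), seed=0)
            s2 = log.events[log.events["type"] == "S2"].iloc[0]
            captured.append(bool(s2["atrial_captured"]))
        # once captured at some coupling, captured at every longer one
        first_true = captured.index(True)
        assert all(captured[first_true:])
        assert not any(captured[:first_true])

    def test_emergent_block_cls_match_configuration(self):
        node = NodeModelParams(wenckebach_cl=90.0, two_to_one_cl=75.0)
        log = simulate_programmed_stimulation(
            node, decremental_schedule(np.arange(100.0, 65.0, -5.0)), seed=0)
        ev = log.events
        paced = ev[(ev["type"] != "spontaneous")
                   & ev["atrial_captured"].astype(bool)]
        drops = {cl: int((~grp["ventricular_conducted"].astype(bool)).sum())
                 for cl, grp in paced.groupby("basic_cl_ms")}
        assert drops[95.0] == 0 and drops[100.0] == 0
        assert drops[90.0] >= 1
        # 2:1 conduction (half the captured beats conduct) at and below 75 ms
        for cl, grp in paced.groupby("basic_cl_ms"):
            cond = grp["ventricular_conducted"].to_numpy(bool)[1:]
            if cl <= 75.0:
                assert np.mean(cond.astype(int)) == pytest.approx(0.5, abs=0.02)
            elif cl >= 95.0:
                assert np.all(cond)

    def test_snrt_suppression_applied_after_overdrive(self):
        node = NodeModelParams(snrt_suppression=25.0,
                               spontaneous_jitter_sd=0.0)
        log = simulate_programmed_stimulation(node, snrt_schedule(1), seed=0)
        ev = log.events
        paced = ev[ev["type"] == "burst"]
        t_last = paced["time_s"].iloc[-1]
        spont = ev[(ev["type"] == "spontaneous") & (ev["time_s"] > t_last)]
        first_cycle = (spont["time_s"].iloc[0] - t_last) * 1000.0
        assert first_cycle == pytest.approx(node.sinus_cl + 25.0, abs=0.5)

    def test_overlapping_pulses_rejected(self):
        df = pd.DataFrame({"time_s": [0.5, 0.502], "type": ["S1", "S1"],
                           "basic_cl_ms": 120.0, "coupling_ms": 120.0})
        with pytest.raises(ValueError):
            StimulationSchedule(df)

    def test_invalid_node_params_rejected(self):
        with pytest.raises(ValueError):
            NodeModelParams(wenckebach_cl=70.0, two_to_one_cl=80.0)


class TestCohort:
    def test_group_means_near_targets(self):
        df = generate_cohort(CohortDesign(), seed=5)
        uas = df[df["condition"] == "UAS"]
        cr = uas[uas["parameter"] == "mean_cr"].groupby("sex")["value"].mean()
        # within 2 SEM-matched SDs of the configured group targets
        assert cr["male"] == pytest.approx(1.22, abs=2 * 0.03 * np.sqrt(13) / np.sqrt(13))
        assert cr["female"] == pytest.approx(1.10, abs=2 * 0.02 * np.sqrt(16) / np.sqrt(16))

    def test_null_design_conditions_exchangeable(self):
        params = {"rr": dataclasses.replace(
            CohortDesign().parameters["rr"], shifts={})}
        design = CohortDesign(n_male=60, n_female=2, parameters=params)
        df = generate_cohort(design, seed=7)
        male_rr = df[(df.sex == "male") & (df.parameter == "rr")]
        means = male_rr.groupby("condition")["value"].mean()
        assert means.max() - means.min() < 3.0   # ~ within-noise scale

    def test_binomial_induction_expectation(self):
        design = CohortDesign(n_male=500, n_female=2)
        df = generate_cohort(design, seed=11)
        m = df[(df.sex == "male") & (df.condition == "UAS")
               & (df.parameter == "af_induction_pct")]["value"]
        assert m.mean() / 100.0 == pytest.approx(0.3077, abs=0.015)

    def test_repeated_measures_structure(self):
        df = generate_cohort(CohortDesign(), seed=3)
        counts = df.groupby(["animal_id", "parameter"])["condition"].nunique()
        assert (counts == 3).all()

    def test_small_design_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_male=1)


class TestRecordingIO:
    def test_hdf5_roundtrip(self, sinus_recording, tmp_path):
        path = tmp_path / "rec.h5"
        sinus_recording.to_hdf5(path)
        back = Recording.from_hdf5(path)
        assert np.array_equal(back.signals, sinus_recording.signals)
        assert back.channel_roles == sinus_recording.channel_roles
        assert back.sample_rate == sinus_recording.sample_rate
        assert len(back.annotations) == len(sinus_recording.annotations)

    def test_csv_roundtrip(self, sinus_recording, tmp_path):
        path = tmp_path / "signals.csv"
        sinus_recording.to_csv(path)
        back = Recording.from_csv(path)
        assert np.allclose(back.signals, sinus_recording.signals)
        assert back.channel_roles == sinus_recording.channel_roles

    def test_duplicate_roles_rejected(self):
        with pytest.raises(ValueError):
            Recording(np.zeros((2, 10)), 2000.0, ["ecg_1", "ecg_1"])
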