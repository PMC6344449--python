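"""Synthetic trial generator: geometry, calibration, spectra, determinism."""

import copy

import numpy as np
import pytest
from scipy import signal as sps

from posturemep.mep import extract_mep_p2p, estimate_mmax
from posturemep.protocol import ConditionName, ScheduleEntry, TrialKind, MUSCLES
from posturemep.synth import (
    BurstParams,
    PopulationConfig,
    sample_subject,
    simulate_cohort,
    simulate_mmax_sweep,
    simulate_subject,
    simulate_trial,
)

HIGH_MEP = ScheduleEntry(ConditionName.High, TrialKind.MEP, "AnteriorLarge")
NOPERT_CATCH = ScheduleEntry(ConditionName.NoPerturbation, TrialKind.catch, None)


class TestTrialGeometry:
    def test_tms_precedes_onset_by_200_samples(self, subject_model):
        t = simulate_trial(subject_model, HIGH_MEP, 0)
        assert t.tms_time is not None and t.perturbation_onset is not None
        fs = t.sample_rate
        assert round(t.perturbation_onset * fs) - round(t.tms_time * fs) == 200

    def test_catch_trial_has_no_tms(self, subject_model):
        entry = ScheduleEntry(ConditionName.High, TrialKind.catch, "AnteriorLarge")
        t = simulate_trial(subject_model, entry, 0)
        assert t.tms_time is None
        assert t.perturbation_onset is not None

    def test_noperturbation_catch_is_pure_background(self, subject_model):
        t = simulate_trial(subject_model, NOPERT_CATCH, 0)
        assert t.tms_time is None and t.perturbation_onset is None
        assert np.all(t.platform_displacement == 0)

    def test_channels_equal_length(self, subject_model):
        t = simulate_trial(subject_model, HIGH_MEP, 1)
        lengths = {x.size for x in t.channels.values()}
        assert lengths == {int(round(3.0 * 4000))}

    def test_platform_reaches_amplitude(self, subject_model):
        t = simulate_trial(subject_model, HIGH_MEP, 1)
        assert t.platform_displacement[-1] == pytest.approx(7.0)


class TestBackground:
    def test_rms_calibration_pre_event(self, subject_model):
        t = simulate_trial(subject_model, NOPERT_CATCH, 5)
        for m in MUSCLES:
            x = t.channels[m][: 4000]  # pre-event window, no MEP/burst anywhere
            target = subject_model.background_rms[m]
            assert np.sqrt(np.mean(x**2)) == pytest.approx(target, rel=0.05)
            assert abs(x.mean()) < 0.1 * target

    def test_spectral_contract(self, subject_model):
        """Out-of-band (outside 15-1000 Hz) power is < 1% of the total."""
        t = simulate_trial(subject_model, NOPERT_CATCH, 6)
        x = t.channels["TA"]
        f, p = sps.periodogram(x, fs=t.sample_rate)
        out_of_band = (f < 15.0) | (f > 1000.0)
        assert p[out_of_band].sum() / p.sum() < 0.01

    def test_determinism(self, subject_model):
        a = simulate_trial(subject_model, HIGH_MEP, 123)
        b = simulate_trial(subject_model, HIGH_MEP, 123)
        for m in MUSCLES:
            assert np.array_equal(a.channels[m], b.channels[m])
        c = simulate_trial(subject_model, HIGH_MEP, 124)
        assert not np.array_equal(a.channels["TA"], c.channels["TA"])


class TestMepInsertion:
    def test_noise_free_p2p_equals_configured(self, quiet_model):
        """Generator <-> pipeline round trip with noise off and trial factor 1."""
        t = simulate_trial(quiet_model, HIGH_MEP, 0)
        for m in MUSCLES:
            measured = extract_mep_p2p(t, m) / quiet_model.mmax_p2p[m] * 100.0
            assert measured == pytest.approx(quiet_model.mep_mean_pct[(m, "High")], rel=1e-9)

    def test_mep_within_40ms_window(self, quiet_model):
        t = simulate_trial(quiet_model, HIGH_MEP, 0)
        fs = t.sample_rate
        tms_idx = round(t.tms_time * fs)
        x = t.channels["TA"]
        after = x[tms_idx + int(0.040 * fs) + 1 :]
        # nothing of the MEP leaks past 40 ms post-TMS (burst starts later)
        burst_start = round(t.perturbation_onset * fs) + int(0.060 * fs)
        assert np.all(after[: burst_start - (tms_idx + int(0.040 * fs) + 1)] == 0)

    def test_waveform_too_long_rejected(self, quiet_model):
        bad = copy.deepcopy(quiet_model)
        bad.mep_latency_ms["TA"] = 35.0  # 35 + 10 > 40
        with pytest.raises(ValueError):
            simulate_trial(bad, HIGH_MEP, 0)

    def test_trial_factor_lognormal_mean_one(self, subject_model):
        """Trial-level amplitude factors preserve the configured mean."""
        model = copy.deepcopy(subject_model)
        model.background_rms = {k: 0.0 for k in model.background_rms}
        p2ps = [
            extract_mep_p2p(simulate_trial(model, HIGH_MEP, s), "TA") for s in range(400)
        ]
        expected = model.mep_mean_pct[("TA", "High")] / 100 * model.mmax_p2p["TA"]
        mean = np.mean(p2ps)
        assert mean == pytest.approx(expected, rel=0.05)
        assert np.std(p2ps) / mean == pytest.approx(model.mep_cv, rel=0.25)


class TestBurst:
    def test_burst_raises_response_window_amplitude(self, subject_model):
        entry = ScheduleEntry(ConditionName.High, TrialKind.catch, "AnteriorLarge")
        t = simulate_trial(subject_model, entry, 3)
        fs = t.sample_rate
        onset = round(t.perturbation_onset * fs)
        bp = subject_model.burst_params[("TA", "AnteriorLarge", "predictable")]
        i0 = onset + int(bp.onset_ms * 1e-3 * fs)
        burst_rms = np.sqrt(np.mean(t.channels["TA"][i0 + 60 : i0 + 200] ** 2))
        pre_rms = np.sqrt(np.mean(t.channels["TA"][:4000] ** 2))
        assert burst_rms > 3 * pre_rms

    def test_alternating_carrier_rectifies_to_envelope(self, alternating_model):
        entry = ScheduleEntry(ConditionName.High, TrialKind.catch, "AnteriorLarge")
        t = simulate_trial(alternating_model, entry, 0)
        fs = t.sample_rate
        rms = alternating_model.background_rms["TA"]
        x = np.abs(t.channels["TA"])
        assert x[:4000] == pytest.approx(np.full(4000, rms))
        bp = alternating_model.burst_params[("TA", "AnteriorLarge", "predictable")]
        onset = round(t.perturbation_onset * fs)
        i0 = onset + int(round(bp.onset_ms * 1e-3 * fs))
        plateau = x[i0 + int(bp.rise_ms * 1e-3 * fs) + 4 : i0 + int((bp.duration_ms - bp.fall_ms) * 1e-3 * fs) - 4]
        assert plateau == pytest.approx(np.full(plateau.size, rms * bp.gain), rel=1e-9)

    def test_invalid_burst_params(self):
        with pytest.raises(ValueError):
            BurstParams(onset_ms=-5.0)
        with pytest.raises(ValueError):
            BurstParams(onset_ms=100.0, duration_ms=30.0, rise_ms=20.0, fall_ms=20.0)


class TestMmaxSweep:
    def test_noise_free_saturates_at_mmax(self, quiet_model):
        sweep = simulate_mmax_sweep(quiet_model, "TA", 0)
        p2ps = [extract_mep_p2p(t, "TA") for t in sweep]
        assert p2ps[-1] == pytest.approx(quiet_model.mmax_p2p["TA"], rel=1e-9)
        assert np.all(np.diff(p2ps) >= -1e-12)

    def test_estimate_recovers_mmax_under_noise(self, subject_model):
        errs = []
        for seed in range(100):
            sweep = simulate_mmax_sweep(subject_model, "TA", seed)
            est = estimate_mmax(sweep, "TA")
            errs.append(est / subject_model.mmax_p2p["TA"] - 1.0)
        assert np.max(np.abs(errs)) < 0.05

    def test_unknown_muscle(self, subject_model):
        with pytest.raises(KeyError):
            simulate_mmax_sweep(subject_model, "biceps", 0)


class TestCohort:
    def test_cohort_shape_and_count(self, population):
        cohort = simulate_cohort(population, 11, n_subjects=2)
        assert len(cohort) == 2
        for ds in cohort:
            assert len(ds.trials) == 75  # 5 conditions x 15 trials
            assert set(ds.mmax_sweeps) == set(MUSCLES)

    def test_expected_total_trials_at_default_size(self, population):
        # 12 subjects x 5 conditions x 15 trials; checked via schedule
        # arithmetic on a cheap kind-restricted synthesis
        cohort = simulate_cohort(
            population, 1, kinds=[], include_mmax=False, include_platform=False
        )
        assert len(cohort) == 12
        assert sum(len(ds.schedule.entries) for ds in cohort) == 900

    def test_zero_between_subject_sd_gives_identical_means(self, population):
        pop = copy.deepcopy(population)
        pop.mep_shared_cv = 0.0
        for m in pop.mep_between_sd:
            pop.mep_between_sd[m] = {c: 0.0 for c in pop.mep_between_sd[m]}
        cohort = simulate_cohort(pop, 5, n_subjects=3, kinds=[], include_mmax=False)
        base = cohort[0].model.mep_mean_pct
        for ds in cohort[1:]:
            for key, v in ds.model.mep_mean_pct.items():
                assert v == pytest.approx(base[key])

    def test_population_means_are_calibrated(self, population):
        """Cohort-level MEP targets: subject draws are mean-preserving."""
        targets = {"Low": 9.7, "High": 14.8, "Posterior": 7.3, "Random": 11.5}
        assert {c: population.mep_mean_pct["TA"][c] for c in targets} == targets
        draws = {c: [] for c in targets}
        root = np.random.SeedSequence(99)
        for sq in root.spawn(600):
            model = sample_subject(population, "s", sq)
            for c in targets:
                draws[c].append(model.mep_mean_pct[("TA", c)])
        for c, t in targets.items():
            assert np.mean(draws[c]) == pytest.approx(t, rel=0.08)

    def test_cohort_determinism(self, population):
        a = simulate_cohort(population, 21, n_subjects=1)
        b = simulate_cohort(population, 21, n_subjects=1)
        for ta, tb in zip(a[0].trials, b[0].trials):
            assert np.array_equal(ta.channels["TA"], tb.channels["TA"])

    def test_nonpositive_n_rejected(self, population):
        with pytest.raises(ValueError):
            simulate_cohort(population, 1, n_subjects=0)
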