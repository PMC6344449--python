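"""Synthetic EMG trial generator for the perturbation-with-TMS protocol.

Generates multi-channel surface-EMG recordings (TA, SOL, MG at 4 kHz) with the
statistical structure the analysis pipelines assume:

* stationary band-limited (15-1000 Hz) background noise with per-muscle RMS;
* a biphasic motor-evoked potential (MEP) time-locked to a TMS marker placed
  50 ms before perturbation onset, with a lognormal trial-to-trial amplitude
  factor and amplitude expressed in % of the muscle's maximal M-wave (M-max);
* perturbation-evoked long-latency bursts modelled as amplitude modulation of
  the background by a rise/plateau/fall envelope whose gain depends on
  muscle x perturbation x predictability;
* M-max calibration sweeps with a saturating recruitment curve;
* between-subject variability (lognormal on amplitudes, normal on latencies)
  for a 12-subject cohort.

Every random draw descends from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical configuration and seeds
reproduce a cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .protocol import (
    CONDITIONS,
    MUSCLES,
    PROFILES,
    TMS_LEAD_S,
    ConditionName,
    ScheduleEntry,
    TrialKind,
    TrialSchedule,
    make_schedule,
    platform_trajectory,
)

__all__ = [
    "BurstParams",
    "SubjectModel",
    "TrialRecording",
    "SubjectDataset",
    "PopulationConfig",
    "sample_subject",
    "simulate_trial",
    "simulate_mmax_sweep",
    "simulate_subject",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class BurstParams:
    """Long-latency burst for one (muscle, perturbation, predictability) cell.

    ``gain`` is the plateau amplitude of the modulation envelope in multiples
    of the background RMS; the envelope rises from 1 to ``gain`` over
    ``rise_ms``, holds, and falls back over ``fall_ms`` (total ``duration_ms``).
    """

    onset_ms: float
    duration_ms: float = 150.0
    gain: float = 2.0
    rise_ms: float = 10.0
    fall_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.onset_ms <= 0:
            raise ValueError("burst onset must be > 0 ms")
        if self.duration_ms < self.rise_ms + self.fall_ms:
            raise ValueError("burst duration shorter than rise + fall")


@dataclass
class SubjectModel:
    """Generator parameters for one subject."""

    subject_id: str
    sample_rate: float = 4000.0
    trial_duration_s: float = 3.0
    perturbation_onset_s: float = 1.5
    background_rms: dict[str, float] = field(default_factory=dict)  # volts
    mmax_p2p: dict[str, float] = field(default_factory=dict)  # volts
    #: (muscle, condition name) -> mean MEP amplitude in % M-max
    mep_mean_pct: dict[tuple[str, str], float] = field(default_factory=dict)
    mep_cv: float = 0.2  # lognormal trial-to-trial CV; 0 disables
    mep_latency_ms: dict[str, float] = field(default_factory=dict)
    mep_duration_ms: float = 10.0
    #: (muscle, perturbation label, predictability) -> burst; predictability in
    #: {"predictable", "unpredictable"}; absent keys mean no evoked burst
    burst_params: dict[tuple[str, str, str], BurstParams] = field(default_factory=dict)
    #: "noise": stochastic band-limited background; "alternating": a +/-RMS
    #: square carrier whose rectified trace is exactly RMS x envelope, used for
    #: closed-form round-trip checks
    carrier: str = "noise"
    rng_seed: int = 0

    def validate(self) -> None:
        for m in self.background_rms:
            if self.background_rms[m] < 0:
                raise ValueError("background RMS must be >= 0")
        for m, lat in self.mep_latency_ms.items():
            if lat + self.mep_duration_ms > 40.0 + 1e-9:
                raise ValueError(
                    f"MEP waveform for {m} ends {lat + self.mep_duration_ms:.1f} ms "
                    "post-TMS, outside the 40-ms peak-to-peak window"
                )
        for key, bp in self.burst_params.items():
            if bp.gain < 1.0:
                raise ValueError(f"burst gain below 1 for {key}")


@dataclass
class TrialRecording:
    """One trial: sampled channels (volts) plus event markers (seconds)."""

    subject_id: str
    condition: str
    kind: str  # "MEP", "catch" or "mmax"
    perturbation: str | None
    sample_rate: float
    channels: dict[str, np.ndarray]
    tms_time: float | None = None
    perturbation_onset: float | None = None
    platform_displacement: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def events(self) -> dict[str, float]:
        ev = {}
        if self.tms_time is not None:
            ev["tms"] = self.tms_time
        if self.perturbation_onset is not None:
            ev["perturbation"] = self.perturbation_onset
        return ev


@dataclass
class SubjectDataset:
    """All generated material for one subject."""

    model: SubjectModel
    schedule: TrialSchedule
    trials: list[TrialRecording]
    mmax_sweeps: dict[str, list[TrialRecording]]


# ---------------------------------------------------------------------------
# population configuration (cohort-level defaults)


def _ta_mep_means() -> dict[str, float]:
    # TA corticospinal presetting scales with predicted perturbation demand:
    # largest before a predictable large anterior translation, intermediate
    # when the perturbation is unpredictable, smallest in quiet standing.
    return {
        "NoPerturbation": 6.5,
        "Low": 9.7,
        "High": 14.8,
        "Posterior": 7.3,
        "Random": 11.5,
    }


def _flat(v: float) -> dict[str, float]:
    return {c.value: v for c in ConditionName}


@dataclass
class PopulationConfig:
    """Population-level generator parameters; subjects are drawn from these.

    Amplitude-like parameters vary between subjects as mean-one lognormal
    factors (a shared per-subject factor plus a condition-specific one);
    latencies vary as truncated normals.  All means are therefore preserved at
    the cohort level.
    """

    n_subjects: int = 12
    sample_rate: float = 4000.0
    trial_duration_s: float = 3.0
    perturbation_onset_s: float = 1.5
    # background activity: TA is nearly silent in quiet standing; the plantar
    # flexors carry postural tone
    background_rms: dict[str, float] = field(
        default_factory=lambda: {"TA": 8e-6, "SOL": 20e-6, "MG": 15e-6}
    )
    mmax_mean: dict[str, float] = field(
        default_factory=lambda: {"TA": 6e-3, "SOL": 8e-3, "MG": 8e-3}
    )
    mmax_between_cv: float = 0.2
    #: muscle -> condition -> mean MEP amplitude (% M-max)
    mep_mean_pct: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"TA": _ta_mep_means(), "SOL": _flat(4.0), "MG": _flat(3.5)}
    )
    #: muscle -> condition -> between-subject SD of the mean (% M-max)
    mep_between_sd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TA": {
                "NoPerturbation": 3.7,
                "Low": 5.5,
                "High": 8.0,
                "Posterior": 4.2,
                "Random": 6.6,
            },
            "SOL": _flat(2.0),
            "MG": _flat(1.75),
        }
    )
    #: lognormal CV of the per-subject factor shared across conditions
    mep_shared_cv: float = 0.4
    mep_trial_cv: float = 0.2
    mep_latency_ms: dict[str, float] = field(
        default_factory=lambda: {"TA": 28.0, "SOL": 30.0, "MG": 30.0}
    )
    mep_latency_between_sd: float = 1.0
    mep_duration_ms: float = 10.0
    #: muscle -> label -> burst onset latency mean (ms post perturbation onset)
    burst_onset_ms: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TA": {"AnteriorLarge": 114.4, "AnteriorSmall": 117.0, "PosteriorLarge": 122.0},
            "SOL": {"PosteriorLarge": 110.7, "AnteriorLarge": 116.0, "AnteriorSmall": 119.0},
            "MG": {"PosteriorLarge": 109.5, "AnteriorLarge": 116.0, "AnteriorSmall": 119.0},
        }
    )
    #: muscle -> label -> between-subject SD of burst onset (ms)
    burst_onset_sd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TA": {"AnteriorLarge": 7.0, "AnteriorSmall": 8.0, "PosteriorLarge": 8.0},
            "SOL": {"PosteriorLarge": 11.3, "AnteriorLarge": 8.0, "AnteriorSmall": 8.0},
            "MG": {"PosteriorLarge": 5.9, "AnteriorLarge": 8.0, "AnteriorSmall": 8.0},
        }
    )
    #: muscle -> label -> plateau gain (x background RMS) under predictability;
    #: direction-appropriate muscles respond strongly (TA to anterior
    #: translations, SOL/MG to the posterior one)
    burst_gain: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TA": {"AnteriorLarge": 8.0, "AnteriorSmall": 4.0, "PosteriorLarge": 1.8},
            "SOL": {"PosteriorLarge": 8.0, "AnteriorLarge": 2.5, "AnteriorSmall": 1.8},
            "MG": {"PosteriorLarge": 8.0, "AnteriorLarge": 2.5, "AnteriorSmall": 1.8},
        }
    )
    #: multiplier applied to the burst gain excess (gain - 1) when the
    #: perturbation is unpredictable (Random condition); the mismatch between
    #: preset corticospinal drive and the actual large anterior perturbation
    #: produces a larger TA response
    unpredictable_gain_multiplier: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"TA": {"AnteriorLarge": 1.3}}
    )
    burst_duration_ms: float = 150.0
    burst_rise_ms: float = 10.0
    burst_fall_ms: float = 40.0
    #: lognormal CVs on burst gain excess: shared per muscle, and per cell
    burst_shared_cv: float = 0.3
    burst_cell_cv: float = 0.1
    mmax_sweep_fractions: tuple[float, ...] = (
        0.10, 0.22, 0.38, 0.56, 0.72, 0.85, 0.94, 1.0, 1.0, 1.0,
    )
    carrier: str = "noise"


# ---------------------------------------------------------------------------
# subject sampling


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Mean-one lognormal factor with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _residual_cv(total_cv: float, shared_cv: float) -> float:
    """CV of the independent factor so the product of two mean-one lognormals
    has total CV ``total_cv`` given a shared factor CV ``shared_cv``."""
    num = (1.0 + total_cv**2) / (1.0 + shared_cv**2) - 1.0
    return math.sqrt(num) if num > 0 else 0.0


def sample_subject(
    population: PopulationConfig, subject_id: str, seed_seq: np.random.SeedSequence
) -> SubjectModel:
    """Draw one subject's generator parameters from the population."""
    param_seed, trial_seed = seed_seq.spawn(2)
    rng = np.random.default_rng(param_seed)

    mmax = {
        m: population.mmax_mean[m] * _lognormal_factor(rng, population.mmax_between_cv)
        for m in MUSCLES
    }
    mep_mean: dict[tuple[str, str], float] = {}
    for m in MUSCLES:
        shared = _lognormal_factor(rng, population.mep_shared_cv)
        for cond, mu in population.mep_mean_pct[m].items():
            total_cv = population.mep_between_sd[m][cond] / mu if mu > 0 else 0.0
            res = _lognormal_factor(rng, _residual_cv(total_cv, population.mep_shared_cv))
            mep_mean[(m, cond)] = mu * shared * res

    lat = {}
    for m in MUSCLES:
        draw = rng.normal(population.mep_latency_ms[m], population.mep_latency_between_sd)
        lat[m] = float(np.clip(draw, 20.0, 40.0 - population.mep_duration_ms))

    bursts: dict[tuple[str, str, str], BurstParams] = {}
    for m in MUSCLES:
        shared = _lognormal_factor(rng, population.burst_shared_cv)
        for label, gain in population.burst_gain[m].items():
            onset_mu = population.burst_onset_ms[m][label]
            onset_sd = population.burst_onset_sd[m][label]
            onset = rng.normal(onset_mu, onset_sd)
            # symmetric truncation keeps the population mean; floor at 60 ms
            onset = float(np.clip(onset, max(60.0, onset_mu - 2 * onset_sd), onset_mu + 2 * onset_sd))
            for pred in ("predictable", "unpredictable"):
                mult = 1.0
                if pred == "unpredictable":
                    mult = population.unpredictable_gain_multiplier.get(m, {}).get(label, 1.0)
                cell = _lognormal_factor(rng, population.burst_cell_cv)
                g = 1.0 + (gain - 1.0) * mult * shared * cell
                bursts[(m, label, pred)] = BurstParams(
                    onset_ms=onset,
                    duration_ms=population.burst_duration_ms,
                    gain=g,
                    rise_ms=population.burst_rise_ms,
                    fall_ms=population.burst_fall_ms,
                )

    model = SubjectModel(
        subject_id=subject_id,
        sample_rate=population.sample_rate,
        trial_duration_s=population.trial_duration_s,
        perturbation_onset_s=population.perturbation_onset_s,
        background_rms=dict(population.background_rms),
        mmax_p2p=mmax,
        mep_mean_pct=mep_mean,
        mep_cv=population.mep_trial_cv,
        mep_latency_ms=lat,
        mep_duration_ms=population.mep_duration_ms,
        burst_params=bursts,
        carrier=population.carrier,
        rng_seed=int(trial_seed.generate_state(1)[0] % (2**31)),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# waveform pieces


_BAND = (15.0, 1000.0)
_MASK_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _band_mask(n: int, fs: float) -> np.ndarray:
    """Amplitude mask for strictly band-limited (15-1000 Hz) noise synthesis.

    Unity inside the band with raised-cosine tapers over 15-20 Hz and
    950-1000 Hz (transitions lie inside the band, so power outside it is
    exactly zero)."""
    key = (n, fs)
    if key not in _MASK_CACHE:
        f = np.fft.rfftfreq(n, 1.0 / fs)
        lo, lo_top, hi_bot, hi = _BAND[0], 20.0, 950.0, _BAND[1]
        mask = np.zeros_like(f)
        mask[(f >= lo_top) & (f <= hi_bot)] = 1.0
        rise = (f >= lo) & (f < lo_top)
        mask[rise] = 0.5 * (1 - np.cos(np.pi * (f[rise] - lo) / (lo_top - lo)))
        fall = (f > hi_bot) & (f <= hi)
        mask[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi_bot) / (hi - hi_bot)))
        _MASK_CACHE[key] = mask
    return _MASK_CACHE[key]


def _background(
    rng: np.random.Generator, rms: dict[str, float], n: int, fs: float, carrier: str
) -> dict[str, np.ndarray]:
    """Per-muscle stationary background traces with exact target RMS.

    Gaussian noise is synthesized in the frequency domain under the band mask
    (independent complex coefficients per bin), giving a flat in-band spectrum
    and zero out-of-band power; the DC bin is zero, so each trace is exactly
    zero-mean."""
    out: dict[str, np.ndarray] = {}
    if carrier == "alternating":
        base = np.tile([1.0, -1.0], (n + 1) // 2)[:n]
        for m, r in rms.items():
            out[m] = r * base
        return out
    mask = _band_mask(n, fs)
    nf = mask.size
    coeff = rng.standard_normal((len(rms), nf)) + 1j * rng.standard_normal((len(rms), nf))
    x = np.fft.irfft(coeff * mask, n=n, axis=-1)
    for i, (m, r) in enumerate(rms.items()):
        cur = np.sqrt(np.mean(x[i] * x[i]))
        out[m] = x[i] * (r / cur) if cur > 0 and r > 0 else np.zeros(n)
    return out


def _mep_waveform(fs: float, duration_ms: float, p2p: float) -> np.ndarray:
    """Biphasic Gaussian-windowed sinusoid with exact sampled peak-to-peak ``p2p``."""
    n = max(int(round(duration_ms * 1e-3 * fs)), 4)
    tau = (np.arange(n) + 0.5) / n
    w = np.sin(2 * np.pi * tau) * np.exp(-0.5 * ((tau - 0.5) / 0.18) ** 2)
    return w * (p2p / (w.max() - w.min()))


def _burst_envelope(n: int, fs: float, onset_idx: int, bp: BurstParams) -> np.ndarray:
    """Multiplicative envelope: 1 outside the burst, rising to ``gain`` inside."""
    env = np.ones(n)
    n_rise = int(round(bp.rise_ms * 1e-3 * fs))
    n_fall = int(round(bp.fall_ms * 1e-3 * fs))
    n_total = int(round(bp.duration_ms * 1e-3 * fs))
    n_plateau = n_total - n_rise - n_fall
    shape = np.concatenate(
        [
            0.5 * (1 - np.cos(np.pi * np.arange(1, n_rise + 1) / n_rise)),
            np.ones(n_plateau),
            0.5 * (1 + np.cos(np.pi * np.arange(1, n_fall + 1) / n_fall)),
        ]
    )
    i0 = max(onset_idx, 0)
    seg = shape[: max(0, min(n_total, n - i0))]
    env[i0 : i0 + seg.size] += (bp.gain - 1.0) * seg
    return env


# ---------------------------------------------------------------------------
# trial simulation


def simulate_trial(
    model: SubjectModel,
    entry: ScheduleEntry,
    trial_seed: int | np.random.SeedSequence,
    include_platform: bool = True,
) -> TrialRecording:
    """Synthesize one trial of the schedule for a subject.

    MEP trials receive a TMS marker 50 ms (to the nearest sample) before the
    perturbation onset and a biphasic MEP whose noise-free peak-to-peak equals
    ``mep_mean_pct/100 * mmax_p2p`` times a mean-one lognormal trial factor
    with CV ``mep_cv``.  Perturbed trials receive the configured long-latency
    burst in each muscle with an entry in ``burst_params``.
    """
    model.validate()
    fs = model.sample_rate
    n = int(round(model.trial_duration_s * fs))
    rng = np.random.default_rng(trial_seed)

    channels = _background(rng, model.background_rms, n, fs, model.carrier)

    cond = CONDITIONS[ConditionName(entry.condition)]
    perturbed = entry.perturbation is not None
    onset_idx = int(round(model.perturbation_onset_s * fs))
    tms_lead_n = int(round(TMS_LEAD_S * fs))
    tms_idx = onset_idx - tms_lead_n

    pert_onset = model.perturbation_onset_s if perturbed else None
    tms_time = None
    if entry.kind is TrialKind.MEP:
        # TMS is delivered in NoPerturbation MEP trials at the same clock time
        tms_time = tms_idx / fs

    # perturbation-evoked bursts (any trial kind)
    if perturbed:
        pred = "predictable" if cond.predictable else "unpredictable"
        for m in channels:
            bp = model.burst_params.get((m, entry.perturbation, pred))
            if bp is not None:
                b0 = onset_idx + int(round(bp.onset_ms * 1e-3 * fs))
                channels[m] = channels[m] * _burst_envelope(n, fs, b0, bp)

    # MEP waveforms
    if entry.kind is TrialKind.MEP:
        factor = _lognormal_factor(rng, model.mep_cv)
        for m in channels:
            pct = model.mep_mean_pct.get((m, entry.condition))
            if pct is None:
                continue
            p2p = pct / 100.0 * model.mmax_p2p[m] * factor
            w = _mep_waveform(fs, model.mep_duration_ms, p2p)
            i0 = tms_idx + int(round(model.mep_latency_ms[m] * 1e-3 * fs))
            channels[m][i0 : i0 + w.size] += w

    platform = None
    if include_platform:
        platform = np.zeros(n)
        if perturbed:
            traj = platform_trajectory(PROFILES[entry.perturbation], fs)
            seg = traj[: n - onset_idx]
            platform[onset_idx : onset_idx + seg.size] = seg
            platform[onset_idx + seg.size :] = seg[-1] if seg.size else 0.0

    return TrialRecording(
        subject_id=model.subject_id,
        condition=entry.condition.value if isinstance(entry.condition, ConditionName) else entry.condition,
        kind=entry.kind.value if isinstance(entry.kind, TrialKind) else entry.kind,
        perturbation=entry.perturbation,
        sample_rate=fs,
        channels=channels,
        tms_time=tms_time,
        perturbation_onset=pert_onset,
        platform_displacement=platform,
    )


def simulate_mmax_sweep(
    model: SubjectModel,
    muscle: str,
    seed: int | np.random.SeedSequence,
    fractions: tuple[float, ...] = (0.10, 0.22, 0.38, 0.56, 0.72, 0.85, 0.94, 1.0, 1.0, 1.0),
) -> list[TrialRecording]:
    """M-max calibration sweep: M-wave trials with saturating recruitment.

    Stimulus intensity increases across trials; the evoked M-wave peak-to-peak
    follows ``fractions x mmax_p2p`` and saturates at the full M-max.  Trials
    are short (0.2 s) with the stimulus marker stored in ``tms_time``.
    """
    if muscle not in model.background_rms:
        raise KeyError(f"unknown muscle {muscle!r}")
    fs = model.sample_rate
    n = int(round(0.2 * fs))
    stim_idx = int(round(0.05 * fs))
    rng = np.random.default_rng(seed)
    trials = []
    for frac in fractions:
        bg = _background(rng, {muscle: model.background_rms[muscle]}, n, fs, model.carrier)
        x = bg[muscle]
        w = _mep_waveform(fs, model.mep_duration_ms, frac * model.mmax_p2p[muscle])
        i0 = stim_idx + int(round(0.006 * fs))  # ~6 ms peripheral conduction
        x[i0 : i0 + w.size] += w
        trials.append(
            TrialRecording(
                subject_id=model.subject_id,
                condition="Mmax",
                kind="mmax",
                perturbation=None,
                sample_rate=fs,
                channels={muscle: x},
                tms_time=stim_idx / fs,
            )
        )
    return trials


def simulate_subject(
    population: PopulationConfig,
    subject_id: str,
    seed_seq: np.random.SeedSequence,
    conditions: list[ConditionName] | None = None,
    kinds: list[TrialKind] | None = None,
    include_platform: bool = True,
    include_mmax: bool = True,
) -> SubjectDataset:
    """Generate one subject: model draw, schedule, trials, M-max sweeps.

    ``conditions``/``kinds`` restrict synthesis to a subset of the schedule
    (the schedule itself is unchanged), which downstream recovery experiments
    use to avoid synthesizing trials they do not read.
    """
    model_seq, sched_seq, trial_seq, mmax_seq = seed_seq.spawn(4)
    model = sample_subject(population, subject_id, model_seq)
    s1, s2 = sched_seq.generate_state(2) % (2**31)
    schedule = make_schedule(int(s1), int(s2))

    trial_seeds = trial_seq.spawn(len(schedule.entries))
    trials = []
    for entry, ts in zip(schedule.entries, trial_seeds):
        if conditions is not None and entry.condition not in conditions:
            continue
        if kinds is not None and entry.kind not in kinds:
            continue
        trials.append(simulate_trial(model, entry, ts, include_platform=include_platform))

    sweeps: dict[str, list[TrialRecording]] = {}
    if include_mmax:
        for m, sq in zip(MUSCLES, mmax_seq.spawn(len(MUSCLES))):
            sweeps[m] = simulate_mmax_sweep(model, m, sq, population.mmax_sweep_fractions)
    return SubjectDataset(model=model, schedule=schedule, trials=trials, mmax_sweeps=sweeps)


def simulate_cohort(
    population: PopulationConfig,
    cohort_seed: int,
    n_subjects: int | None = None,
    **kwargs,
) -> list[SubjectDataset]:
    """Generate a cohort of subjects; fully reproducible under ``cohort_seed``."""
    n = population.n_subjects if n_subjects is None else n_subjects
    if n < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(int(cohort_seed))
    out = []
    for i, sq in enumerate(root.spawn(n)):
        out.append(simulate_subject(population, f"sub-{i + 1:02d}", sq, **kwargs))
    return out
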