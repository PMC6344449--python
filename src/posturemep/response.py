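"""Perturbation-evoked EMG responses in catch trials.

Rectified-demeaned catch-trial channels are ensemble-averaged per condition
(aligned on perturbation onset).  Amplitudes are normalized by the mean of the
muscle-appropriate reference ensemble over the 250 ms after onset (TA -> High
condition, SOL/MG -> Posterior condition).  Response onset is the first time
the ensemble trace exceeds its pre-perturbation mean + 2 SD for a sustained
10 ms; the integrated EMG (iEMG) is the time integral of each trial's
normalized rectified trace over 100 ms from the reference-condition ensemble
onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import rectify_demean
from .synth import SubjectDataset, TrialRecording

__all__ = [
    "REFERENCE_CONDITION",
    "Ensemble",
    "ResponseMeasurement",
    "ensemble_average",
    "normalize_reference",
    "detect_onset",
    "integrate_iemg",
    "compare_predictability",
    "response_tables",
]

#: reference condition per muscle for amplitude normalization and iEMG onset
REFERENCE_CONDITION = {"TA": "High", "SOL": "Posterior", "MG": "Posterior"}

REFERENCE_WINDOW_MS = 250.0
BGA_WINDOW_MS = 100.0
HOLD_MS = 10.0
SEARCH_MS = 300.0
IEMG_WINDOW_MS = 100.0


@dataclass
class Ensemble:
    """Event-aligned ensemble average: ``series[onset_idx]`` is perturbation onset."""

    series: np.ndarray
    sample_rate: float
    onset_idx: int
    n_trials: int


@dataclass
class ResponseMeasurement:
    subject_id: str
    muscle: str
    condition: str  # condition name; Random trials keep "Random"
    perturbation: str  # profile label
    predictability: str  # "predictable" | "unpredictable"
    onset_latency_ms: float | None  # ensemble onset of this muscle's reference
    iemg_norm: float
    bga_ref: float  # volts, ensemble pre-perturbation rectified mean


def ensemble_average(trials: list[TrialRecording], muscle: str) -> Ensemble:
    """Pointwise mean of rectified-demeaned channels aligned on perturbation onset."""
    if not trials:
        raise ValueError("need at least one trial")
    fs = trials[0].sample_rate
    if any(t.sample_rate != fs for t in trials):
        raise ValueError("mixed sample rates")
    if any(t.perturbation_onset is None for t in trials):
        raise ValueError("all trials must have a perturbation onset")
    onset_idx = [int(round(t.perturbation_onset * t.sample_rate)) for t in trials]
    pre = min(onset_idx)
    post = min(t.n_samples - i for t, i in zip(trials, onset_idx))
    stack = np.stack(
        [rectify_demean(t.channels[muscle])[i - pre : i + post] for t, i in zip(trials, onset_idx)]
    )
    return Ensemble(stack.mean(axis=0), fs, pre, len(trials))


def reference_mean(ens: Ensemble, window_ms: float = REFERENCE_WINDOW_MS) -> float:
    """Mean rectified amplitude over [onset, onset + window_ms)."""
    i0 = ens.onset_idx
    i1 = i0 + int(round(window_ms * 1e-3 * ens.sample_rate))
    if i1 > ens.series.size:
        raise ValueError("reference window extends past end of ensemble")
    return float(ens.series[i0:i1].mean())


def normalize_reference(series: np.ndarray, ref_mean: float) -> np.ndarray:
    """Divide an amplitude trace by the reference-window mean amplitude."""
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return np.asarray(series, dtype=float) / ref_mean


def detect_onset(
    ens: Ensemble,
    bga_window_ms: float = BGA_WINDOW_MS,
    hold_ms: float = HOLD_MS,
    search_ms: float = SEARCH_MS,
) -> float | None:
    """Burst onset latency (ms after perturbation onset) of an ensemble trace.

    Threshold is mean + 2 SD of the rectified trace over the ``bga_window_ms``
    immediately before onset; the latency is the first time from which the
    trace stays above threshold for ``hold_ms``.  Returns ``None`` when no
    sustained crossing occurs within ``search_ms``.
    """
    fs = ens.sample_rate
    x = ens.series
    n_bga = int(round(bga_window_ms * 1e-3 * fs))
    i_on = ens.onset_idx
    if i_on - n_bga < 0:
        raise ValueError("BGA window precedes start of trace")
    bga = x[i_on - n_bga : i_on]
    thr = bga.mean() + 2.0 * bga.std(ddof=1)
    n_hold = int(round(hold_ms * 1e-3 * fs))
    n_search = min(int(round(search_ms * 1e-3 * fs)), x.size - i_on)
    above = (x[i_on : i_on + n_search] > thr).astype(np.int64)
    if above.size < n_hold:
        return None
    csum = np.concatenate([[0], np.cumsum(above)])
    runs = csum[n_hold:] - csum[:-n_hold]  # count of supra-threshold samples per window
    hits = np.nonzero(runs == n_hold)[0]
    if hits.size == 0:
        return None
    return float(hits[0] / fs * 1e3)


def integrate_iemg(
    series_norm: np.ndarray,
    sample_rate: float,
    onset_idx: int,
    onset_latency_ms: float,
    window_ms: float = IEMG_WINDOW_MS,
) -> float:
    """Trapezoidal integral (s x normalized units) over 100 ms from response onset."""
    i0 = onset_idx + int(round(onset_latency_ms * 1e-3 * sample_rate))
    i1 = i0 + int(round(window_ms * 1e-3 * sample_rate))
    if i0 < 0 or i1 + 1 > series_norm.size:
        raise ValueError("iEMG window exceeds trace")
    return float(np.trapezoid(series_norm[i0 : i1 + 1], dx=1.0 / sample_rate))


def compare_predictability(measurements: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-muscle 2x3 (predictability x perturbation) iEMG cell-mean tables.

    Input rows are per-trial ``ResponseMeasurement`` records; output cell means
    average within subject first, then across subjects, and feed the two-way
    repeated-measures ANOVA.
    """
    out = {}
    for muscle, grp in measurements.groupby("muscle"):
        subj = (
            grp.groupby(["predictability", "perturbation", "subject_id"])["iemg_norm"]
            .mean()
            .reset_index()
        )
        cells = subj.pivot_table(
            index="predictability", columns="perturbation", values="iemg_norm"
        )
        if cells.isna().any().any() or cells.shape != (2, 3):
            raise ValueError(f"missing predictability x perturbation cell for {muscle}")
        out[muscle] = cells
    return out


def response_tables(
    dataset: SubjectDataset,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the response pipeline for one subject.

    Returns ``(trials, onsets)``: per-trial normalized iEMG rows for every
    perturbed catch trial, and per condition x muscle ensemble onset
    latencies.  iEMG integration uses, for each muscle, the ensemble onset of
    that muscle's reference condition (TA -> High, SOL/MG -> Posterior).
    """
    catch = [
        t for t in dataset.trials if t.kind == "catch" and t.perturbation is not None
    ]
    if not catch:
        raise ValueError("dataset has no perturbed catch trials")
    by_cond: dict[str, list[TrialRecording]] = {}
    for t in catch:
        by_cond.setdefault(t.condition, []).append(t)

    sid = dataset.model.subject_id
    onset_rows = []
    trial_rows = []
    for muscle in dataset.model.background_rms:
        ensembles = {c: ensemble_average(ts, muscle) for c, ts in by_cond.items()}
        onsets = {c: detect_onset(e) for c, e in ensembles.items()}
        for c, e in ensembles.items():
            onset_rows.append(
                {
                    "subject_id": sid,
                    "muscle": muscle,
                    "condition": c,
                    "onset_latency_ms": onsets[c],
                    "n_trials": e.n_trials,
                }
            )
        ref_cond = REFERENCE_CONDITION[muscle]
        if ref_cond not in ensembles:
            continue  # reference condition absent: no normalized iEMG
        ref = reference_mean(ensembles[ref_cond])
        ref_onset = onsets[ref_cond]
        if ref_onset is None:
            continue
        for t in catch:
            pred = "predictable" if t.condition != "Random" else "unpredictable"
            x = normalize_reference(rectify_demean(t.channels[muscle]), ref)
            onset_idx = int(round(t.perturbation_onset * t.sample_rate))
            iemg = integrate_iemg(x, t.sample_rate, onset_idx, ref_onset)
            n_bga = int(round(BGA_WINDOW_MS * 1e-3 * t.sample_rate))
            bga_ref = float(
                rectify_demean(t.channels[muscle])[onset_idx - n_bga : onset_idx].mean()
            )
            trial_rows.append(
                ResponseMeasurement(
                    subject_id=sid,
                    muscle=muscle,
                    condition=t.condition,
                    perturbation=t.perturbation,
                    predictability=pred,
                    onset_latency_ms=ref_onset,
                    iemg_norm=iemg,
                    bga_ref=bga_ref,
                )
            )
    trials_df = pd.DataFrame([vars(r) for r in trial_rows])
    onsets_df = pd.DataFrame(onset_rows)
    return trials_df, onsets_df
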