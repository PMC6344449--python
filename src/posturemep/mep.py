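"""MEP quantification: peak-to-peak extraction, M-max estimation, trial
exclusion (background-activity and interquartile rules) and per-condition
summaries.

Per trial, the MEP is the peak-to-peak amplitude within 40 ms after the TMS
pulse; background EMG activity (BGA) is the RMS over the 50 ms preceding the
pulse.  Within each subject x condition x muscle cell, trials whose BGA
exceeds the cell mean + 2 SD are discarded, then peak-to-peak outliers beyond
1.5 x IQR from the quartiles are discarded, and the surviving amplitudes are
normalized by the muscle's M-max and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import WindowSpec, window_rms
from .synth import SubjectDataset, TrialRecording

__all__ = [
    "MEPMeasurement",
    "ConditionSummary",
    "extract_mep_p2p",
    "estimate_mmax",
    "exclude_high_bga",
    "iqr_outlier_filter",
    "measure_trials",
    "summarize_condition",
    "mep_tables",
]

MEP_WINDOW_MS = 40.0
BGA_WINDOW_MS = 50.0

#: BGA window: the 50 ms immediately preceding the TMS pulse
BGA_WINDOW = WindowSpec("tms", -BGA_WINDOW_MS, 0.0)


@dataclass
class MEPMeasurement:
    subject_id: str
    condition: str
    muscle: str
    p2p_raw: float  # volts
    bga_rms: float  # volts
    p2p_norm: float | None = None  # % M-max, filled at summary time
    excluded_bga: bool = False
    outlier: bool = False

    @property
    def used(self) -> bool:
        return not (self.excluded_bga or self.outlier)


@dataclass
class ConditionSummary:
    subject_id: str
    condition: str
    muscle: str
    n_used: int
    mean_p2p_norm: float  # NaN when no trial survives
    mean_bga: float


def extract_mep_p2p(trial: TrialRecording, muscle: str) -> float:
    """Peak-to-peak amplitude (V) in the half-open window (tms, tms + 40 ms]."""
    if trial.tms_time is None:
        raise ValueError("trial has no TMS marker (catch trial?)")
    fs = trial.sample_rate
    x = trial.channels[muscle]
    tms_idx = int(round(trial.tms_time * fs))
    i0 = tms_idx + 1
    i1 = tms_idx + int(round(MEP_WINDOW_MS * 1e-3 * fs)) + 1
    if i1 > x.size:
        raise ValueError("MEP window extends past end of recording")
    seg = x[i0:i1]
    return float(seg.max() - seg.min())


def estimate_mmax(sweep: list[TrialRecording], muscle: str, k: int = 3) -> float:
    """Plateau M-wave amplitude: mean of the top-``k`` peak-to-peak values."""
    if len(sweep) < k:
        raise ValueError(f"need at least {k} sweep trials, got {len(sweep)}")
    p2ps = np.array([extract_mep_p2p(t, muscle) for t in sweep])
    top = np.sort(p2ps)[-k:]
    return float(top.mean())


def exclude_high_bga(measurements: list[MEPMeasurement]) -> list[MEPMeasurement]:
    """Flag trials whose BGA RMS exceeds mean + 2 SD of all trials in the cell.

    The threshold is computed once from all trials (sample SD, n-1); flags are
    set in place and the list is returned for chaining.
    """
    if len(measurements) < 2:
        raise ValueError("need at least 2 trials for the BGA rule")
    bga = np.array([m.bga_rms for m in measurements])
    thr = bga.mean() + 2.0 * bga.std(ddof=1)
    for m in measurements:
        m.excluded_bga = bool(m.bga_rms > thr)
    return measurements


def _tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    """Tukey hinges: medians of the lower/upper halves (median included when n odd)."""
    s = np.sort(x)
    n = s.size
    half = (n + 1) // 2
    return float(np.median(s[:half])), float(np.median(s[-half:]))


def iqr_outlier_filter(values: np.ndarray, method: str = "tukey") -> np.ndarray:
    """Boolean flags for values beyond 1.5 x IQR outside the quartiles.

    ``method``: "tukey" (hinge quartiles, default) or "linear"
    (linear-interpolation percentiles).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for the IQR rule")
    if method == "tukey":
        q1, q3 = _tukey_hinges(x)
    elif method == "linear":
        q1, q3 = np.percentile(x, [25, 75])
    else:
        raise ValueError(f"unknown quartile method {method!r}")
    iqr = q3 - q1
    return (x > q3 + 1.5 * iqr) | (x < q1 - 1.5 * iqr)


def measure_trials(
    trials: list[TrialRecording], muscle: str
) -> list[MEPMeasurement]:
    """Per-trial raw measurements (peak-to-peak and BGA) for MEP trials."""
    out = []
    for t in trials:
        out.append(
            MEPMeasurement(
                subject_id=t.subject_id,
                condition=t.condition,
                muscle=muscle,
                p2p_raw=extract_mep_p2p(t, muscle),
                bga_rms=window_rms(t.channels[muscle], t.sample_rate, BGA_WINDOW, t.events()),
            )
        )
    return out


def summarize_condition(
    measurements: list[MEPMeasurement],
    mmax: float,
    quartile_method: str = "tukey",
) -> ConditionSummary:
    """Apply the exclusion cascade and average the surviving normalized MEPs.

    Filter order is fixed: (1) BGA exclusion over all trials, (2) IQR outlier
    rejection on the survivors' raw peak-to-peak values (skipped when fewer
    than 4 survive, since quartiles are then undefined), (3) M-max
    normalization, (4) mean.  A cell with no survivors yields ``n_used = 0``
    and NaN means.
    """
    if mmax <= 0:
        raise ValueError("M-max must be positive")
    exclude_high_bga(measurements)
    survivors = [m for m in measurements if not m.excluded_bga]
    if len(survivors) >= 4:
        flags = iqr_outlier_filter(np.array([m.p2p_raw for m in survivors]), quartile_method)
        for m, f in zip(survivors, flags):
            m.outlier = bool(f)
    for m in measurements:
        m.p2p_norm = 100.0 * m.p2p_raw / mmax
    used = [m for m in measurements if m.used]
    first = measurements[0]
    return ConditionSummary(
        subject_id=first.subject_id,
        condition=first.condition,
        muscle=first.muscle,
        n_used=len(used),
        mean_p2p_norm=float(np.mean([m.p2p_norm for m in used])) if used else float("nan"),
        mean_bga=float(np.mean([m.bga_rms for m in used])) if used else float("nan"),
    )


def mep_tables(
    dataset: SubjectDataset,
    quartile_method: str = "tukey",
    mmax_override: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full MEP pipeline for one subject.

    Returns ``(trials, summaries)`` DataFrames: one row per MEP trial x muscle
    with measurements and exclusion flags, and one row per condition x muscle
    with the surviving-trial means.  M-max is estimated from the subject's
    calibration sweeps unless ``mmax_override`` provides values.
    """
    mmax = dict(mmax_override) if mmax_override else {
        m: estimate_mmax(sweep, m) for m, sweep in dataset.mmax_sweeps.items()
    }
    trial_rows = []
    summary_rows = []
    mep_trials = [t for t in dataset.trials if t.kind == "MEP"]
    conditions = sorted({t.condition for t in mep_trials})
    for muscle in dataset.model.background_rms:
        for cond in conditions:
            cell = [t for t in mep_trials if t.condition == cond]
            ms = measure_trials(cell, muscle)
            summ = summarize_condition(ms, mmax[muscle], quartile_method)
            summary_rows.append(vars(summ))
            trial_rows.extend(vars(m) for m in ms)
    trials_df = pd.DataFrame(trial_rows)
    summaries_df = pd.DataFrame(summary_rows)
    return trials_df, summaries_df
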