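"""End-to-end orchestration: generation -> MEP & response pipelines -> statistics.

``run_all`` drives a complete reproducible run from a :class:`RunConfig`:
simulate (or load) a cohort, quantify MEPs and perturbation responses, run the
repeated-measures battery, and write delimited tables plus a human-readable
report of group means +/- SE.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import read_dataset, write_dataset
from .mep import mep_tables
from .response import response_tables
from .rmstats import bonferroni_pairwise, rm_anova_oneway, rm_anova_twoway
from .synth import SubjectDataset, simulate_cohort

__all__ = [
    "run_mep",
    "run_response",
    "predictability_array",
    "run_stats",
    "run_all",
]

CONDITION_ORDER = ["NoPerturbation", "Low", "High", "Posterior", "Random"]
PERTURBATION_ORDER = ["AnteriorLarge", "AnteriorSmall", "PosteriorLarge"]


def run_mep(datasets: list[SubjectDataset], config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MEP pipeline over a cohort; returns per-trial and per-condition tables."""
    trials, summaries = [], []
    for ds in datasets:
        t, s = mep_tables(ds, quartile_method=config.pipeline.quartile_method)
        trials.append(t)
        summaries.append(s)
    return pd.concat(trials, ignore_index=True), pd.concat(summaries, ignore_index=True)


def run_response(datasets: list[SubjectDataset]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Response pipeline over a cohort; returns per-trial iEMG and ensemble onsets."""
    trials, onsets = [], []
    for ds in datasets:
        t, o = response_tables(ds)
        trials.append(t)
        onsets.append(o)
    return pd.concat(trials, ignore_index=True), pd.concat(onsets, ignore_index=True)


def predictability_array(response_trials: pd.DataFrame, muscle: str) -> np.ndarray:
    """Subjects x predictability x perturbation iEMG means for the two-way ANOVA."""
    grp = response_trials[response_trials["muscle"] == muscle]
    cell = (
        grp.groupby(["subject_id", "predictability", "perturbation"])["iemg_norm"]
        .mean()
        .unstack(["predictability", "perturbation"])
    )
    subjects = sorted(cell.index)
    arr = np.empty((len(subjects), 2, 3))
    for i, sid in enumerate(subjects):
        for j, pred in enumerate(["predictable", "unpredictable"]):
            for l, lab in enumerate(PERTURBATION_ORDER):
                arr[i, j, l] = cell.loc[sid, (pred, lab)]
    if np.isnan(arr).any():
        raise ValueError(f"missing predictability x perturbation cell for {muscle}")
    return arr


def _anova_row(muscle: str, outcome: str, res) -> dict:
    d = dataclasses.asdict(res)
    d.update({"muscle": muscle, "outcome": outcome})
    return d


def run_stats(
    mep_summaries: pd.DataFrame,
    response_trials: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The repeated-measures battery.

    Per muscle: one-way RM-ANOVAs across the five conditions on the mean
    normalized MEP and on the BGA; a one-way across the three predictable
    perturbed conditions on the iEMG; a two-way predictability x perturbation
    RM-ANOVA on the iEMG; Bonferroni-corrected pairwise post hocs for the MEP.
    """
    policy = config.stats.sphericity_policy
    m_alpha = config.stats.mauchly_alpha
    anova_rows, pairwise_rows = [], []
    for muscle in sorted(mep_summaries["muscle"].unique()):
        sub = mep_summaries[mep_summaries["muscle"] == muscle]
        for outcome, col in [("MEP", "mean_p2p_norm"), ("BGA", "mean_bga")]:
            wide = sub.pivot(index="subject_id", columns="condition", values=col)
            wide = wide[CONDITION_ORDER].dropna()
            res = rm_anova_oneway(wide.to_numpy(), policy, m_alpha)
            anova_rows.append(_anova_row(muscle, outcome, res))
            if outcome == "MEP":
                for pc in bonferroni_pairwise(
                    wide.to_numpy(), CONDITION_ORDER, config.stats.alpha
                ):
                    row = dataclasses.asdict(pc)
                    row.update({"muscle": muscle, "outcome": outcome})
                    pairwise_rows.append(row)
        if not response_trials.empty:
            resp = response_trials[
                (response_trials["muscle"] == muscle)
                & (response_trials["predictability"] == "predictable")
            ]
            wide = (
                resp.groupby(["subject_id", "condition"])["iemg_norm"]
                .mean()
                .unstack("condition")[["Low", "High", "Posterior"]]
                .dropna()
            )
            res = rm_anova_oneway(wide.to_numpy(), policy, m_alpha)
            anova_rows.append(_anova_row(muscle, "iEMG", res))
            arr = predictability_array(response_trials, muscle)
            for res in rm_anova_twoway(arr, ("predictability", "perturbation"), policy, m_alpha):
                anova_rows.append(_anova_row(muscle, "iEMG 2-way", res))
    return pd.DataFrame(anova_rows), pd.DataFrame(pairwise_rows)


def _report(
    mep_summaries: pd.DataFrame,
    response_trials: pd.DataFrame,
    mep_trials: pd.DataFrame,
    anova: pd.DataFrame,
) -> str:
    lines = ["MEP amplitude (% M-max), group mean +/- SE", ""]
    for muscle in sorted(mep_summaries["muscle"].unique()):
        sub = mep_summaries[mep_summaries["muscle"] == muscle]
        lines.append(f"  {muscle}:")
        for cond in CONDITION_ORDER:
            vals = sub[sub["condition"] == cond]["mean_p2p_norm"].dropna()
            se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            lines.append(f"    {cond:15s} {vals.mean():6.2f} +/- {se:.2f}")
    lines += ["", "Excluded MEP trials (BGA rule / IQR rule):"]
    for (muscle, cond), grp in mep_trials.groupby(["muscle", "condition"]):
        lines.append(
            f"  {muscle} {cond:15s} {int(grp['excluded_bga'].sum())} / {int(grp['outlier'].sum())}"
        )
    if not response_trials.empty:
        lines += ["", "iEMG (normalized), predictability x perturbation group means:", ""]
        for muscle in sorted(response_trials["muscle"].unique()):
            grp = response_trials[response_trials["muscle"] == muscle]
            cell = (
                grp.groupby(["subject_id", "predictability", "perturbation"])["iemg_norm"]
                .mean()
                .groupby(["predictability", "perturbation"])
                .mean()
                .unstack("perturbation")
            )
            lines.append(f"  {muscle}:")
            lines.append(cell.to_string(float_format=lambda v: f"{v:8.4f}"))
            lines.append("")
    lines += ["ANOVA effects:", ""]
    for _, r in anova.iterrows():
        lines.append(
            f"  {r['muscle']} {r['outcome']:10s} {r['effect']:28s} "
            f"F({r['df_effect']:.0f},{r['df_error']:.0f}) = {r['F']:.2f}, "
            f"p = {r['p']:.4f}, pes = {r['partial_eta_sq']:.3f}, "
            f"eps = {r['epsilon_gg']:.3f}"
        )
    return "\n".join(lines) + "\n"


def run_all(
    config: RunConfig,
    out_dir: str | Path,
    data_dir: str | Path | None = None,
) -> dict:
    """Full reproducible run; writes tables and a report under ``out_dir``.

    When ``data_dir`` is given, trials are read from that dataset instead of
    being simulated.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data_dir is not None:
        datasets = read_dataset(data_dir)
    else:
        datasets = simulate_cohort(config.generator, config.cohort_seed)
        if config.write_trials:
            write_dataset(datasets, out / "dataset")
    mep_trials, mep_summaries = run_mep(datasets, config)
    resp_trials, resp_onsets = run_response(datasets)
    anova, pairwise = run_stats(mep_summaries, resp_trials, config)

    mep_trials.to_csv(out / "mep_trials.csv", index=False)
    mep_summaries.to_csv(out / "mep_summary.csv", index=False)
    resp_trials.to_csv(out / "response_trials.csv", index=False)
    resp_onsets.to_csv(out / "response_onsets.csv", index=False)
    anova.to_csv(out / "anova.csv", index=False)
    pairwise.to_csv(out / "pairwise.csv", index=False)
    report = _report(mep_summaries, resp_trials, mep_trials, anova)
    (out / "report.txt").write_text(report)
    config.to_yaml(out / "config.yaml")
    return {
        "datasets": datasets,
        "mep_trials": mep_trials,
        "mep_summaries": mep_summaries,
        "response_trials": resp_trials,
        "response_onsets": resp_onsets,
        "anova": anova,
        "pairwise": pairwise,
        "report": report,
    }
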