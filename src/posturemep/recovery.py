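"""Parameter-recovery experiments on the calibrated synthetic generator.

These experiments measure how well the analysis pipelines recover the
generator's configured group-level quantities: condition-mean MEP amplitudes
(% M-max), perturbation-response onset latencies, the type-I error of the
repeated-measures ANOVA under a null generator configuration, and the power
to detect the configured predictability effect on the TA response.
"""

from __future__ import annotations

import math

import numpy as np

from .config import RunConfig, default_config
from .pipeline import predictability_array, run_mep, run_response
from .protocol import ConditionName, TrialKind
from .response import detect_onset, ensemble_average
from .rmstats import rm_anova_oneway, rm_anova_twoway
from .synth import PopulationConfig, simulate_cohort, simulate_subject

__all__ = [
    "recover_mep_means",
    "recover_onset_latencies",
    "null_rejection_rate",
    "predictability_detection_rate",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(int(seed)).generate_state(n) % (2**31)


def recover_mep_means(
    n_cohorts: int,
    seed: int,
    config: RunConfig | None = None,
    muscle: str = "TA",
) -> dict[str, dict[str, float]]:
    """Full MEP-pipeline recovery of condition means over repeated cohorts.

    Simulates ``n_cohorts`` cohorts with the (default) calibrated config, runs
    the complete MEP pipeline (M-max estimation from sweeps, BGA exclusion,
    IQR outlier rejection, normalization) and returns, per condition, the
    grand mean of subject-level mean normalized amplitudes plus the number of
    subject values pooled.
    """
    cfg = config or default_config()
    values: dict[str, list[float]] = {}
    for s in _child_seeds(seed, n_cohorts):
        cohort = simulate_cohort(cfg.generator, int(s))
        _, summaries = run_mep(cohort, cfg)
        sub = summaries[summaries.muscle == muscle]
        for cond, grp in sub.groupby("condition"):
            values.setdefault(cond, []).extend(grp.mean_p2p_norm.dropna().tolist())
    return {
        c: {"mean": float(np.mean(v)), "n": len(v)} for c, v in values.items()
    }


def recover_onset_latencies(
    condition: ConditionName,
    muscles: list[str],
    n_seeds: int,
    seed: int,
    population: PopulationConfig | None = None,
) -> dict[str, dict[str, float]]:
    """Mean detected ensemble onset latency over seeded catch-trial sets.

    Each seed draws one subject and that condition's five catch trials; the
    2 SD / 10 ms sustained-threshold detector runs on the rectified ensemble.
    Returns per muscle the mean detected latency (ms) and the detection count.
    """
    pop = population or PopulationConfig()
    detected: dict[str, list[float]] = {m: [] for m in muscles}
    for s in _child_seeds(seed, n_seeds):
        ds = simulate_subject(
            pop,
            "sub-01",
            np.random.SeedSequence(int(s)),
            conditions=[condition],
            kinds=[TrialKind.catch],
            include_platform=False,
            include_mmax=False,
        )
        for m in muscles:
            lat = detect_onset(ensemble_average(ds.trials, m))
            if lat is not None:
                detected[m].append(lat)
    return {
        m: {"mean": float(np.mean(v)), "n": len(v)} for m, v in detected.items()
    }


def null_rejection_rate(
    n_sims: int,
    seed: int,
    population: PopulationConfig | None = None,
    n_subjects: int = 12,
    k: int = 5,
    alpha: float = 0.05,
    distribution: str = "normal",
) -> float:
    """Type-I error of the Mauchly-gated one-way RM-ANOVA under a null generator.

    Subject x condition matrices with no condition effect are drawn with the
    generator's variance structure: a shared per-subject component, an
    independent per-condition component, and trial-averaged measurement
    variability.  ``distribution="normal"`` (default) draws the components as
    Gaussians, the model under which the F-test's size is defined;
    ``"lognormal"`` draws the generator's mean-one lognormal factors instead,
    probing robustness to the amplitude skew the MEP pipeline actually
    produces.  Returns the rejection rate at ``alpha``.
    """
    pop = population or PopulationConfig()
    rng = np.random.default_rng(int(seed))

    # residual condition CV: representative of the calibrated TA cells
    total_cv = np.mean(
        [sd / mu for sd, mu in zip(
            pop.mep_between_sd["TA"].values(), pop.mep_mean_pct["TA"].values()
        )]
    )
    res_cv = math.sqrt(
        max((1 + total_cv**2) / (1 + pop.mep_shared_cv**2) - 1, 0.0)
    )
    trial_cv = pop.mep_trial_cv / math.sqrt(10)

    if distribution == "normal":
        y = (
            1.0
            + pop.mep_shared_cv * rng.standard_normal((n_sims, n_subjects, 1))
            + res_cv * rng.standard_normal((n_sims, n_subjects, k))
            + trial_cv * rng.standard_normal((n_sims, n_subjects, k))
        )
    elif distribution == "lognormal":
        def logn(cv, size):
            if cv <= 0:
                return np.ones(size)
            s2 = math.log(1 + cv * cv)
            return rng.lognormal(-0.5 * s2, math.sqrt(s2), size)

        y = (
            logn(pop.mep_shared_cv, (n_sims, n_subjects, 1))
            * logn(res_cv, (n_sims, n_subjects, k))
            * logn(pop.mep_trial_cv, (n_sims, n_subjects, k, 10)).mean(axis=-1)
        )
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    rejections = sum(rm_anova_oneway(y[i]).p < alpha for i in range(n_sims))
    return rejections / n_sims


def predictability_detection_rate(
    n_cohorts: int,
    seed: int,
    population: PopulationConfig | None = None,
    alpha: float = 0.05,
) -> float:
    """Power for the TA predictability main effect at the configured gain.

    Simulates cohorts of catch trials (predictable High/Low/Posterior plus
    Random), runs the response pipeline and the 2 x 3 two-way RM-ANOVA, and
    returns the fraction of cohorts whose predictability main effect on the
    TA iEMG is significant at ``alpha``.
    """
    pop = population or PopulationConfig()
    conditions = [
        ConditionName.High,
        ConditionName.Low,
        ConditionName.Posterior,
        ConditionName.Random,
    ]
    hits = 0
    for s in _child_seeds(seed, n_cohorts):
        cohort = simulate_cohort(
            pop,
            int(s),
            conditions=conditions,
            kinds=[TrialKind.catch],
            include_platform=False,
            include_mmax=False,
        )
        trials, _ = run_response(cohort)
        arr = predictability_array(trials, "TA")
        res = rm_anova_twoway(arr, ("predictability", "perturbation"))
        if res[0].p < alpha:
            hits += 1
    return hits / n_cohorts
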