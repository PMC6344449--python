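"""Experimental protocol model: perturbation profiles, conditions, trial schedules.

The protocol has five standing-balance conditions built from three support-surface
translations (two anterior, one posterior).  Each condition comprises 15 trials:
10 trials with a TMS pulse delivered 50 ms before perturbation onset ("MEP"
trials) and 5 perturbation-only "catch" trials used to measure the evoked EMG
response uncontaminated by stimulation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Direction",
    "PerturbationProfile",
    "PROFILES",
    "ConditionName",
    "Condition",
    "CONDITIONS",
    "TrialKind",
    "ScheduleEntry",
    "TrialSchedule",
    "make_schedule",
    "platform_trajectory",
    "TMS_LEAD_S",
    "MUSCLES",
]

#: seconds by which the TMS pulse precedes the perturbation onset
TMS_LEAD_S = 0.050

#: recorded lower-leg muscles: tibialis anterior, soleus, medial gastrocnemius
MUSCLES = ("TA", "SOL", "MG")


class Direction(str, enum.Enum):
    anterior = "anterior"
    posterior = "posterior"


@dataclass(frozen=True)
class PerturbationProfile:
    """One support-surface translation: direction, displacement (cm), peak velocity (cm/s)."""

    label: str
    direction: Direction
    amplitude_cm: float
    peak_velocity_cm_s: float

    def __post_init__(self) -> None:
        if self.amplitude_cm <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude_cm}")
        if self.peak_velocity_cm_s <= 0:
            raise ValueError(f"peak velocity must be > 0, got {self.peak_velocity_cm_s}")


#: the three canonical translations
PROFILES: dict[str, PerturbationProfile] = {
    "AnteriorLarge": PerturbationProfile("AnteriorLarge", Direction.anterior, 7.0, 25.0),
    "AnteriorSmall": PerturbationProfile("AnteriorSmall", Direction.anterior, 3.5, 10.0),
    "PosteriorLarge": PerturbationProfile("PosteriorLarge", Direction.posterior, 7.0, 25.0),
}


class ConditionName(str, enum.Enum):
    NoPerturbation = "NoPerturbation"
    Low = "Low"
    High = "High"
    Posterior = "Posterior"
    Random = "Random"


@dataclass(frozen=True)
class Condition:
    """A block of the experiment: which perturbations may occur.

    ``perturbation_labels`` is empty for NoPerturbation, a singleton for the
    three predictable perturbed conditions, and all three labels for Random.
    """

    name: ConditionName
    perturbation_labels: tuple[str, ...]

    @property
    def predictable(self) -> bool:
        return self.name is not ConditionName.Random


CONDITIONS: dict[ConditionName, Condition] = {
    ConditionName.NoPerturbation: Condition(ConditionName.NoPerturbation, ()),
    ConditionName.Low: Condition(ConditionName.Low, ("AnteriorSmall",)),
    ConditionName.High: Condition(ConditionName.High, ("AnteriorLarge",)),
    ConditionName.Posterior: Condition(ConditionName.Posterior, ("PosteriorLarge",)),
    ConditionName.Random: Condition(
        ConditionName.Random, ("AnteriorLarge", "AnteriorSmall", "PosteriorLarge")
    ),
}

N_TRIALS_PER_CONDITION = 15
N_MEP_TRIALS = 10
N_CATCH_TRIALS = 5

#: per-perturbation trial counts in the Random condition.  The protocol hands
#: each of the three perturbation types roughly equal probability; with 10 MEP
#: trials the counts are a random permutation of (4, 3, 3) and with 5 catch
#: trials a random permutation of (2, 2, 1).
RANDOM_MEP_COUNTS = (4, 3, 3)
RANDOM_CATCH_COUNTS = (2, 2, 1)


class TrialKind(str, enum.Enum):
    MEP = "MEP"
    catch = "catch"


@dataclass(frozen=True)
class ScheduleEntry:
    condition: ConditionName
    kind: TrialKind
    perturbation: str | None  # profile label, None for NoPerturbation


@dataclass
class TrialSchedule:
    """Ordered list of trials for one subject (conditions in block order)."""

    entries: list[ScheduleEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def for_condition(self, name: ConditionName) -> list[ScheduleEntry]:
        return [e for e in self.entries if e.condition is name]


def _condition_entries(cond: Condition, rng: np.random.Generator) -> list[ScheduleEntry]:
    """15 trials for one condition: 10 MEP + 5 catch in randomized order."""
    if cond.name is ConditionName.Random:
        mep_counts = rng.permutation(RANDOM_MEP_COUNTS)
        catch_counts = rng.permutation(RANDOM_CATCH_COUNTS)
        mep_labels: list[str | None] = []
        catch_labels: list[str | None] = []
        for lab, m, c in zip(cond.perturbation_labels, mep_counts, catch_counts):
            mep_labels += [lab] * int(m)
            catch_labels += [lab] * int(c)
        rng.shuffle(mep_labels)
        rng.shuffle(catch_labels)
    else:
        lab = cond.perturbation_labels[0] if cond.perturbation_labels else None
        mep_labels = [lab] * N_MEP_TRIALS
        catch_labels = [lab] * N_CATCH_TRIALS

    kinds = [TrialKind.MEP] * N_MEP_TRIALS + [TrialKind.catch] * N_CATCH_TRIALS
    order = rng.permutation(N_TRIALS_PER_CONDITION)
    mep_iter = iter(mep_labels)
    catch_iter = iter(catch_labels)
    entries = []
    for idx in order:
        kind = kinds[idx]
        lab = next(mep_iter) if kind is TrialKind.MEP else next(catch_iter)
        entries.append(ScheduleEntry(cond.name, kind, lab))
    return entries


def make_schedule(condition_order_seed: int, per_condition_seed: int) -> TrialSchedule:
    """Build one subject's full trial schedule.

    The five condition blocks are randomized with ``condition_order_seed``;
    within-block trial order and the Random condition's perturbation draw use
    ``per_condition_seed``.  Identical seeds reproduce the schedule exactly.
    """
    order_rng = np.random.default_rng(int(condition_order_seed))
    trial_rng = np.random.default_rng(int(per_condition_seed))
    names = list(ConditionName)
    block_order = [names[i] for i in order_rng.permutation(len(names))]
    entries: list[ScheduleEntry] = []
    for name in block_order:
        entries.extend(_condition_entries(CONDITIONS[name], trial_rng))
    return TrialSchedule(entries)


def platform_trajectory(
    profile: PerturbationProfile, sample_rate: float, hold_s: float = 0.5
) -> np.ndarray:
    """Support-surface displacement (cm) from movement onset, sampled at ``sample_rate``.

    A minimum-jerk profile ``x(tau) = A (10 tau^3 - 15 tau^4 + 6 tau^5)`` whose
    movement time is chosen so the analytic peak velocity ``1.875 A / T`` equals
    the profile's peak velocity.  Posterior translations are negative.  The
    platform holds the final position for ``hold_s`` seconds.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    amp = profile.amplitude_cm
    vmax = profile.peak_velocity_cm_s
    t_move = 1.875 * amp / vmax  # min-jerk peak velocity = 15/8 * A / T
    n_move = int(round(t_move * sample_rate))
    n_hold = int(round(hold_s * sample_rate))
    tau = np.arange(n_move + 1) / (t_move * sample_rate)
    x = amp * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    x = np.concatenate([x, np.full(n_hold, amp)])
    if profile.direction is Direction.posterior:
        x = -x
    return x
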