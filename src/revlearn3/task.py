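"""Three-option probabilistic reversal learning task environment.

The paradigm: on each of 80 trials the agent chooses one of three stimuli and
receives binary feedback (reward +1 or punishment -1).  One stimulus is mostly
rewarded during acquisition and mostly punished after the mid-task reversal
("R-P"), one has the mirrored contingencies ("P-R"), and a neutral stimulus
("N-N") is rewarded half the time throughout.  Stimulus roles are defined
relative to the participant's behaviour: whichever stimulus is chosen first
becomes R-P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ROLES",
    "ROLE_RP",
    "ROLE_PR",
    "ROLE_NN",
    "TaskConfig",
    "FeedbackSchedule",
    "Session",
    "generate_feedback_schedule",
    "assign_roles",
    "step",
]

# Canonical role order used for all index-based APIs.
ROLES = ("R-P", "P-R", "N-N")
ROLE_RP, ROLE_PR, ROLE_NN = 0, 1, 2


@dataclass(frozen=True)
class TaskConfig:
    """Structural constants of the reversal learning paradigm.

    Parameters
    ----------
    n_trials : int
        Total number of trials per session.
    reversal_trial : int
        1-based index of the first reversal-phase trial.  The default 41
        means contingencies flip after 40 acquisition trials.
    contingencies : ndarray, shape (2, n_options)
        Reward probability of each role in each phase (row 0 acquisition,
        row 1 reversal).
    schedule_mode : {"exact_ratio", "iid"}
        ``exact_ratio`` realises reward counts exactly per phase per
        stimulus; ``iid`` draws each outcome independently.
    max_run : int or None
        In ``exact_ratio`` mode, reject shuffles in which the R-P or P-R
        stimulus delivers more than ``max_run`` identical outcomes in a row
        within a phase.  ``None`` disables the rule (always the case in
        ``iid`` mode).
    """

    n_trials: int = 80
    reversal_trial: int = 41
    n_options: int = 3
    contingencies: np.ndarray = field(
        default_factory=lambda: np.array([[0.75, 0.25, 0.50], [0.25, 0.75, 0.50]])
    )
    schedule_mode: str = "exact_ratio"
    max_run: Optional[int] = 4

    def __post_init__(self):
        cont = np.asarray(self.contingencies, dtype=float)
        object.__setattr__(self, "contingencies", cont)
        if cont.shape != (2, self.n_options):
            raise ValueError(
                f"contingencies must have shape (2, {self.n_options}), got {cont.shape}"
            )
        if np.any(cont < 0) or np.any(cont > 1):
            raise ValueError("reward probabilities must lie in [0, 1]")
        if not (1 < self.reversal_trial <= self.n_trials):
            raise ValueError("reversal_trial must lie in (1, n_trials]")
        if self.schedule_mode not in ("exact_ratio", "iid"):
            raise ValueError(f"unknown schedule_mode {self.schedule_mode!r}")

    @property
    def phase_lengths(self) -> tuple[int, int]:
        acq = self.reversal_trial - 1
        return acq, self.n_trials - acq

    def phase_of_trial(self, trial: np.ndarray | int) -> np.ndarray | str:
        """Phase label for 1-based trial index/indices."""
        t = np.asarray(trial)
        out = np.where(t < self.reversal_trial, "acquisition", "reversal")
        return out if out.ndim else str(out)


@dataclass(frozen=True)
class FeedbackSchedule:
    """Predetermined outcome of every stimulus on every trial.

    ``outcomes[t, j]`` is the feedback (+1/-1) stimulus-role ``j`` would
    deliver if chosen on trial ``t`` (0-based).  Choice-independent schedules
    make environments comparable across agents run with the same seed.
    """

    outcomes: np.ndarray
    seed: int
    mode: str

    def __post_init__(self):
        out = np.asarray(self.outcomes, dtype=np.int8)
        if not np.isin(out, (-1, 1)).all():
            raise ValueError("schedule entries must be -1 or +1")
        object.__setattr__(self, "outcomes", out)

    @property
    def n_trials(self) -> int:
        return self.outcomes.shape[0]


@dataclass
class Session:
    """One subject-session of trial-level behaviour.

    Choices are stored as role indices into :data:`ROLES`; outcomes are the
    feedback actually received, coded -1/+1.  Working-memory span and
    impulsivity scores are carried at the subject level for covariate
    analyses.
    """

    subject_id: str
    drug_label: str  # "placebo" | "MPH"
    choices: np.ndarray  # int role index per trial
    outcomes: np.ndarray  # -1 / +1 per trial
    config: TaskConfig = field(default_factory=TaskConfig)
    rt_ms: Optional[np.ndarray] = None
    wm_span: Optional[float] = None
    bis: Optional[float] = None
    session_index: int = 1

    def __post_init__(self):
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.outcomes = np.asarray(self.outcomes, dtype=np.float64)
        if self.drug_label not in ("placebo", "MPH"):
            raise ValueError(f"unknown drug label {self.drug_label!r}")
        if self.choices.shape != self.outcomes.shape:
            raise ValueError("choices and outcomes must be the same length")
        if not np.isin(self.outcomes, (-1.0, 1.0)).all():
            raise ValueError("outcomes must be -1 or +1")
        if self.choices.min(initial=0) < 0 or self.choices.max(initial=0) >= self.config.n_options:
            raise ValueError("choice role indices out of range")
        if self.rt_ms is not None:
            self.rt_ms = np.asarray(self.rt_ms, dtype=float)
            if (self.rt_ms < 0).any():
                raise ValueError("negative reaction times")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def phases(self) -> np.ndarray:
        """Phase label per trial."""
        return self.config.phase_of_trial(np.arange(1, self.n_trials + 1))


def _phase_block(p_reward: float, length: int, rng: np.random.Generator,
                 mode: str, max_run: Optional[int]) -> np.ndarray:
    from . import _kernels

    if mode == "iid":
        return np.where(rng.random(length) < p_reward, 1, -1).astype(np.int8)
    n_reward_f = p_reward * length
    n_reward = round(n_reward_f)
    if abs(n_reward_f - n_reward) > 1e-9:
        raise ValueError(
            f"exact_ratio mode needs an integer reward count; "
            f"p={p_reward} over {length} trials gives {n_reward_f}"
        )
    mr = max_run if max_run is not None else length + 1
    block = _kernels.sample_outcome_block(n_reward, length - n_reward, mr,
                                          int(rng.integers(2**31)))
    if block[0] == -2:
        raise RuntimeError("could not satisfy the run-length constraint")
    return block


def generate_feedback_schedule(config: TaskConfig, seed: int) -> FeedbackSchedule:
    """Generate the per-stimulus outcome schedule for one session.

    In ``exact_ratio`` mode every stimulus realises its programmed reward
    count exactly within each phase (e.g. 30 rewards in 40 acquisition trials
    at p=0.75), with an optional rejection rule that forbids long identical
    runs for the two reversing stimuli.  In ``iid`` mode outcomes are
    independent Bernoulli draws.  Deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    acq_len, rev_len = config.phase_lengths
    out = np.empty((config.n_trials, config.n_options), dtype=np.int8)
    for j in range(config.n_options):
        # run-length rule applies only to the reversing stimuli
        max_run = config.max_run if (config.schedule_mode == "exact_ratio" and j in (ROLE_RP, ROLE_PR)) else None
        out[:acq_len, j] = _phase_block(config.contingencies[0, j], acq_len, rng,
                                        config.schedule_mode, max_run)
        out[acq_len:, j] = _phase_block(config.contingencies[1, j], rev_len, rng,
                                        config.schedule_mode, max_run)
    return FeedbackSchedule(outcomes=out, seed=seed, mode=config.schedule_mode)


def assign_roles(first_choice: str, stimulus_ids: Sequence[str],
                 rng: np.random.Generator) -> dict[str, str]:
    """Map raw stimulus identifiers to task roles.

    The first-chosen stimulus becomes R-P by definition of the paradigm; the
    two remaining roles are assigned uniformly at random between the other
    stimuli (the assignment rule for the non-chosen pair is a free choice of
    the environment).
    """
    ids = list(stimulus_ids)
    if len(ids) != 3 or len(set(ids)) != 3:
        raise ValueError("exactly three distinct stimulus ids required")
    if first_choice not in ids:
        raise ValueError(f"first choice {first_choice!r} not among stimuli {ids}")
    others = [s for s in ids if s != first_choice]
    if rng.random() < 0.5:
        others = others[::-1]
    return {first_choice: "R-P", others[0]: "P-R", others[1]: "N-N"}


def step(schedule: FeedbackSchedule, trial: int, choice: int) -> int:
    """Outcome delivered when ``choice`` (role index) is taken on 0-based ``trial``."""
    if not (0 <= trial < schedule.n_trials):
        raise IndexError(f"trial {trial} out of range")
    if not (0 <= choice < schedule.outcomes.shape[1]):
        raise IndexError(f"choice {choice} out of range")
    return int(schedule.outcomes[trial, choice])
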