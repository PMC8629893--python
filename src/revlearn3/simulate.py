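"""Agent simulation, posterior-predictive validation, and the
optimal-learning-rate analysis.

Simulated agents honour the paradigm's role-assignment rule: in role space
the first choice is R-P by definition (whichever stimulus an agent picks
first *becomes* the mostly-rewarded acquisition stimulus), so simulated and
observed datasets are structurally identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .models import ModelSpec, get_model
from .task import Session, TaskConfig, generate_feedback_schedule

__all__ = ["simulate_agent", "PosteriorPredictive", "posterior_predictive",
           "LearningRateCurve", "optimal_learning_rate_curve",
           "two_option_config"]

_FAMILY_CODE = {"ewa": _kernels.FAMILY_EWA, "hybrid": _kernels.FAMILY_HYBRID}


def _kernel_params(model: ModelSpec, params, drug_label: str) -> np.ndarray:
    """4-slot constrained kernel parameters from a dict (constrained scale,
    keyed by parameter name) or an unconstrained vector."""
    if isinstance(params, Mapping):
        out = np.zeros(4)
        for k, slot in enumerate(model.slots):
            if slot in params:
                out[k] = params[slot]
            elif f"{slot}_{drug_label}" in params:
                out[k] = params[f"{slot}_{drug_label}"]
            elif slot == "alpha_f" and not model.use_forgetting:
                out[k] = 0.0
            else:
                raise KeyError(f"missing parameter for slot {slot!r}")
        lo_hi = [(0, 1), (0, 1), (0, np.inf), (0, 1)]
        for k, (lo, hi) in enumerate(lo_hi):
            if not lo <= out[k] <= hi:
                raise ValueError(f"parameter slot {model.slots[k]}={out[k]} violates constraint")
        return out
    return model.session_params(np.asarray(params, float), drug_label)


def simulate_agent(model: ModelSpec | str, params, config: TaskConfig,
                   seed: int, drug_label: str = "placebo",
                   subject_id: str = "sim", wm_span=None, bis=None,
                   schedule=None) -> Session:
    """Simulate one agent-session.

    ``params`` is either a dict of constrained parameter values or an
    unconstrained parameter vector matching the model spec.  A fresh
    feedback schedule is generated from ``seed`` unless one is supplied.
    """
    if isinstance(model, str):
        model = get_model(model)
    theta = _kernel_params(model, params, drug_label)
    ss = np.random.SeedSequence(seed)
    sched_seed, choice_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if schedule is None:
        schedule = generate_feedback_schedule(config, sched_seed)
    rng = np.random.default_rng(choice_seed)
    u = rng.random(config.n_trials)
    choices, outcomes = _kernels.simulate_session_kernel(
        _FAMILY_CODE[model.family], schedule.outcomes.astype(np.float64),
        theta[0], theta[1], theta[2], theta[3], u, True)
    return Session(subject_id=subject_id, drug_label=drug_label,
                   choices=choices, outcomes=outcomes, config=config,
                   wm_span=wm_span, bis=bis)


@dataclass
class PosteriorPredictive:
    """Per-subject trial-wise choice probabilities averaged over agents.

    ``choice_probs[subject_id][drug]`` is an (n_trials, n_options) matrix of
    the fraction of simulated agents choosing each role on each trial.
    """

    choice_probs: dict
    covariates: pd.DataFrame  # index subject_id; columns wm_span, bis
    config: TaskConfig
    n_agents: int
    seed: int

    def accuracy_table(self, avoid_convention: str = "chance") -> pd.DataFrame:
        """Study-shaped long accuracy table ready for the behavioural ANOVA."""
        from .behaviour import metrics_from_probs
        rows = []
        for sid, per_drug in self.choice_probs.items():
            for drug, probs in per_drug.items():
                for phase, metrics in metrics_from_probs(
                        probs, self.config, avoid_convention).items():
                    for valence in ("pReward", "pAvoidPunish"):
                        rows.append({
                            "subject": sid, "drug": drug, "phase": phase,
                            "valence": valence,
                            "value": metrics[f"{valence}_corrected"],
                            "pNeutral_corrected": metrics["pNeutral_corrected"],
                        })
        df = pd.DataFrame(rows)
        return df.merge(self.covariates, left_on="subject", right_index=True, how="left")

    def mean_trajectory(self, drug: Optional[str] = None) -> np.ndarray:
        """Grand-average (n_trials, n_options) choice-probability trajectory."""
        mats = [probs for per_drug in self.choice_probs.values()
                for d, probs in per_drug.items() if drug is None or d == drug]
        return np.mean(mats, axis=0)


def posterior_predictive(fits: Sequence, config: TaskConfig,
                         n_agents: int = 100, seed: int = 0,
                         drug_labels: Sequence[str] = ("placebo", "MPH")) -> PosteriorPredictive:
    """Simulate ``n_agents`` task plays per fitted subject per session and
    average their choices — the model-validation step that turns fitted
    parameters back into study-shaped behaviour.

    ``fits`` are :class:`~revlearn3.fitting.SubjectFitResults`, one per
    subject (fitted jointly on both sessions).  Each agent plays a freshly
    generated schedule.
    """
    if not fits:
        raise ValueError("no fits supplied")
    probs: dict = {}
    cov_rows = {}
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(len(fits))
    trial_idx = np.arange(config.n_trials)
    for fit, sub_ss in zip(fits, subj_seeds):
        sess0 = fit.model.sessions[0]
        sid = sess0.subject_id
        cov_rows[sid] = {"wm_span": sess0.wm_span, "bis": sess0.bis}
        probs[sid] = {}
        drug_seeds = sub_ss.spawn(len(drug_labels))
        for drug, d_ss in zip(drug_labels, drug_seeds):
            theta = _kernel_params(fit.spec, fit.params_unconstrained, drug)
            fam = _FAMILY_CODE[fit.spec.family]
            rng = np.random.default_rng(d_ss)
            acc = np.zeros((config.n_trials, config.n_options))
            for _ in range(n_agents):
                sched = generate_feedback_schedule(
                    config, int(rng.integers(2**31))).outcomes.astype(np.float64)
                choices, _ = _kernels.simulate_session_kernel(
                    fam, sched, theta[0], theta[1], theta[2], theta[3],
                    rng.random(config.n_trials), True)
                acc[trial_idx, choices] += 1.0
            probs[sid][drug] = acc / n_agents
    covariates = pd.DataFrame.from_dict(cov_rows, orient="index")
    covariates.index.name = "subject"
    return PosteriorPredictive(choice_probs=probs, covariates=covariates,
                               config=config, n_agents=n_agents, seed=seed)


def two_option_config(n_trials: int = 80, reversal_trial: int = 41) -> TaskConfig:
    """The predecessor 2-option reversal paradigm: 70:30 / 30:70."""
    return TaskConfig(n_trials=n_trials, reversal_trial=reversal_trial,
                      n_options=2,
                      contingencies=np.array([[0.7, 0.3], [0.3, 0.7]]))


@dataclass
class LearningRateCurve:
    """Simulated task performance as a function of the payoff-decay phi.

    Accuracy is the fraction of trials on which the currently-best stimulus
    (mostly rewarded in the current phase) was chosen; mean reward per trial
    is reported alongside since either could define "optimal".
    """

    phi_grid: np.ndarray
    accuracy: np.ndarray
    accuracy_se: np.ndarray
    mean_reward: np.ndarray
    reward_se: np.ndarray
    label: str
    n_sims: int

    def peak_phi(self, criterion: str = "accuracy", window: int = 3) -> float:
        """Location of the maximum, refined by a quadratic fit through the
        grid points around the best one (less grid- and noise-sensitive
        than the raw argmax)."""
        y = self.accuracy if criterion == "accuracy" else self.mean_reward
        i = int(np.argmax(y))
        lo, hi = max(0, i - window), min(len(y), i + window + 1)
        if hi - lo < 3:
            return float(self.phi_grid[i])
        c = np.polyfit(self.phi_grid[lo:hi], y[lo:hi], 2)
        if c[0] >= 0:  # not locally concave; fall back to the grid argmax
            return float(self.phi_grid[i])
        return float(np.clip(-c[1] / (2 * c[0]),
                             self.phi_grid[lo], self.phi_grid[hi - 1]))

    def argmax_phi(self, criterion: str = "accuracy", flat_tol: float = 0.0) -> float:
        """phi maximising the criterion; with ``flat_tol`` > 0, the midpoint
        of the grid region within ``flat_tol`` of the maximum."""
        y = self.accuracy if criterion == "accuracy" else self.mean_reward
        if flat_tol > 0:
            near = self.phi_grid[y >= y.max() - flat_tol]
            return float(0.5 * (near.min() + near.max()))
        return float(self.phi_grid[int(np.argmax(y))])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.phi_grid, self.accuracy, yerr=self.accuracy_se,
                    label=self.label)
        ax.set_xlabel(r"payoff decay $\varphi$")
        ax.set_ylabel("accuracy")
        ax.legend(frameon=False)
        return ax


def optimal_learning_rate_curve(config: TaskConfig,
                                reference_params: Mapping[str, float],
                                phi_grid: Sequence[float],
                                n_sims: int = 1000, seed: int = 0,
                                label: str = "") -> LearningRateCurve:
    """Sweep phi with the other EWA+F parameters fixed at reference values
    and measure simulated task performance.

    The best available stimulus is role 0 (R-P) during acquisition and role
    1 (P-R) after reversal; in the 2-option variant the same role indexing
    applies.
    """
    phi_grid = np.asarray(list(phi_grid), dtype=float)
    if phi_grid.size == 0:
        raise ValueError("empty phi grid")
    if np.any((phi_grid < 0) | (phi_grid > 1)):
        raise ValueError("phi grid must lie in [0, 1]")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    acq_len = config.reversal_trial - 1
    best = np.zeros(config.n_trials, dtype=np.int64)
    best[acq_len:] = 1
    rho = reference_params["rho"]
    beta = reference_params["beta"]
    alpha_f = reference_params.get("alpha_f", 0.0)

    acc = np.zeros(len(phi_grid))
    acc_se = np.zeros(len(phi_grid))
    rew = np.zeros(len(phi_grid))
    rew_se = np.zeros(len(phi_grid))
    for gi, phi in enumerate(phi_grid):
        # identical rng per grid point: common random numbers across phis
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        a_acc = np.zeros(n_sims)
        a_rew = np.zeros(n_sims)
        for ai in range(n_sims):
            schedule = generate_feedback_schedule(config, int(rng.integers(2**31)))
            u = rng.random(config.n_trials)
            choices, outcomes = _kernels.simulate_session_kernel(
                _kernels.FAMILY_EWA, schedule.outcomes.astype(np.float64),
                phi, rho, beta, alpha_f, u, True)
            a_acc[ai] = np.mean(choices == best)
            a_rew[ai] = np.mean(outcomes)
        acc[gi] = a_acc.mean()
        acc_se[gi] = a_acc.std(ddof=1) / np.sqrt(n_sims) if n_sims > 1 else np.nan
        rew[gi] = a_rew.mean()
        rew_se[gi] = a_rew.std(ddof=1) / np.sqrt(n_sims) if n_sims > 1 else np.nan
    return LearningRateCurve(phi_grid=phi_grid, accuracy=acc, accuracy_se=acc_se,
                             mean_reward=rew, reward_se=rew_se,
                             label=label or f"{config.n_options}-option",
                             n_sims=n_sims)
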