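"""The learning-model family for the 3-option reversal task.

Two base families are implemented:

* **EWA** — experience-weighted attraction.  Each option carries an
  experience weight ``n`` that grows with use (``n <- n*rho + 1``), so the
  effective learning rate ``1/n`` shrinks with experience; ``phi`` is the
  decay factor on previous payoffs (the "inverse learning rate": higher phi,
  slower updating).
* **Hybrid** — a Pearce-Hall/Rescorla-Wagner hybrid in which the learning
  rate tracks recent surprise through an associability term.

Each family optionally forgets the values of unchosen options toward their
initial value 0 at rate ``alpha_f`` ("+F" models), and any single parameter
of the EWA+F model can be split by drug session (placebo vs methylphenidate)
to form the drug-effect model family.

All fitting happens on an unconstrained scale: unit-interval parameters map
through the logistic sigmoid, positive parameters through exp, and every
unconstrained parameter carries an independent N(0, 10) prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from . import _kernels
from .task import Session

__all__ = [
    "ParamSpec",
    "ModelSpec",
    "LearnerState",
    "MODEL_REGISTRY",
    "get_model",
    "list_models",
    "ewa_update",
    "forget_unchosen",
    "hybrid_update",
    "softmax_probs",
    "negative_log_likelihood",
    "nll_and_grad",
]

PRIOR_MEAN = 0.0
PRIOR_VAR = 10.0


@dataclass(frozen=True)
class ParamSpec:
    """One model parameter: its constraint set, transform and prior.

    ``constrain`` maps the unconstrained real line onto the constraint set
    (logistic sigmoid for [0,1], exp for positives); the prior is Gaussian
    N(0, 10) on the unconstrained scale for every parameter.
    """

    name: str
    constraint: str  # "unit_interval" | "positive"
    prior_mean: float = PRIOR_MEAN
    prior_var: float = PRIOR_VAR

    def __post_init__(self):
        if self.constraint not in ("unit_interval", "positive"):
            raise ValueError(f"unknown constraint {self.constraint!r}")

    def constrain(self, x: float) -> float:
        if self.constraint == "unit_interval":
            return float(expit(x))
        # cap keeps the likelihood finite when an optimizer line search
        # overshoots; exp(50) is far beyond any plausible inverse temperature
        return float(np.exp(min(x, 50.0)))

    def unconstrain(self, v: float) -> float:
        if self.constraint == "unit_interval":
            if not 0.0 < v < 1.0:
                raise ValueError(f"{self.name}={v} outside (0, 1)")
            return float(logit(v))
        if v <= 0.0:
            raise ValueError(f"{self.name}={v} must be positive")
        return float(np.log(v))

    def dconstrain(self, x: float) -> float:
        """Jacobian d(constrained)/d(unconstrained) at x."""
        if self.constraint == "unit_interval":
            s = expit(x)
            return float(s * (1.0 - s))
        return float(np.exp(min(x, 50.0)))


def _unit(name):
    return ParamSpec(name, "unit_interval")


def _pos(name):
    return ParamSpec(name, "positive")


# slot layout shared with _kernels: (value-decay, experience/assoc rate, beta, alpha_f)
_EWA_SLOTS = ("phi", "rho", "beta", "alpha_f")
_HYBRID_SLOTS = ("eta", "kappa", "beta", "alpha_f")


@dataclass(frozen=True)
class ModelSpec:
    """A model identity: family, parameter list, optional drug split.

    ``split_param`` names the one parameter estimated separately for the
    placebo and methylphenidate sessions; the parameter vector then carries
    ``<p>_placebo`` and ``<p>_MPH`` entries in place of ``<p>``.
    """

    name: str
    family: str  # "ewa" | "hybrid"
    params: tuple[ParamSpec, ...]
    split_param: Optional[str] = None
    use_forgetting: bool = True

    def __post_init__(self):
        if self.family not in ("ewa", "hybrid"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.split_param is not None:
            names = [p.name for p in self.params]
            if (f"{self.split_param}_placebo" not in names
                    or f"{self.split_param}_MPH" not in names):
                raise ValueError(
                    f"split parameter {self.split_param!r} lacks per-drug entries")

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def slots(self) -> tuple[str, ...]:
        return _EWA_SLOTS if self.family == "ewa" else _HYBRID_SLOTS

    def slot_indices(self, drug_label: str) -> np.ndarray:
        """Index into the parameter vector for each kernel slot.

        Returns a length-4 int array; -1 marks a slot fixed at its default
        (alpha_f = 0 for models without forgetting).
        """
        names = list(self.param_names)
        idx = np.full(4, -1, dtype=np.int64)
        for k, slot in enumerate(self.slots):
            if slot in names:
                idx[k] = names.index(slot)
            elif f"{slot}_{drug_label}" in names:
                idx[k] = names.index(f"{slot}_{drug_label}")
            elif slot == "alpha_f" and not self.use_forgetting:
                idx[k] = -1
            else:
                raise ValueError(f"model {self.name}: no parameter for slot {slot}")
        return idx

    def constrain(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.array([p.constrain(xi) for p, xi in zip(self.params, x)])

    def unconstrain(self, v: np.ndarray) -> np.ndarray:
        return np.array([p.unconstrain(vi) for p, vi in zip(self.params, np.asarray(v, float))])

    def session_params(self, x: np.ndarray, drug_label: str) -> np.ndarray:
        """Constrained kernel parameters (4-vector) for one session."""
        idx = self.slot_indices(drug_label)
        out = np.zeros(4)
        for k in range(4):
            if idx[k] >= 0:
                out[k] = self.params[idx[k]].constrain(float(x[idx[k]]))
        return out


def _base(name, family, slots, use_forgetting):
    params = tuple(_pos(s) if s == "beta" else _unit(s)
                   for s in slots if s != "alpha_f" or use_forgetting)
    return ModelSpec(name, family, params, use_forgetting=use_forgetting)


def _split(split: str) -> ModelSpec:
    params = []
    for s in _EWA_SLOTS:
        mk = _pos if s == "beta" else _unit
        if s == split:
            params += [mk(f"{s}_placebo"), mk(f"{s}_MPH")]
        else:
            params.append(mk(s))
    return ModelSpec(f"EWA+F+d{split}", "ewa", tuple(params), split_param=split)


MODEL_REGISTRY: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        _base("EWA", "ewa", _EWA_SLOTS, use_forgetting=False),
        _base("EWA+F", "ewa", _EWA_SLOTS, use_forgetting=True),
        _base("Hybrid", "hybrid", _HYBRID_SLOTS, use_forgetting=False),
        _base("Hybrid+F", "hybrid", _HYBRID_SLOTS, use_forgetting=True),
        _split("phi"),
        _split("rho"),
        _split("beta"),
        _split("alpha_f"),
    ]
}

BASE_MODELS = ("EWA", "EWA+F", "Hybrid", "Hybrid+F")
DRUG_MODELS = ("EWA+F", "EWA+F+dphi", "EWA+F+drho", "EWA+F+dalpha_f", "EWA+F+dbeta")


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}") from None


def list_models() -> list[str]:
    return sorted(MODEL_REGISTRY)


# ---------------------------------------------------------------------------
# Single-step update rules (reference implementations of the recursions).
# The likelihood below uses the compiled kernels; these are the readable,
# stateless versions used for documentation, small simulations and tests.
# ---------------------------------------------------------------------------

@dataclass
class LearnerState:
    """Per-option learner state: values V (init 0), experience weights n
    (init 1), and, for hybrid models, associability (init 1)."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(3))
    experience: np.ndarray = field(default_factory=lambda: np.ones(3))
    associability: np.ndarray = field(default_factory=lambda: np.ones(3))

    def copy(self) -> "LearnerState":
        return LearnerState(self.values.copy(), self.experience.copy(),
                            self.associability.copy())


def _check_outcome(outcome: float):
    if outcome not in (-1, 1, -1.0, 1.0):
        raise ValueError(f"outcome must be -1 or +1, got {outcome}")


def ewa_update(state: LearnerState, choice: int, outcome: float,
               phi: float, rho: float) -> LearnerState:
    """One EWA value update for the chosen option; unchosen options untouched."""
    _check_outcome(outcome)
    if not (0.0 <= phi <= 1.0 and 0.0 <= rho <= 1.0):
        raise ValueError("phi and rho must lie in [0, 1]")
    s = state.copy()
    n_old = s.experience[choice]
    n_new = n_old * rho + 1.0
    s.values[choice] = (s.values[choice] * phi * n_old + outcome) / n_new
    s.experience[choice] = n_new
    return s


def forget_unchosen(state: LearnerState, choice: int, alpha_f: float) -> LearnerState:
    """Decay unchosen options' values toward the initial value 0."""
    if not 0.0 <= alpha_f <= 1.0:
        raise ValueError("alpha_f must lie in [0, 1]")
    s = state.copy()
    mask = np.arange(len(s.values)) != choice
    s.values[mask] *= 1.0 - alpha_f
    return s


def hybrid_update(state: LearnerState, choice: int, outcome: float,
                  eta: float, kappa: float) -> LearnerState:
    """One Pearce-Hall hybrid update: surprise-scaled learning rate.

    The effective learning rate ``eta * associability`` is capped at 1:
    with feedback coded -1/+1 the associability may exceed ``1/eta``, and
    the uncapped recursion can diverge on unlucky choice-outcome sequences.
    """
    _check_outcome(outcome)
    if not (0.0 <= eta <= 1.0 and 0.0 <= kappa <= 1.0):
        raise ValueError("eta and kappa must lie in [0, 1]")
    s = state.copy()
    delta = outcome - s.values[choice]
    s.values[choice] += min(eta * s.associability[choice], 1.0) * delta
    s.associability[choice] = (1.0 - kappa) * s.associability[choice] + kappa * abs(delta)
    return s


def softmax_probs(values: np.ndarray, beta: float) -> np.ndarray:
    """Choice probabilities p_i proportional to exp(beta * V_i), computed
    via log-sum-exp for stability."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    z = beta * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _require_sessions(model: ModelSpec, sessions: Sequence[Session]):
    if isinstance(sessions, Session):
        sessions = [sessions]
    sessions = list(sessions)
    if not sessions:
        raise ValueError("at least one session required")
    if model.split_param is not None:
        labels = {s.drug_label for s in sessions}
        if labels != {"placebo", "MPH"}:
            raise ValueError(
                f"drug-split model {model.name} needs one placebo and one MPH "
                f"session, got labels {sorted(labels)}")
    return sessions


def nll_and_grad(model: ModelSpec, x: np.ndarray,
                 sessions: Sequence[Session] | Session) -> tuple[float, np.ndarray]:
    """Negative log likelihood of the sessions' choices and its gradient with
    respect to the unconstrained parameter vector ``x``.

    The learner state is reset at the start of each session (no carry-over
    between testing days); drug-split parameters are routed by each
    session's drug label.
    """
    sessions = _require_sessions(model, sessions)
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_params,):
        raise ValueError(f"expected {model.n_params} parameters, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite parameters")
    kernel = _kernels.ewa_nll_grad if model.family == "ewa" else _kernels.hybrid_nll_grad
    total = 0.0
    grad = np.zeros(model.n_params)
    for sess in sessions:
        idx = model.slot_indices(sess.drug_label)
        theta = np.zeros(4)
        jac = np.zeros(4)
        for k in range(4):
            if idx[k] >= 0:
                theta[k] = model.params[idx[k]].constrain(float(x[idx[k]]))
                jac[k] = model.params[idx[k]].dconstrain(float(x[idx[k]]))
        nll, g = kernel(sess.choices, sess.outcomes, theta[0], theta[1], theta[2], theta[3])
        if not math.isfinite(nll):
            raise FloatingPointError("non-finite likelihood encountered")
        total += nll
        for k in range(4):
            if idx[k] >= 0:
                grad[idx[k]] += g[k] * jac[k]
    return total, grad


def negative_log_likelihood(model: ModelSpec, x: np.ndarray,
                            sessions: Sequence[Session] | Session) -> float:
    """NLL of the observed choices under ``model`` at unconstrained ``x``."""
    return nll_and_grad(model, x, sessions)[0]
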