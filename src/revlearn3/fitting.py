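"""Per-subject MAP estimation with Laplace-approximated model evidence.

The posterior over a subject's unconstrained parameters x combines the
choice likelihood with independent Gaussian priors; the objective minimised
is

    f(x) = NLL(x) + 0.5 * sum_j [ (x_j - mu_j)^2 / v_j + ln(2 pi v_j) ]

(the prior normalising constant is kept so that the Laplace approximation

    log Z ~= -f(x*) + (d/2) ln(2 pi) - 0.5 ln det H(x*)

is an approximation of the true log marginal likelihood).  Optimisation is
multi-start quasi-Newton (BFGS) with analytic gradients; restart initial
points are drawn from the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .models import ModelSpec, nll_and_grad
from .task import Session

__all__ = ["MAPFit", "fit_map", "SubjectModel", "SubjectFitResults",
           "fit_subjects", "extract_subject_parameters", "parameter_summary"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MAPFit:
    """Result of one multi-start MAP optimisation."""

    x: np.ndarray                 # MAP estimate, unconstrained scale
    objective: float              # value of f at the MAP
    hessian: np.ndarray           # Hessian of f at the MAP (symmetrised)
    log_evidence: float           # Laplace log marginal likelihood
    grad_norm: float
    n_restarts: int
    restart_objectives: np.ndarray
    converged: bool
    warnings: list = field(default_factory=list)

    @property
    def posterior_cov(self) -> np.ndarray:
        return np.linalg.inv(self.hessian)


def _laplace_log_evidence(objective: float, hessian: np.ndarray,
                          warnings: list) -> float:
    d = hessian.shape[0]
    sign, logdet = np.linalg.slogdet(hessian)
    if sign <= 0:
        # not positive definite at the optimum: ridge-regularise
        ridge = 1e-6 * max(1.0, np.abs(np.diag(hessian)).max())
        h = hessian.copy()
        for _ in range(30):
            h = h + ridge * np.eye(d)
            sign, logdet = np.linalg.slogdet(h)
            if sign > 0:
                break
            ridge *= 10.0
        warnings.append(f"hessian regularised with ridge {ridge:g}")
        hessian[:] = h
    return -objective + 0.5 * d * _LOG2PI - 0.5 * logdet


def fit_map(nll_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
            n_params: int,
            prior_mean: np.ndarray | float = 0.0,
            prior_var: np.ndarray | float = 10.0,
            n_restarts: int = 20,
            seed: int = 0,
            x0: Optional[np.ndarray] = None,
            gtol: float = 1e-6) -> MAPFit:
    """Multi-start MAP optimisation for any differentiable NLL.

    ``nll_grad(x) -> (nll, grad)``.  The Gaussian prior (mean/variance per
    parameter, broadcastable scalars accepted) is added internally.  The
    first start is the prior mean (or ``x0`` when given); the remaining
    starts are drawn from the prior using ``seed``, so the fit is
    deterministic given its arguments.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    mu = np.broadcast_to(np.asarray(prior_mean, float), (n_params,)).copy()
    v = np.broadcast_to(np.asarray(prior_var, float), (n_params,)).copy()
    if np.any(v <= 0):
        raise ValueError("prior variances must be positive")
    const = 0.5 * np.sum(np.log(2.0 * np.pi * v))

    def objective(x):
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                nll, g = nll_grad(x)
            except FloatingPointError:
                # line-search overshoot: report +inf so the search backtracks
                return np.inf, (x - mu) / v
            dev = (x - mu) / v
            return nll + 0.5 * np.sum(dev * (x - mu)) + const, g + dev

    rng = np.random.default_rng(seed)
    starts = [mu if x0 is None else np.asarray(x0, float)]
    starts += [rng.normal(mu, np.sqrt(v)) for _ in range(n_restarts - 1)]

    best = None
    objectives = []
    any_success = False
    for s in starts:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                res = optimize.minimize(objective, s, jac=True, method="BFGS",
                                        options={"gtol": gtol, "maxiter": 500})
        except FloatingPointError:
            objectives.append(np.inf)
            continue
        objectives.append(res.fun)
        any_success = any_success or res.success or np.linalg.norm(res.jac) < 1e-3
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"all {n_restarts} restarts failed; objectives: {objectives}")

    x = best.x
    # numeric Hessian via central differences of the analytic gradient
    d = n_params
    h = np.zeros((d, d))
    eps = 1e-5 * np.maximum(1.0, np.abs(x))
    for i in range(d):
        xp = x.copy(); xp[i] += eps[i]
        xm = x.copy(); xm[i] -= eps[i]
        h[:, i] = (objective(xp)[1] - objective(xm)[1]) / (2.0 * eps[i])
    h = 0.5 * (h + h.T)
    warn: list = []
    log_ev = _laplace_log_evidence(best.fun, h, warn)
    return MAPFit(x=x, objective=float(best.fun), hessian=h,
                  log_evidence=float(log_ev),
                  grad_norm=float(np.linalg.norm(best.jac)),
                  n_restarts=n_restarts,
                  restart_objectives=np.asarray(objectives),
                  converged=bool(any_success), warnings=warn)


class SubjectModel:
    """One subject's learning model, ready to fit to their session(s).

    statsmodels-style: construct from data, call :meth:`fit`, inspect the
    returned :class:`SubjectFitResults`.
    """

    def __init__(self, model: ModelSpec, sessions: Sequence[Session] | Session):
        if isinstance(sessions, Session):
            sessions = [sessions]
        self.model = model
        self.sessions = list(sessions)

    def nll(self, x: np.ndarray) -> float:
        return nll_and_grad(self.model, x, self.sessions)[0]

    def fit(self, n_restarts: int = 20, seed: int = 0,
            prior_mean: np.ndarray | float = 0.0,
            prior_var: np.ndarray | float = 10.0,
            x0: Optional[np.ndarray] = None,
            gtol: float = 1e-6) -> "SubjectFitResults":
        res = fit_map(lambda x: nll_and_grad(self.model, x, self.sessions),
                      self.model.n_params, prior_mean, prior_var,
                      n_restarts=n_restarts, seed=seed, x0=x0, gtol=gtol)
        return SubjectFitResults(self, res)


class SubjectFitResults:
    """MAP fit of one subject: estimates, curvature, Laplace evidence."""

    def __init__(self, model: SubjectModel, fit: MAPFit):
        self.model = model
        self.spec = model.model
        self._fit = fit

    @property
    def params_unconstrained(self) -> np.ndarray:
        return self._fit.x

    @property
    def params(self) -> dict[str, float]:
        """Constrained-scale MAP estimates keyed by parameter name."""
        vals = self.spec.constrain(self._fit.x)
        return dict(zip(self.spec.param_names, map(float, vals)))

    @property
    def hessian(self) -> np.ndarray:
        return self._fit.hessian

    @property
    def log_evidence(self) -> float:
        return self._fit.log_evidence

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def nll(self) -> float:
        return self.model.nll(self._fit.x)

    def se_unconstrained(self) -> np.ndarray:
        return np.sqrt(np.diag(self._fit.posterior_cov))

    def summary(self) -> pd.DataFrame:
        se = self.se_unconstrained()
        rows = []
        for j, p in enumerate(self.spec.params):
            rows.append({
                "param": p.name,
                "constrained": p.constrain(self._fit.x[j]),
                "unconstrained": self._fit.x[j],
                "se_unconstrained": se[j],
            })
        return pd.DataFrame(rows)

    def __repr__(self):
        pars = ", ".join(f"{k}={v:.3g}" for k, v in self.params.items())
        return (f"<SubjectFitResults {self.spec.name}: {pars}, "
                f"logZ={self.log_evidence:.2f}>")


def fit_subjects(model: ModelSpec, dataset: Sequence[Sequence[Session]],
                 seed: int = 0, n_restarts: int = 20,
                 **kwargs) -> list[SubjectFitResults]:
    """Independent (non-hierarchical) MAP fits for every subject.

    This is the estimation step whose parameter estimates feed all
    drug-effect statistics: it avoids the shrinkage coupling between
    sessions that hierarchical fitting would introduce.
    """
    out = []
    ss = np.random.SeedSequence(seed).spawn(len(dataset))
    for sessions, sub_ss in zip(dataset, ss):
        sub_seed = int(sub_ss.generate_state(1)[0] % (2**31))
        out.append(SubjectModel(model, sessions).fit(
            n_restarts=n_restarts, seed=sub_seed, **kwargs))
    return out


def extract_subject_parameters(fits: Sequence[SubjectFitResults]) -> pd.DataFrame:
    """Constrained-scale MAP parameter table, one row per subject."""
    rows = []
    for i, f in enumerate(fits):
        if not f.converged:
            raise RuntimeError(f"fit for subject index {i} did not converge")
        row = {"subject": i, **f.params}
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def parameter_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group median and 25-75% range per parameter."""
    return pd.DataFrame({
        "median": table.median(),
        "q25": table.quantile(0.25),
        "q75": table.quantile(0.75),
    })
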