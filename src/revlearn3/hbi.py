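"""Hierarchical Bayesian inference (HBI) across subjects and models.

A random-effects scheme in the spirit of the cbm toolbox: each subject is
assigned soft responsibilities over candidate models; per-model group
Gaussians (diagonal) act as empirical priors for the subject-level Laplace
fits, and a Dirichlet posterior over model frequencies drives model
comparison.  Iterating (subject MAP fits under group priors) <-> (group
moment / Dirichlet updates) is an EM-like coordinate ascent on a variational
free energy

    F = sum_n logsumexp_m [ L_nm + E(ln p_m) ] - KL( Dir(alpha) || Dir(alpha0) )

where L_nm is subject n's Laplace log evidence under model m's group prior
and E(ln p_m) = psi(alpha_m) - psi(sum alpha).

Model selection uses the protected exceedance probability: the probability
that a model is the most frequent in the population, shrunk toward 1/K by
the Bayes omnibus risk (BOR), the posterior probability that all models are
in fact equally frequent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import beta as beta_dist

from .fitting import MAPFit, fit_map
from .models import ModelSpec, nll_and_grad
from .task import Session

__all__ = ["HBI", "HBIResults", "exceedance_probability",
           "protected_exceedance_probability", "dirichlet_kl"]


def dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL( Dir(alpha) || Dir(alpha0) )."""
    a = np.asarray(alpha, float)
    a0 = np.asarray(alpha0, float)
    asum, a0sum = a.sum(), a0.sum()
    return float(
        gammaln(asum) - gammaln(a).sum()
        - gammaln(a0sum) + gammaln(a0).sum()
        + np.sum((a - a0) * (digamma(a) - digamma(asum)))
    )


def exceedance_probability(alpha: np.ndarray, seed: int = 0,
                           n_samples: int = 1_000_000) -> np.ndarray:
    """P(model m has the largest frequency) under Dir(alpha).

    Exact Beta tail integral for K=2, seeded Monte Carlo otherwise.
    """
    a = np.asarray(alpha, float)
    if a.ndim != 1 or len(a) < 2 or np.any(a <= 0):
        raise ValueError("alpha must be a vector of positive concentrations")
    if len(a) == 2:
        # p1 ~ Beta(a1, a2); P(p1 > 1/2)
        p1 = beta_dist.sf(0.5, a[0], a[1])
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    xp = np.zeros(len(a))
    chunk = 200_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(a, size=m)
        winners = np.argmax(draws, axis=1)
        xp += np.bincount(winners, minlength=len(a))
        remaining -= m
    return xp / n_samples


def protected_exceedance_probability(alpha: np.ndarray, bor: float,
                                     seed: int = 0,
                                     n_samples: int = 1_000_000) -> np.ndarray:
    """pxp_m = (1 - BOR) * xp_m + BOR / K."""
    if not 0.0 <= bor <= 1.0:
        raise ValueError("BOR must lie in [0, 1]")
    xp = exceedance_probability(alpha, seed=seed, n_samples=n_samples)
    k = len(xp)
    return (1.0 - bor) * xp + bor / k


@dataclass
class HBIResults:
    """Group-level result of the hierarchical fit."""

    model_names: list
    alpha: np.ndarray                 # Dirichlet concentrations
    responsibilities: np.ndarray      # (n_subjects, K), rows sum to 1
    group_mean: list                  # per model: unconstrained mean vector
    group_var: list                   # per model: unconstrained variance vector
    subject_params: list              # per model: (n_subjects, d) MAP matrix
    log_evidence: np.ndarray          # (n_subjects, K) Laplace evidences (final)
    free_energy_trace: np.ndarray
    converged: bool
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    seed: int

    @property
    def model_frequency(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.model_names,
            "frequency": self.model_frequency,
            "alpha": self.alpha,
            "xp": self.xp,
            "pxp": self.pxp,
            "bor": self.bor,
        })

    def group_parameter_table(self, model: "ModelSpec") -> pd.DataFrame:
        """Constrained-scale group posterior means for one model."""
        m = self.model_names.index(model.name)
        mu = np.asarray(self.group_mean[m])
        vals = model.constrain(mu)
        return pd.DataFrame({"param": model.param_names,
                             "group_mean_constrained": vals,
                             "group_mean_unconstrained": mu,
                             "group_var_unconstrained": self.group_var[m]})

    def plot(self, ax=None):
        """Bar plot of model frequency and pxp."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.model_names) + 2, 3))
        x = np.arange(len(self.model_names))
        ax.bar(x - 0.2, self.model_frequency, width=0.4, label="model frequency")
        ax.bar(x + 0.2, self.pxp, width=0.4, label="pxp")
        ax.set_xticks(x, self.model_names, rotation=30, ha="right")
        ax.set_ylim(0, 1)
        ax.legend(frameon=False)
        return ax


class HBI:
    """Hierarchical model comparison over a cohort.

    Parameters
    ----------
    dataset : sequence of per-subject session lists
    models : sequence of ModelSpec
    prior_var : float
        Variance of the top-level prior on unconstrained parameters; also
        the initial group variance.
    alpha0 : float
        Symmetric Dirichlet prior concentration over models.
    b0 : float
        Weak regulariser added to the group-variance update; keeps variances
        bounded away from 0 when a model claims few subjects.
    """

    def __init__(self, dataset: Sequence[Sequence[Session]],
                 models: Sequence[ModelSpec], seed: int = 0,
                 prior_var: float = 10.0, alpha0: float = 1.0, b0: float = 1.0):
        self.dataset = [list(s) if not isinstance(s, Session) else [s] for s in dataset]
        self.models = list(models)
        if len(self.dataset) < 2:
            raise ValueError("HBI needs at least 2 subjects")
        if len(self.models) < 1:
            raise ValueError("HBI needs at least 1 model")
        self.seed = seed
        self.prior_var = prior_var
        self.alpha0 = alpha0
        self.b0 = b0

    def _fit_cell(self, sessions, model, mu, var, x0, n_restarts, seed, gtol) -> MAPFit:
        return fit_map(lambda x: nll_and_grad(model, x, sessions),
                       model.n_params, mu, var, n_restarts=n_restarts,
                       seed=seed, x0=x0, gtol=gtol)

    def fit(self, max_iter: int = 30, tol: float = 0.05,
            n_restarts_init: int = 4, gtol: float = 1e-5,
            verbose: bool = False) -> HBIResults:
        n = len(self.dataset)
        K = len(self.models)
        rng_seeds = np.random.SeedSequence(self.seed).generate_state(n * K + 1) % (2**31)
        mc_seed = int(rng_seeds[-1])

        mu = [np.zeros(m.n_params) for m in self.models]
        var = [np.full(m.n_params, self.prior_var) for m in self.models]
        theta = [np.zeros((n, m.n_params)) for m in self.models]
        cvar = [np.full((n, m.n_params), self.prior_var) for m in self.models]
        L = np.zeros((n, K))

        def refit_all(n_restarts, warm):
            for m_idx, model in enumerate(self.models):
                for s_idx, sessions in enumerate(self.dataset):
                    x0 = theta[m_idx][s_idx] if warm else None
                    fit = self._fit_cell(
                        sessions, model, mu[m_idx], var[m_idx], x0,
                        n_restarts, int(rng_seeds[m_idx * n + s_idx]), gtol)
                    theta[m_idx][s_idx] = fit.x
                    cvar[m_idx][s_idx] = np.diag(fit.posterior_cov)
                    L[s_idx, m_idx] = fit.log_evidence

        refit_all(n_restarts_init, warm=False)

        alpha = np.full(K, self.alpha0)
        a0 = np.full(K, self.alpha0)
        trace = []
        converged = False
        r = np.full((n, K), 1.0 / K)
        for it in range(max_iter):
            eln_p = digamma(alpha) - digamma(alpha.sum())
            logr = L + eln_p
            logr -= logsumexp(logr, axis=1, keepdims=True)
            r = np.exp(logr)
            alpha = a0 + r.sum(axis=0)
            # group moment updates (diagonal)
            for m_idx in range(K):
                w = r[:, m_idx]
                R = w.sum()
                if R < 1e-12:
                    continue
                mu[m_idx] = (w[:, None] * theta[m_idx]).sum(axis=0) / R
                dev2 = (theta[m_idx] - mu[m_idx]) ** 2 + cvar[m_idx]
                var[m_idx] = ((w[:, None] * dev2).sum(axis=0) + self.b0) / (R + 1.0)
            # subject refits under updated group priors (warm-started)
            refit_all(1, warm=True)
            eln_p = digamma(alpha) - digamma(alpha.sum())
            F = float(logsumexp(L + eln_p, axis=1).sum() - dirichlet_kl(alpha, a0))
            trace.append(F)
            if verbose:
                print(f"HBI iter {it}: F = {F:.3f}")
            if it > 0 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break

        eln_p = digamma(alpha) - digamma(alpha.sum())
        logr = L + eln_p
        logr -= logsumexp(logr, axis=1, keepdims=True)
        r = np.exp(logr)

        if K == 1:
            xp = np.array([1.0])
            bor = 0.0
            pxp = np.array([1.0])
        else:
            xp = exceedance_probability(alpha, seed=mc_seed)
            f1 = trace[-1]
            f0 = float(logsumexp(L - np.log(K), axis=1).sum())
            bor = float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -500, 500))))
            pxp = (1.0 - bor) * xp + bor / K
        return HBIResults(
            model_names=[m.name for m in self.models], alpha=alpha,
            responsibilities=r, group_mean=mu, group_var=var,
            subject_params=theta, log_evidence=L.copy(),
            free_energy_trace=np.asarray(trace), converged=converged,
            xp=xp, bor=bor, pxp=pxp, seed=self.seed)
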