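"""Behavioural measures and statistics for the 3-option reversal task.

Accuracy is summarised per phase by two chance-corrected probabilities:
selecting the mostly-rewarded stimulus (pReward; chance 1/3) and avoiding
the mostly-punished stimulus (pAvoidPunish; chance 2/3).  "Rewarded" and
"punished" are re-evaluated per phase: after the reversal the P-R stimulus
is the rewarded one.  The neutral stimulus acts as implicit baseline.

Two correction conventions for avoidance are provided, because subtracting
the literal 1/3 leaves chance-level avoidance at +1/3 rather than 0:

* ``"chance"`` (default): corrected = (1 - pPunish) - 2/3, so a uniform
  chooser scores 0 on both valence metrics;
* ``"third"``: corrected = (1 - pPunish) - 1/3.

The repeated-measures ANOVA is the 2 (Valence) x 2 (Phase) x 2 (Drug)
within-subject design with mean-centred continuous covariates (WM span,
impulsivity).  With 2-level factors every within-subject effect is a single
subject-wise contrast, so each F test is the squared t of that contrast's
regression on [1, covariates]; the Huynh-Feldt epsilon is identically 1
(sphericity cannot be violated with two levels) and is reported as such.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import ROLE_NN, ROLE_PR, ROLE_RP, Session, TaskConfig

__all__ = ["filter_fast_rt", "accuracy_metrics", "metrics_from_probs",
           "accuracy_table", "stay_probabilities", "rm_anova",
           "simple_effects", "performance_change", "parameter_change_stats",
           "wm_median_split"]

WITHIN_FACTORS = ("valence", "phase", "drug")
_LEVELS = {"valence": ("pReward", "pAvoidPunish"),
           "phase": ("acquisition", "reversal"),
           "drug": ("MPH", "placebo")}


# ---------------------------------------------------------------------------
# trial filtering and accuracy
# ---------------------------------------------------------------------------

def filter_fast_rt(session: Session, threshold_ms: float = 200.0):
    """Drop trials with reaction time strictly below the threshold.

    Returns ``(filtered_session, n_excluded)``; the input is untouched.  A
    session without RTs is returned unchanged (count 0): the filter cannot
    apply.
    """
    if session.rt_ms is None:
        return session, 0
    keep = session.rt_ms >= threshold_ms
    n_excluded = int((~keep).sum())
    if n_excluded == 0:
        return session, 0
    filtered = Session(
        subject_id=session.subject_id, drug_label=session.drug_label,
        choices=session.choices[keep], outcomes=session.outcomes[keep],
        config=session.config, rt_ms=session.rt_ms[keep],
        wm_span=session.wm_span, bis=session.bis)
    # keep the original trial phases: filtering must not shift the boundary
    filtered._phases = session.phases[keep]
    return filtered, n_excluded


def _session_phases(session: Session) -> np.ndarray:
    return getattr(session, "_phases", session.phases)


def _phase_metrics(block: np.ndarray, phase: str, avoid_convention: str) -> dict:
    if avoid_convention not in ("chance", "third"):
        raise ValueError(f"unknown avoid convention {avoid_convention!r}")
    if block.shape[0] == 0:
        raise ValueError(f"empty {phase} phase")
    rewarded = ROLE_RP if phase == "acquisition" else ROLE_PR
    punished = ROLE_PR if phase == "acquisition" else ROLE_RP
    p_rew = float(block[:, rewarded].mean())
    p_pun = float(block[:, punished].mean())
    p_neu = float(block[:, ROLE_NN].mean())
    avoid_offset = 2.0 / 3.0 if avoid_convention == "chance" else 1.0 / 3.0
    return {
        "pReward_raw": p_rew, "pPunish_raw": p_pun, "pNeutral_raw": p_neu,
        "pReward_corrected": p_rew - 1.0 / 3.0,
        "pAvoidPunish_corrected": (1.0 - p_pun) - avoid_offset,
        "pNeutral_corrected": p_neu - 1.0 / 3.0,
    }


def metrics_from_probs(probs: np.ndarray, config: TaskConfig,
                       avoid_convention: str = "chance") -> dict:
    """Chance-corrected accuracy metrics from an (n_trials, 3) matrix of
    per-trial choice probabilities (one-hot for observed sessions)."""
    probs = np.asarray(probs, dtype=float)
    acq_len = config.reversal_trial - 1
    return {
        "acquisition": _phase_metrics(probs[:acq_len], "acquisition", avoid_convention),
        "reversal": _phase_metrics(probs[acq_len:], "reversal", avoid_convention),
    }


def _one_hot(session: Session, phases: np.ndarray, phase: str) -> np.ndarray:
    mask = phases == phase
    oh = np.zeros((int(mask.sum()), session.config.n_options))
    oh[np.arange(oh.shape[0]), session.choices[mask]] = 1.0
    return oh


def accuracy_metrics(session: Session, config: Optional[TaskConfig] = None,
                     avoid_convention: str = "chance") -> dict:
    """Per-phase accuracy metrics for one observed session.

    Works on RT-filtered sessions (phase membership of remaining trials is
    preserved by the filter).
    """
    phases = _session_phases(session)
    out = {}
    for phase in ("acquisition", "reversal"):
        oh = _one_hot(session, phases, phase)
        out[phase] = _phase_metrics(oh, phase, avoid_convention)
    return out


def accuracy_table(dataset: Sequence[Sequence[Session]],
                   avoid_convention: str = "chance",
                   rt_filter_ms: Optional[float] = None) -> pd.DataFrame:
    """Long-format accuracy table over a cohort.

    One row per subject x drug x phase x valence, with the chance-corrected
    value in ``value`` and subject covariates attached.  ``rt_filter_ms``
    applies the fast-RT filter first (the robustness-check variant).
    """
    rows = []
    for sessions in dataset:
        for sess in sessions:
            if rt_filter_ms is not None:
                sess, _ = filter_fast_rt(sess, rt_filter_ms)
            m = accuracy_metrics(sess, avoid_convention=avoid_convention)
            for phase, metrics in m.items():
                for valence in ("pReward", "pAvoidPunish"):
                    rows.append({
                        "subject": sess.subject_id, "drug": sess.drug_label,
                        "phase": phase, "valence": valence,
                        "value": metrics[f"{valence}_corrected"],
                        "pNeutral_corrected": metrics["pNeutral_corrected"],
                        "wm_span": sess.wm_span, "bis": sess.bis,
                    })
    return pd.DataFrame(rows)


def stay_probabilities(session: Session) -> pd.DataFrame:
    """P(repeat current choice on the next trial), split by the current
    trial's outcome (win/loss) and phase.

    The phase bin is the *current* trial's phase; bins with no qualifying
    trials report NaN.
    """
    if session.n_trials < 2:
        raise ValueError("need at least 2 trials")
    stay = session.choices[1:] == session.choices[:-1]
    outcome = session.outcomes[:-1]
    phases = _session_phases(session)[:-1]
    rows = []
    for phase in ("acquisition", "reversal"):
        for label, sign in (("win", 1.0), ("loss", -1.0)):
            mask = (phases == phase) & (outcome == sign)
            rows.append({
                "phase": phase, "outcome": label,
                "p_stay": float(stay[mask].mean()) if mask.any() else np.nan,
                "n_trials": int(mask.sum()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with continuous covariates
# ---------------------------------------------------------------------------

def _cell_matrix(table: pd.DataFrame, factors: Sequence[str],
                 covariates: Sequence[str]):
    """Wide per-subject cell means + covariates; errors on missing cells."""
    for f in factors:
        levels = set(table[f].unique())
        if levels != set(_LEVELS[f]):
            raise ValueError(f"factor {f!r}: expected levels {_LEVELS[f]}, got {sorted(levels)}")
    wide = table.pivot_table(index="subject", columns=list(factors),
                             values="value", aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any(axis=0)].tolist()
        raise ValueError(f"unbalanced design; missing cells: {missing}")
    if not covariates:
        return wide, pd.DataFrame(index=wide.index)
    cov = table.groupby("subject")[list(covariates)].first()
    return wide, cov.loc[wide.index]


def _ols_f_tests(y: np.ndarray, X: np.ndarray):
    """F, p and partial eta^2 for each coefficient of a small OLS fit."""
    n, k = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df2 = n - k
    sigma2 = float(resid @ resid) / df2
    xtx_inv = np.linalg.inv(X.T @ X)
    out = []
    for j in range(k):
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        t = coef[j] / se if se > 0 else np.inf
        F = t * t
        p = float(stats.f.sf(F, 1, df2))
        out.append((float(F), 1, df2, p, float(F / (F + df2))))
    return out


def rm_anova(table: pd.DataFrame,
             covariates: Sequence[str] = ("wm_span", "bis"),
             factors: Sequence[str] = WITHIN_FACTORS) -> pd.DataFrame:
    """Full-factorial within-subject ANOVA with continuous covariates.

    ``table`` is the long accuracy table (columns subject, value, the
    within factors, and the covariates).  Covariates are mean-centred.
    Every within-subject effect (and its interaction with each covariate)
    is tested by regressing the subject-wise +-1 contrast on
    ``[1, covariates]``; rows named ``Intercept``/covariate alone are the
    between-subject effects on the overall mean.

    Returns a report with F, df, p, partial eta^2, the Huynh-Feldt epsilon
    (1 for 2-level factors) and the corrected p (equal to p here).
    """
    factors = [f for f in factors if f in table.columns]
    cov_names = list(covariates)
    wide, cov = _cell_matrix(table, factors, cov_names)
    n = wide.shape[0]
    X = np.column_stack([np.ones(n)] +
                        [cov[c].to_numpy(float) - cov[c].to_numpy(float).mean()
                         for c in cov_names])
    cols = list(wide.columns) if len(factors) > 1 else [(c,) for c in wide.columns]

    rows = []
    from itertools import combinations
    effect_sets = [()] + [c for r in range(1, len(factors) + 1)
                          for c in combinations(factors, r)]
    pretty = {"valence": "Valence", "phase": "Phase", "drug": "Drug",
              "wm_span": "WM", "bis": "BIS"}
    for eff in effect_sets:
        signs = np.ones(len(cols))
        for fi, f in enumerate(factors):
            if f in eff:
                first_level = _LEVELS[f][0]
                signs *= np.array([1.0 if col[fi] == first_level else -1.0
                                   for col in cols])
        scores = wide.to_numpy(float) @ (signs / len(cols))
        tests = _ols_f_tests(scores, X)
        base = " x ".join(pretty[f] for f in eff) if eff else "Intercept"
        for j, name in enumerate([None] + cov_names):
            F, df1, df2, p, eta = tests[j]
            label = base if name is None else (
                pretty.get(name, name) if not eff else f"{base} x {pretty.get(name, name)}")
            rows.append({"effect": label, "F": F, "df1": df1, "df2": df2,
                         "p": p, "partial_eta2": eta,
                         "hf_epsilon": 1.0, "p_hf": p})
    return pd.DataFrame(rows)


def simple_effects(table: pd.DataFrame, split_by: str,
                   covariates: Sequence[str] = ("wm_span", "bis")) -> dict:
    """Re-run the omnibus ANOVA within each level of one factor.

    Follows the convention of refitting the model within each level (the
    error term comes from that level's data only).
    """
    if split_by not in table.columns:
        raise ValueError(f"unknown factor {split_by!r}")
    levels = sorted(table[split_by].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {split_by!r} has fewer than 2 levels")
    remaining = [f for f in WITHIN_FACTORS if f != split_by and f in table.columns]
    out = {}
    for level in levels:
        sub = table[table[split_by] == level]
        out[level] = rm_anova(sub, covariates=covariates, factors=remaining)
    return out


# ---------------------------------------------------------------------------
# drug effects on fitted parameters
# ---------------------------------------------------------------------------

def wm_median_split(wm: pd.Series) -> pd.Series:
    """Low/high working-memory grouping for visualisation: scores at or
    below the median go to the low group (with n=102 integer scores this
    yields the slightly larger low group)."""
    return pd.Series(np.where(wm <= wm.median(), "low", "high"),
                     index=wm.index, name="wm_group")


def performance_change(table: pd.DataFrame) -> pd.Series:
    """Per-subject drug-induced change in raw performance: the mean
    corrected accuracy (over phases and valences) on MPH minus placebo."""
    per = table.groupby(["subject", "drug"])["value"].mean().unstack("drug")
    return per["MPH"] - per["placebo"]


def parameter_change_stats(param_table: pd.DataFrame,
                           covariates: pd.DataFrame,
                           performance_delta: Optional[pd.Series] = None,
                           param: str = "phi") -> dict:
    """Drug-effect statistics on a split parameter.

    Paired t-test of ``<param>_MPH`` vs ``<param>_placebo`` across subjects
    and Spearman correlations of the per-subject difference with WM span,
    impulsivity, and (optionally) the drug-induced raw-performance change.
    """
    c_m, c_p = f"{param}_MPH", f"{param}_placebo"
    if c_m not in param_table or c_p not in param_table:
        raise ValueError(f"param table lacks {c_m}/{c_p}")
    if len(param_table) < 3:
        raise ValueError("need at least 3 subjects")
    delta = param_table[c_m] - param_table[c_p]
    t, p_t = stats.ttest_rel(param_table[c_m], param_table[c_p])
    if np.allclose(delta, 0):
        t, p_t = 0.0, 1.0
    out = {"delta_mean": float(delta.mean()), "t": float(t), "p_t": float(p_t),
           "n": int(len(delta))}
    cov = covariates.loc[param_table.index]
    for key, series in (("wm", cov["wm_span"]), ("bis", cov["bis"])):
        r, p = stats.spearmanr(delta, series)
        out[f"spearman_{key}_r"] = float(r)
        out[f"spearman_{key}_p"] = float(p)
    if performance_delta is not None:
        perf = performance_delta.loc[param_table.index]
        r, p = stats.spearmanr(delta, perf)
        out["spearman_perf_r"] = float(r)
        out["spearman_perf_p"] = float(p)
    return out
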