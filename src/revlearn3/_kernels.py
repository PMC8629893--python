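"""Numba-compiled inner loops: trial-wise likelihoods with analytic gradients,
and agent simulation.

The recursions are cheap but strictly sequential, so they are JIT-compiled
and the gradients of the value trajectories are propagated forward alongside
the values themselves.  Gradients returned here are on the *constrained*
parameter scale; callers apply the transform Jacobians.

Parameter slot convention (both families):
  slot 0: phi (EWA payoff decay) / eta (hybrid learning rate)
  slot 1: rho (EWA experience decay) / kappa (hybrid associability rate)
  slot 2: beta (softmax inverse temperature)
  slot 3: alpha_f (forgetting rate for unchosen options; 0 disables)
"""

import numpy as np
from numba import njit

FAMILY_EWA = 0
FAMILY_HYBRID = 1


@njit(cache=True)
def sample_outcome_block(n_plus, n_minus, max_run, seed):
    """Exactly uniform draw from the arrangements of n_plus (+1) and
    n_minus (-1) outcomes whose longest identical run is <= max_run.

    Sequential sampling weighted by a dynamic-programming count of valid
    completions; f[p, m, last, run-1] counts valid suffixes with p/m
    symbols remaining after a run of `run` copies of `last` (0:+1, 1:-1).
    Returns a first element of -2 when the constraint is unsatisfiable.
    """
    np.random.seed(seed)
    P, M = n_plus, n_minus
    n = P + M
    R = max_run if max_run < n else n
    out = np.empty(n, dtype=np.int8)
    if n == 0:
        return out
    if R < 1:
        out[0] = -2
        return out
    f = np.zeros((P + 1, M + 1, 2, R))
    for p in range(P + 1):
        for m in range(M + 1):
            for last in range(2):
                for run in range(1, R + 1):
                    if p == 0 and m == 0:
                        f[p, m, last, run - 1] = 1.0
                        continue
                    tot = 0.0
                    if p > 0:
                        if last == 0:
                            if run < R:
                                tot += f[p - 1, m, 0, run]
                        else:
                            tot += f[p - 1, m, 0, 0]
                    if m > 0:
                        if last == 1:
                            if run < R:
                                tot += f[p, m - 1, 1, run]
                        else:
                            tot += f[p, m - 1, 1, 0]
                    f[p, m, last, run - 1] = tot
    p, m = P, M
    last = -1
    run = 0
    for i in range(n):
        wp = 0.0
        wm = 0.0
        if p > 0:
            if last == 0:
                if run < R:
                    wp = f[p - 1, m, 0, run]
            else:
                wp = f[p - 1, m, 0, 0]
        if m > 0:
            if last == 1:
                if run < R:
                    wm = f[p, m - 1, 1, run]
            else:
                wm = f[p, m - 1, 1, 0]
        tot = wp + wm
        if tot <= 0.0:
            out[0] = -2
            return out
        if np.random.random() * tot < wp:
            out[i] = 1
            run = run + 1 if last == 0 else 1
            last = 0
            p -= 1
        else:
            out[i] = -1
            run = run + 1 if last == 1 else 1
            last = 1
            m -= 1
    return out


@njit(cache=True)
def _softmax3(V, beta, p):
    m0 = beta * V[0]
    m1 = beta * V[1]
    m2 = beta * V[2]
    mx = max(m0, max(m1, m2))
    e0 = np.exp(m0 - mx)
    e1 = np.exp(m1 - mx)
    e2 = np.exp(m2 - mx)
    Z = e0 + e1 + e2
    p[0] = e0 / Z
    p[1] = e1 / Z
    p[2] = e2 / Z
    return mx + np.log(Z)


@njit(cache=True)
def ewa_nll_grad(choices, outcomes, phi, rho, beta, alpha_f):
    """Session NLL and gradient for the EWA(+forgetting) model.

    Value update (chosen option c, feedback lam in {-1,+1}):
        n_c <- n_c * rho + 1
        V_c <- (V_c * phi * n_c_old + lam) / n_c_new
    Unchosen options decay toward 0: V_j <- (1 - alpha_f) * V_j.
    Returns (nll, grad) with grad on the constrained (phi, rho, beta,
    alpha_f) scale.
    """
    V = np.zeros(3)
    n = np.ones(3)
    G = np.zeros((3, 3))  # dV/d(phi, rho, alpha_f)
    dn = np.zeros(3)      # dn/drho
    p = np.zeros(3)
    g = np.zeros(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        lam = outcomes[t]
        lse = _softmax3(V, beta, p)
        nll -= beta * V[c] - lse
        vbar = p[0] * V[0] + p[1] * V[1] + p[2] * V[2]
        g[2] -= V[c] - vbar
        for j in range(3):
            ind = 1.0 if j == c else 0.0
            dLdV = -beta * (ind - p[j])
            g[0] += dLdV * G[j, 0]
            g[1] += dLdV * G[j, 1]
            g[3] += dLdV * G[j, 2]
        # chosen-option update
        n_old = n[c]
        dn_old = dn[c]
        n_new = n_old * rho + 1.0
        dn_new = dn_old * rho + n_old
        v_old = V[c]
        v_new = (v_old * phi * n_old + lam) / n_new
        g_phi = (G[c, 0] * phi * n_old + v_old * n_old) / n_new
        g_rho = (G[c, 1] * phi * n_old + v_old * phi * dn_old) / n_new - v_new * dn_new / n_new
        g_af = (G[c, 2] * phi * n_old) / n_new
        V[c] = v_new
        n[c] = n_new
        dn[c] = dn_new
        G[c, 0] = g_phi
        G[c, 1] = g_rho
        G[c, 2] = g_af
        # forgetting of unchosen values (no-op when alpha_f == 0)
        keep = 1.0 - alpha_f
        for j in range(3):
            if j != c:
                G[j, 2] = keep * G[j, 2] - V[j]
                G[j, 0] *= keep
                G[j, 1] *= keep
                V[j] *= keep
    return nll, g


@njit(cache=True)
def hybrid_nll_grad(choices, outcomes, eta, kappa, beta, alpha_f):
    """Session NLL and gradient for the Pearce-Hall hybrid model.

    delta = lam - V_c;  V_c <- V_c + eta * a_c * delta;
    a_c <- (1 - kappa) * a_c + kappa * |delta|  (associability, init 1).
    Unchosen values forgotten as in the EWA family.
    """
    V = np.zeros(3)
    a = np.ones(3)
    G = np.zeros((3, 3))  # dV/d(eta, kappa, alpha_f)
    A = np.zeros((3, 3))  # da/d(eta, kappa, alpha_f)
    p = np.zeros(3)
    g = np.zeros(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        lam = outcomes[t]
        lse = _softmax3(V, beta, p)
        nll -= beta * V[c] - lse
        vbar = p[0] * V[0] + p[1] * V[1] + p[2] * V[2]
        g[2] -= V[c] - vbar
        for j in range(3):
            ind = 1.0 if j == c else 0.0
            dLdV = -beta * (ind - p[j])
            g[0] += dLdV * G[j, 0]
            g[1] += dLdV * G[j, 1]
            g[3] += dLdV * G[j, 2]
        delta = lam - V[c]
        a_c = a[c]
        sgn = 0.0
        if delta > 0.0:
            sgn = 1.0
        elif delta < 0.0:
            sgn = -1.0
        # effective learning rate capped at 1: with feedback in {-1,+1} the
        # associability can exceed 1/eta and the uncapped recursion diverges
        lr = eta * a_c
        if lr >= 1.0:
            lr = 1.0
            dlr0 = 0.0  # d lr / d eta
            dlrA0 = 0.0
            dlrA1 = 0.0
            dlrA2 = 0.0
        else:
            dlr0 = a_c
            dlrA0 = eta * A[c, 0]
            dlrA1 = eta * A[c, 1]
            dlrA2 = eta * A[c, 2]
        # new dV/dtheta uses old associability derivatives and old G row
        g0 = G[c, 0] + (dlr0 + dlrA0) * delta - lr * G[c, 0]
        g1 = G[c, 1] + dlrA1 * delta - lr * G[c, 1]
        g2 = G[c, 2] + dlrA2 * delta - lr * G[c, 2]
        # associability derivatives use the pre-update G row via d|delta|
        A0 = (1.0 - kappa) * A[c, 0] - kappa * sgn * G[c, 0]
        A1 = (1.0 - kappa) * A[c, 1] + (np.abs(delta) - a_c) - kappa * sgn * G[c, 1]
        A2 = (1.0 - kappa) * A[c, 2] - kappa * sgn * G[c, 2]
        V[c] = V[c] + lr * delta
        a[c] = (1.0 - kappa) * a_c + kappa * np.abs(delta)
        G[c, 0], G[c, 1], G[c, 2] = g0, g1, g2
        A[c, 0], A[c, 1], A[c, 2] = A0, A1, A2
        keep = 1.0 - alpha_f
        for j in range(3):
            if j != c:
                G[j, 2] = keep * G[j, 2] - V[j]
                G[j, 0] *= keep
                G[j, 1] *= keep
                V[j] *= keep
    return nll, g


@njit(cache=True)
def simulate_session_kernel(family, schedule, p0, p1, beta, alpha_f, u, fix_first):
    """Roll one agent through a schedule; returns (choices, outcomes).

    ``u`` is a vector of uniforms, one per trial.  With ``fix_first`` the
    first choice is role 0 by construction: the mostly-rewarded acquisition
    stimulus (R-P) is *defined* as whichever stimulus the agent picks first,
    so in role space the first choice is always R-P.  Works for any number
    of options (the 2-option comparison task reuses it).
    """
    T = schedule.shape[0]
    K = schedule.shape[1]
    choices = np.zeros(T, dtype=np.int64)
    outcomes = np.zeros(T)
    V = np.zeros(K)
    n = np.ones(K)
    a = np.ones(K)
    p = np.zeros(K)
    for t in range(T):
        if t == 0 and fix_first:
            c = 0
        else:
            mx = V[0]
            for j in range(1, K):
                if V[j] > mx:
                    mx = V[j]
            Z = 0.0
            for j in range(K):
                p[j] = np.exp(beta * (V[j] - mx))
                Z += p[j]
            r = u[t] * Z
            acc = 0.0
            c = K - 1
            for j in range(K):
                acc += p[j]
                if r < acc:
                    c = j
                    break
        lam = float(schedule[t, c])
        choices[t] = c
        outcomes[t] = lam
        if family == FAMILY_EWA:
            n_new = n[c] * p1 + 1.0
            V[c] = (V[c] * p0 * n[c] + lam) / n_new
            n[c] = n_new
        else:
            delta = lam - V[c]
            lr = min(p0 * a[c], 1.0)
            V[c] = V[c] + lr * delta
            a[c] = (1.0 - p1) * a[c] + p1 * np.abs(delta)
        keep = 1.0 - alpha_f
        for j in range(K):
            if j != c:
                V[j] *= keep
    return choices, outcomes
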