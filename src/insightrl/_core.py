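"""Jitted inner loops for the Q-learning model.

The value recursion is inherently sequential in trials, so the hot paths
(likelihood evaluation inside the MAP optimizer, forward simulation of large
cohorts) run as numba kernels. Every kernel has a pure-Python counterpart in
the test suite that recomputes the same quantities with explicit scalar
arithmetic; the kernels are the implementation, never their own oracle.

Parameter vectors are ordered (beta, mu, nu, alpha_pos, alpha_neg, lam, phi).
Box indices: 0 = right, 1 = left.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# transformed-coordinate layout used by the MAP optimizer:
# x = [log beta, log mu, log nu, logit a+, logit a-, log lam, phi]

_BIG = 1e12  # penalty returned for numerically invalid points


@njit(cache=False)
def _utility(reward: float, mu: float, nu: float, lam: float) -> float:
    if reward > 0.0:
        return reward ** mu
    if reward < 0.0:
        return -lam * (-reward) ** nu
    return 0.0


@njit(cache=False)
def _p_right(q_right: float, q_left: float, beta: float) -> float:
    # overflow-safe softmax over two actions
    ar = beta * q_right
    al = beta * q_left
    m = ar if ar > al else al
    er = math.exp(ar - m)
    el = math.exp(al - m)
    return er / (er + el)


@njit(cache=False)
def loglik(choices, rewards, beta, mu, nu, alpha_pos, alpha_neg, lam, phi):
    """Sum over trials of log P(choice_t | Q_t) under the model recursion.

    The per-trial log probability is computed directly by log-sum-exp, so it
    stays finite (if astronomically negative) even where the softmax
    probability itself would underflow — which keeps the MAP search landscape
    smooth far from the optimum.
    """
    qr = 0.0
    ql = 0.0
    total = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        ar = beta * qr
        al = beta * ql
        m = ar if ar > al else al
        lse = m + math.log(math.exp(ar - m) + math.exp(al - m))
        total += (ar if c == 0 else al) - lse
        u = _utility(rewards[t], mu, nu, lam)
        qc = qr if c == 0 else ql
        d = u - qc
        a = alpha_pos if d >= 0.0 else alpha_neg
        qc = qc + a * d + phi
        if c == 0:
            qr = qc
        else:
            ql = qc
    if math.isnan(total):
        return -np.inf
    return total


@njit(cache=False)
def replay(choices, rewards, beta, mu, nu, alpha_pos, alpha_neg, lam, phi):
    """Trial-by-trial traces for a fixed choice/reward sequence.

    Returns (utility, delta, p_right, q_right_before, q_left_before,
    q_right_after, q_left_after) arrays aligned with trials.
    """
    n = choices.shape[0]
    util = np.empty(n)
    delta = np.empty(n)
    p_right = np.empty(n)
    qr_b = np.empty(n)
    ql_b = np.empty(n)
    qr_a = np.empty(n)
    ql_a = np.empty(n)
    qr = 0.0
    ql = 0.0
    for t in range(n):
        c = choices[t]
        qr_b[t] = qr
        ql_b[t] = ql
        p_right[t] = _p_right(qr, ql, beta)
        u = _utility(rewards[t], mu, nu, lam)
        qc = qr if c == 0 else ql
        d = u - qc
        a = alpha_pos if d >= 0.0 else alpha_neg
        qc = qc + a * d + phi
        if c == 0:
            qr = qc
        else:
            ql = qc
        util[t] = u
        delta[t] = d
        qr_a[t] = qr
        ql_a[t] = ql
    return util, delta, p_right, qr_b, ql_b, qr_a, ql_a


@njit(cache=False)
def simulate(
    u_choice,
    u_reward,
    p_win_right,
    p_win_left,
    reward_win,
    reward_loss,
    beta,
    mu,
    nu,
    alpha_pos,
    alpha_neg,
    lam,
    phi,
):
    """Forward-simulate one agent given per-trial uniforms for choice/reward.

    Choice is sampled by inverse CDF on the softmax (u < P(right) → right);
    the chosen box's outcome is a win iff its uniform falls below that box's
    scheduled win probability. Returns (choices, rewards).
    """
    n = u_choice.shape[0]
    choices = np.empty(n, dtype=np.int64)
    rewards = np.empty(n)
    qr = 0.0
    ql = 0.0
    for t in range(n):
        pr = _p_right(qr, ql, beta)
        c = 0 if u_choice[t] < pr else 1
        p_win = p_win_right[t] if c == 0 else p_win_left[t]
        r = reward_win if u_reward[t] < p_win else reward_loss
        u = _utility(r, mu, nu, lam)
        qc = qr if c == 0 else ql
        d = u - qc
        a = alpha_pos if d >= 0.0 else alpha_neg
        qc = qc + a * d + phi
        if c == 0:
            qr = qc
        else:
            ql = qc
        choices[t] = c
        rewards[t] = r
    return choices, rewards


@njit(cache=False)
def neg_log_posterior_t(
    x,
    choices,
    rewards,
    alpha_a,
    alpha_b,
    gamma_shape,
    gamma_scale,
    phi_mean,
    phi_sd,
):
    """Negative log posterior in transformed coordinates.

    The transform (log for beta/mu/nu/lam, logit for the learning rates,
    identity for phi) is a search device only: the objective is the natural-
    space posterior density, with no Jacobian term added.
    """
    beta = math.exp(x[0])
    mu = math.exp(x[1])
    nu = math.exp(x[2])
    ap = 1.0 / (1.0 + math.exp(-x[3]))
    an = 1.0 / (1.0 + math.exp(-x[4]))
    lam = math.exp(x[5])
    phi = x[6]

    lp = 0.0
    # Beta(alpha_a, alpha_b) on each learning rate
    lbeta = math.lgamma(alpha_a) + math.lgamma(alpha_b) - math.lgamma(alpha_a + alpha_b)
    for a in (ap, an):
        if a <= 0.0 or a >= 1.0:
            return _BIG
        lp += (alpha_a - 1.0) * math.log(a) + (alpha_b - 1.0) * math.log(1.0 - a) - lbeta
    # Gamma(shape, scale) on beta, mu, nu, lam
    lgnorm = math.lgamma(gamma_shape) + gamma_shape * math.log(gamma_scale)
    for v in (beta, mu, nu, lam):
        if v <= 0.0:
            return _BIG
        lp += (gamma_shape - 1.0) * math.log(v) - v / gamma_scale - lgnorm
    # Normal(phi_mean, phi_sd) on phi
    z = (phi - phi_mean) / phi_sd
    lp += -0.5 * z * z - math.log(phi_sd) - 0.5 * math.log(2.0 * math.pi)

    ll = loglik(choices, rewards, beta, mu, nu, ap, an, lam, phi)
    obj = ll + lp
    if not math.isfinite(obj):
        return _BIG
    return -obj
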