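"""Jit-compiled trial loops.

The sequential per-trial recursions (contingency learning -> likelihoods ->
biased posterior -> drifted prediction) cannot be vectorized, and model
fitting evaluates them tens of thousands of times, so the inner loops live
here as numba kernels. ``mabc.model`` exposes the same computations as plain
Python single-step operations; the test suite asserts the two routes agree.
"""
from __future__ import annotations

import numpy as np
from numba import njit

EPS = 1e-6


@njit(cache=True)
def _safe_log(x):
    if x < EPS:
        x = EPS
    return np.log(x)


@njit(cache=True)
def mabc_session_loglik(actions_self, actions_other, outcomes, is_causality,
                        probe_resp, task_start,
                        a_self, a_other, bias_pos, bias_neg, beta0, tau,
                        theta, beta_con,
                        use_other, report_lcr, mirror_update):
    """Joint log-likelihood of outcome-related choices and causality reports.

    Arrays are one entry per trial; ``probe_resp`` is 1 (reported SELF),
    0 (reported OTHER) or -1 (no causality probe). ``task_start`` marks the
    first trial of each task session, where learned contingencies and the
    controllability prediction reset to the uninformative 0.5.

    Returns the total log-likelihood plus the full belief trace:
    (ll, prior_pred, lik_self, lik_other, posterior, lcr, v_left, v_right,
    beta_trial, p_choose_right, p_report_self).
    """
    n = actions_self.shape[0]
    prior_pred = np.empty(n)
    lik_self = np.empty(n)
    lik_other = np.empty(n)
    posterior = np.empty(n)
    lcr = np.empty(n)
    v_left = np.empty(n)
    v_right = np.empty(n)
    beta_trial = np.empty(n)
    p_choose_right = np.empty(n)
    p_report_self = np.full(n, np.nan)

    p_self = np.empty(2)
    p_oth = np.empty(2)
    pp = 0.5
    ll = 0.0
    for t in range(n):
        if task_start[t]:
            p_self[0] = 0.5
            p_self[1] = 0.5
            p_oth[0] = 0.5
            p_oth[1] = 0.5
            pp = 0.5
        if pp < EPS:
            pp = EPS
        elif pp > 1.0 - EPS:
            pp = 1.0 - EPS
        prior_pred[t] = pp

        # controllability-modulated softmax choice on the learned self values
        beta = beta0 * np.exp(tau * np.log(pp / (1.0 - pp)))
        beta_trial[t] = beta
        vl = p_self[0]
        vr = p_self[1]
        v_left[t] = vl
        v_right[t] = vr
        d = vr - vl
        if d == 0.0:
            p_right = 0.5
        else:
            p_right = 1.0 / (1.0 + np.exp(-beta * d))
        p_choose_right[t] = p_right
        a = actions_self[t]
        ll += _safe_log(p_right if a == 1 else 1.0 - p_right)

        # delta-rule contingency updates for the observed actions
        o = outcomes[t]
        b = actions_other[t]
        p_self[a] += a_self * (o - p_self[a])
        p_oth[b] += a_other * (o - p_oth[b])
        if mirror_update:
            p_self[1 - a] = 1.0 - p_self[a]
            p_oth[1 - b] = 1.0 - p_oth[b]

        # likelihood of the observed outcome under each controller hypothesis
        ls = p_self[a] if o == 1 else 1.0 - p_self[a]
        if use_other:
            lo = p_oth[b] if o == 1 else 1.0 - p_oth[b]
        else:
            lo = 0.5
        lik_self[t] = ls
        lik_other[t] = lo

        # valence-biased Bayesian integration, computed in log space
        bias = bias_pos if o == 1 else bias_neg
        log_num = bias + _safe_log(ls) + np.log(pp)
        log_alt = _safe_log(lo) + np.log(1.0 - pp)
        post = 1.0 / (1.0 + np.exp(log_alt - log_num))
        if post < EPS:
            post = EPS
        elif post > 1.0 - EPS:
            post = 1.0 - EPS
        posterior[t] = post
        lcr[t] = np.log(post / (1.0 - post))

        if is_causality[t]:
            if report_lcr:
                x = beta_con * lcr[t]
            else:
                x = beta_con * (2.0 * post - 1.0)
            pr_self = 1.0 / (1.0 + np.exp(-x))
            p_report_self[t] = pr_self
            r = probe_resp[t]
            if r >= 0:
                ll += _safe_log(pr_self if r == 1 else 1.0 - pr_self)

        pp = (1.0 - theta) * post + 0.5 * theta

    return (ll, prior_pred, lik_self, lik_other, posterior, lcr,
            v_left, v_right, beta_trial, p_choose_right, p_report_self)


@njit(cache=True)
def rw_loglik(actions, outcomes, learning_rate, inv_temp):
    """Log-likelihood of a choice stream under a Rescorla-Wagner softmax."""
    q0 = 0.5
    q1 = 0.5
    ll = 0.0
    for t in range(actions.shape[0]):
        p_right = 1.0 / (1.0 + np.exp(-inv_temp * (q1 - q0)))
        a = actions[t]
        ll += _safe_log(p_right if a == 1 else 1.0 - p_right)
        o = outcomes[t]
        if a == 1:
            q1 += learning_rate * (o - q1)
        else:
            q0 += learning_rate * (o - q0)
    return ll
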