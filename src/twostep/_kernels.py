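"""Numba-compiled inner loops for the hybrid agent.

Parameters enter as a length-7 natural-space vector
``(alpha1, alpha2, lam, omega, beta1, beta2, rho)`` with any model-variant
fixings already applied by the caller.  Coding matches :mod:`twostep.task`:
second-stage state 0 is the common destination of first-stage action 0 and
the walk matrix columns are ordered ``2*state + action``.
"""

import math

import numpy as np
from numba import njit

# indices into the natural-space parameter vector
A1, A2, LAM, OM, B1, B2, RHO = 0, 1, 2, 3, 4, 5, 6

_LOG_FLOOR = 1e-300


@njit(cache=True)
def session_nll(theta, p_common, a1, s2, a2, r):  # pragma: no cover - compiled
    """Negative log-likelihood (nats) of an observed session under the hybrid model."""
    al1, al2, lam, om = theta[A1], theta[A2], theta[LAM], theta[OM]
    b1, b2, rho = theta[B1], theta[B2], theta[RHO]
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    nll = 0.0
    n = a1.shape[0]
    for t in range(n):
        m0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        m1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = p_common * m1 + (1.0 - p_common) * m0
        x0 = b1 * (om * qmb0 + (1.0 - om) * q1[0] + (rho if prev == 0 else 0.0))
        x1 = b1 * (om * qmb1 + (1.0 - om) * q1[1] + (rho if prev == 1 else 0.0))
        m = x0 if x0 > x1 else x1
        e0 = math.exp(x0 - m)
        e1 = math.exp(x1 - m)
        p0 = e0 / (e0 + e1)
        p_choice = p0 if a1[t] == 0 else 1.0 - p0
        nll -= math.log(p_choice if p_choice > _LOG_FLOOR else _LOG_FLOOR)

        s = s2[t]
        y0 = b2 * q2[s, 0]
        y1 = b2 * q2[s, 1]
        m = y0 if y0 > y1 else y1
        e0 = math.exp(y0 - m)
        e1 = math.exp(y1 - m)
        p0 = e0 / (e0 + e1)
        p_choice = p0 if a2[t] == 0 else 1.0 - p0
        nll -= math.log(p_choice if p_choice > _LOG_FLOOR else _LOG_FLOOR)

        d1 = q2[s, a2[t]] - q1[a1[t]]
        q1[a1[t]] += al1 * d1
        d2 = r[t] - q2[s, a2[t]]
        q2[s, a2[t]] += al2 * d2
        q1[a1[t]] += al1 * lam * d2
        prev = a1[t]
    return nll


@njit(cache=True)
def simulate(theta, p_common, walk, seed):  # pragma: no cover - compiled
    """Generative rollout of one session against a reward walk.

    Returns ``(first_choice, second_state, second_choice, reward)`` int64
    arrays of length ``walk.shape[0]``; deterministic given ``seed``.
    """
    np.random.seed(seed)
    al1, al2, lam, om = theta[A1], theta[A2], theta[LAM], theta[OM]
    b1, b2, rho = theta[B1], theta[B2], theta[RHO]
    n = walk.shape[0]
    a1 = np.empty(n, np.int64)
    s2 = np.empty(n, np.int64)
    a2 = np.empty(n, np.int64)
    r = np.empty(n, np.int64)
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    for t in range(n):
        m0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        m1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = p_common * m1 + (1.0 - p_common) * m0
        x0 = b1 * (om * qmb0 + (1.0 - om) * q1[0] + (rho if prev == 0 else 0.0))
        x1 = b1 * (om * qmb1 + (1.0 - om) * q1[1] + (rho if prev == 1 else 0.0))
        m = x0 if x0 > x1 else x1
        e0 = math.exp(x0 - m)
        p0 = e0 / (e0 + math.exp(x1 - m))
        c1 = 0 if np.random.random() < p0 else 1

        s = c1 if np.random.random() < p_common else 1 - c1

        y0 = b2 * q2[s, 0]
        y1 = b2 * q2[s, 1]
        m = y0 if y0 > y1 else y1
        e0 = math.exp(y0 - m)
        p0 = e0 / (e0 + math.exp(y1 - m))
        c2 = 0 if np.random.random() < p0 else 1

        rew = 1 if np.random.random() < walk[t, 2 * s + c2] else 0

        d1 = q2[s, c2] - q1[c1]
        q1[c1] += al1 * d1
        d2 = rew - q2[s, c2]
        q2[s, c2] += al2 * d2
        q1[c1] += al1 * lam * d2
        prev = c1

        a1[t] = c1
        s2[t] = s
        a2[t] = c2
        r[t] = rew
    return a1, s2, a2, r
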