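"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities step by step with plain Python
arithmetic, independent of the package's vectorised/compiled code paths.
"""

import math


def naive_session_nll(params, p_common, first_choice, second_state, second_choice, reward):
    """Trial-by-trial replay of the hybrid agent's choice likelihood.

    `params` is a mapping with keys alpha1, alpha2, lam, omega, beta1,
    beta2, rho (natural space).
    """
    a1v, a2v = params["alpha1"], params["alpha2"]
    lam, om = params["lam"], params["omega"]
    b1, b2, rho = params["beta1"], params["beta2"], params["rho"]
    q1 = [0.0, 0.0]
    q2 = [[0.0, 0.0], [0.0, 0.0]]
    prev = None
    nll = 0.0
    for a1, s, a2, r in zip(first_choice, second_state, second_choice, reward):
        best0, best1 = max(q2[0]), max(q2[1])
        qmb = [
            p_common * best0 + (1 - p_common) * best1,
            p_common * best1 + (1 - p_common) * best0,
        ]
        logits = []
        for a in (0, 1):
            qnet = om * qmb[a] + (1 - om) * q1[a]
            rep = 1.0 if prev == a else 0.0
            logits.append(b1 * (qnet + rho * rep))
        z = math.exp(logits[0]) + math.exp(logits[1])
        nll -= math.log(math.exp(logits[a1]) / z)

        z = math.exp(b2 * q2[s][0]) + math.exp(b2 * q2[s][1])
        nll -= math.log(math.exp(b2 * q2[s][a2]) / z)

        d1 = q2[s][a2] - q1[a1]
        q1[a1] += a1v * d1
        d2 = r - q2[s][a2]
        q2[s][a2] += a2v * d2
        q1[a1] += a1v * lam * d2
        prev = a1
    return nll
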