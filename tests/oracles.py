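"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithms: the frontier oracle
decides membership geometrically, by checking each strategy against every
single competitor (strict dominance) and every pair of competitors
(extended dominance via linear interpolation at equal effectiveness).
"""

import numpy as np


def brute_force_frontier(costs, qalys):
    """Return the boolean frontier membership for each strategy.

    A strategy is off the frontier iff some other strategy is at least as
    effective and strictly cheaper (or more effective and no more
    expensive), or some convex combination of two others matches its
    effectiveness at strictly lower cost.
    """
    costs = np.asarray(costs, float)
    qalys = np.asarray(qalys, float)
    k = len(costs)
    on = np.ones(k, dtype=bool)
    for s in range(k):
        for j in range(k):
            if j == s:
                continue
            if ((qalys[j] >= qalys[s] and costs[j] < costs[s])
                    or (qalys[j] > qalys[s] and costs[j] <= costs[s])):
                on[s] = False
        if not on[s]:
            continue
        for i in range(k):
            for j in range(k):
                if s in (i, j) or not (qalys[i] < qalys[s] < qalys[j]):
                    continue
                alpha = (qalys[j] - qalys[s]) / (qalys[j] - qalys[i])
                c_mix = alpha * costs[i] + (1 - alpha) * costs[j]
                if c_mix < costs[s]:
                    on[s] = False
    return on
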