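"""Independent brute-force reference for the diversity computation.

Implements the whole chain — trapezoidal integrals, pairwise overlap
distances, relative intensities, the Rao factor and order-q diversity —
with explicit Python loops and the math module only, so that it shares
no code path with the package implementation.
"""

import math


def trapz(values, times):
    total = 0.0
    for k in range(len(values) - 1):
        total += 0.5 * (values[k] + values[k + 1]) * (times[k + 1] - times[k])
    return total


def overlap_distance_bf(zi, zj, times):
    cross = trapz([a * b for a, b in zip(zi, zj)], times)
    denom = trapz([a * a for a in zi], times) + trapz([b * b for b in zj], times)
    return 1.0 - 2.0 * cross / denom


def qpd_bf(curves, times, q):
    """curves: list of value lists on the shared grid `times`."""
    S = len(curves)
    areas = [trapz(c, times) for c in curves]
    total_area = sum(areas)
    p = [a / total_area for a in areas]
    O = [[0.0] * S for _ in range(S)]
    for i in range(S):
        for j in range(S):
            if i != j:
                O[i][j] = overlap_distance_bf(curves[i], curves[j], times)
    Q = 0.0
    for i in range(S):
        for j in range(S):
            Q += O[i][j] * p[i] * p[j]
    if Q == 0.0:
        return 0.0
    if abs(q - 1.0) < 1e-6:
        acc = 0.0
        for i in range(S):
            for j in range(S):
                pp = p[i] * p[j]
                acc += O[i][j] / Q * pp * math.log(pp)
        return math.exp(-0.5 * acc)
    acc = 0.0
    for i in range(S):
        for j in range(S):
            acc += O[i][j] / Q * (p[i] * p[j]) ** q
    return acc ** (1.0 / (2.0 * (1.0 - q)))
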