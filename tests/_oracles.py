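"""Brute-force reference implementations of the stability statistics.

Deliberately written with explicit Python loops and stdlib math only, so
they share no code path with the package's vectorized implementations.
"""

import math


def sample_sd(xs):
    n = len(xs)
    mean = sum(xs) / n
    return math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))


def pairwise_v(frame, j, k):
    ratios = [math.log2(frame.loc[j, s] / frame.loc[k, s]) for s in frame.columns]
    return sample_sd(ratios)


def m_values_bruteforce(frame):
    out = {}
    for j in frame.index:
        vs = [pairwise_v(frame, j, k) for k in frame.index if k != j]
        out[j] = sum(vs) / len(vs)
    return out


def cv_bruteforce(frame):
    out = {}
    for j in frame.index:
        row = [frame.loc[j, s] for s in frame.columns]
        out[j] = sample_sd(row) / (sum(row) / len(row))
    return out


def geometric_mean(xs):
    return math.exp(sum(math.log(x) for x in xs) / len(xs))


def v_series_bruteforce(frame, order):
    """V(n, n+1) for n = 2..G-1 given a most-stable-first gene order."""
    out = []
    for n in range(2, len(order)):
        logratios = []
        for s in frame.columns:
            nf_n = geometric_mean([frame.loc[g, s] for g in order[:n]])
            nf_n1 = geometric_mean([frame.loc[g, s] for g in order[: n + 1]])
            logratios.append(math.log2(nf_n / nf_n1))
        out.append((n, sample_sd(logratios)))
    return out
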