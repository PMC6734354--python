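"""Brute-force oracle for time-domain and Poincaré HRV features.

Written independently of the package: plain Python loops evaluating the
printed definitions directly, no numpy vector tricks shared with the
implementation.  Used to cross-check richrv.features on random series.
"""

import math


def brute_force_features(rr_ms):
    rr = [float(v) for v in rr_ms]
    n = len(rr)
    mean = sum(rr) / n
    s = sorted(rr)
    if n % 2:
        median = s[n // 2]
    else:
        median = 0.5 * (s[n // 2 - 1] + s[n // 2])
    sdrr = math.sqrt(sum((v - mean) ** 2 for v in rr) / n)
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    m = len(diffs)
    dmean = sum(diffs) / m
    sdsd = math.sqrt(sum((d - dmean) ** 2 for d in diffs) / m)
    rmssd = math.sqrt(sum(d * d for d in diffs) / m)
    nn50 = sum(1 for d in diffs if abs(d) > 50.0)
    pnn50 = 100.0 * nn50 / n
    # Poincaré from the variance identities, population convention
    var_diff = sum((d - dmean) ** 2 for d in diffs) / m
    var_rr = sum((v - mean) ** 2 for v in rr) / n
    sd1 = math.sqrt(0.5 * var_diff)
    sd2_sq = 2.0 * var_rr - 0.5 * var_diff
    sd2 = math.sqrt(sd2_sq) if sd2_sq > 0 else 0.0
    return {
        "mean_rr_ms": mean,
        "median_rr_ms": median,
        "sdrr_ms": sdrr,
        "sdsd_ms": sdsd,
        "rmssd_ms": rmssd,
        "nn50": float(nn50),
        "pnn50": pnn50,
        "sd1_ms": sd1,
        "sd2_ms": sd2,
        "sd2_sq_raw_ms2": sd2_sq,
    }


def brute_force_wilcoxon_two_sided(diffs):
    """Exact two-sided signed-rank p by literal enumeration of sign patterns.

    Only feasible for small n; average ranks computed by hand.
    """
    d = [float(v) for v in diffs if v != 0]
    n = len(d)
    assert n <= 12, "enumeration oracle limited to small n"
    absd = sorted((abs(v), i) for i, v in enumerate(d))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[j + 1][0] == absd[i][0]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[absd[k][1]] = avg
        i = j + 1
    total = sum(ranks)
    w_plus_obs = sum(r for v, r in zip(d, ranks) if v > 0)
    w_obs = min(w_plus_obs, total - w_plus_obs)
    count = 0
    for pattern in range(2**n):
        w_plus = sum(ranks[i] for i in range(n) if pattern >> i & 1)
        if min(w_plus, total - w_plus) <= w_obs + 1e-12:
            count += 1
    return count / 2.0**n
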