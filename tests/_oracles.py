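"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately written with plain loops / enumeration, sharing
no code with the package paths it checks.
"""
from __future__ import annotations

import itertools
import math


def histogram_features_oracle(values, n_bins):
    """Direct-summation first-order statistics (population moments, bits)."""
    values = list(float(v) for v in values)
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    sd = math.sqrt(var)

    positive = [v for v in values if v > 0]
    mpp = sum(positive) / len(positive) if positive else float("nan")

    if sd > 0:
        skew = sum(((v - mean) / sd) ** 3 for v in values) / n
        kurt = sum(((v - mean) / sd) ** 4 for v in values) / n - 3.0
    else:
        skew = kurt = float("nan")

    lo, hi = min(values), max(values)
    if lo == hi:
        entropy = 0.0
    else:
        counts = [0] * n_bins
        for v in values:
            idx = int((v - lo) / (hi - lo) * n_bins)
            counts[min(idx, n_bins - 1)] += 1
        entropy = -sum((c / n) * math.log2(c / n) for c in counts if c)

    nsd = math.log(sd) / math.log(n) if (n >= 2 and sd > 0) else float("nan")
    return {"mpp": mpp, "sd": sd, "skewness": skew, "kurtosis": kurt,
            "entropy_bits": entropy, "nsd": nsd, "n_pixels": n}


def cox_partial_loglik(beta, times, events, x):
    """Partial log-likelihood for one covariate (assumes untied event times)."""
    ll = 0.0
    for i, (t_i, e_i) in enumerate(zip(times, events)):
        if not e_i:
            continue
        risk = [math.exp(beta * x[j]) for j, t_j in enumerate(times) if t_j >= t_i]
        ll += beta * x[i] - math.log(sum(risk))
    return ll


def cox_grid_mle(times, events, x, lo=-10.0, hi=10.0):
    """Two-stage grid maximization of the partial likelihood (1e-5 grid)."""
    best = None
    for _ in range(3):
        step = (hi - lo) / 2000
        grid = [lo + k * step for k in range(2001)]
        lls = [cox_partial_loglik(b, times, events, x) for b in grid]
        best = grid[lls.index(max(lls))]
        lo, hi = best - 2 * step, best + 2 * step
    return best


def km_product_limit(times, events):
    """Brute-force product-limit estimator: (event_times, survival) steps."""
    pairs = sorted(zip(times, events))
    uniq_event_times = sorted({t for t, e in pairs if e})
    surv, out = 1.0, []
    for t in uniq_event_times:
        at_risk = sum(1 for tt, _ in pairs if tt >= t)
        deaths = sum(1 for tt, e in pairs if tt == t and e)
        surv *= 1.0 - deaths / at_risk
        out.append((t, surv))
    return out


def recist_best_subset(lesions):
    """Exhaustive search for the feasible target-lesion set maximizing the
    diameter sum: <= 5 lesions, <= 2 per organ, every eligible unresected
    primary included, all >= 10 mm.

    ``lesions`` is a list of (lesion_id, organ, diameter_mm, is_primary).
    Returns (best_total_diameter, best_size) over feasible subsets.
    """
    eligible = [l for l in lesions if l[2] >= 10.0]
    primaries = [l for l in eligible if l[3]]
    best_total, best_size = -1.0, 0
    for r in range(0, min(5, len(eligible)) + 1):
        for subset in itertools.combinations(eligible, r):
            if any(p not in subset for p in primaries):
                continue
            organs = [l[1] for l in subset]
            if any(organs.count(o) > 2 for o in set(organs)):
                continue
            total = sum(l[2] for l in subset)
            if total > best_total:
                best_total, best_size = total, len(subset)
    return best_total, best_size
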