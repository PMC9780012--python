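"""Independent naive reference implementations used as oracles.

Everything here recomputes quantities from first principles (explicit
window slicing, explicit pair enumeration, explicit probability-table
summation) without touching the package's vectorized code paths, so
agreement is a genuine cross-check.
"""

import math

import numpy as np


# --- entropy ---------------------------------------------------------------


def naive_coarse(x, tau, k):
    """Window means straight from the definition, 1-based bookkeeping."""
    x = list(x)
    n = len(x)
    out = []
    j = 1
    while j * tau + k - 1 <= n:
        lo = (j - 1) * tau + k  # 1-based inclusive
        hi = j * tau + k - 1
        out.append(sum(x[lo - 1 : hi]) / tau)
        j += 1
    return np.array(out)


def naive_match_counts(y, m, r):
    """O(N^2) pair enumeration over the compatible template range."""
    y = np.asarray(y, dtype=float)
    nt = y.size - m  # templates i = 0..nt-1 exist at both lengths
    n_m = n_m1 = 0
    for i in range(nt):
        ti = y[i : i + m + 1]
        for j in range(i + 1, nt):
            tj = y[j : j + m + 1]
            d_m = np.max(np.abs(ti[:m] - tj[:m]))
            if d_m <= r:
                n_m += 1
                if abs(ti[m] - tj[m]) <= r:
                    n_m1 += 1
    return n_m, n_m1


def naive_match_counts_fast(y, m, r):
    """Same enumeration with the inner loop vectorized over j (needed to
    keep the 50-series oracle sweep affordable); outer loop and window
    construction stay explicit."""
    y = np.asarray(y, dtype=float)
    nt = y.size - m
    n_m = n_m1 = 0
    for i in range(nt - 1):
        d_m = np.zeros(nt - 1 - i)
        for t in range(m):
            d_m = np.maximum(d_m, np.abs(y[i + t] - y[i + 1 + t : nt + t]))
        hit_m = d_m <= r
        n_m += int(hit_m.sum())
        d_m1 = np.maximum(d_m, np.abs(y[i + m] - y[i + 1 + m : nt + m]))
        n_m1 += int((d_m1 <= r).sum())
    return n_m, n_m1


def _neg_log(a, b, base):
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b) / math.log(base)


def naive_sample_entropy(y, m, r, base=2.0, fast=False):
    counter = naive_match_counts_fast if fast else naive_match_counts
    n_m, n_m1 = counter(y, m, r)
    return _neg_log(n_m1, n_m, base)


def naive_mse(x, taus, m=2, r_coef=0.2, base=2.0, fast=False):
    """Per tau: SampEn of the single k=1 coarse series, r from original x."""
    x = np.asarray(x, dtype=float)
    r = r_coef * float(np.std(x))
    out = {}
    counter = naive_match_counts_fast if fast else naive_match_counts
    for tau in taus:
        y = naive_coarse(x, tau, 1)
        if y.size < m + 1:
            out[tau] = (math.nan, 0, 0)
            continue
        n_m, n_m1 = counter(y, m, r)
        out[tau] = (_neg_log(n_m1, n_m, base), n_m, n_m1)
    return out


def naive_rcmse(x, taus, m=2, r_coef=0.2, base=2.0, fast=False):
    """Explicitly builds every offset series k=1..tau and pools counts."""
    x = np.asarray(x, dtype=float)
    r = r_coef * float(np.std(x))
    out = {}
    counter = naive_match_counts_fast if fast else naive_match_counts
    for tau in taus:
        if x.size < (m + 1) * tau:
            out[tau] = (math.nan, 0, 0)
            continue
        tot_m = tot_m1 = 0
        for k in range(1, tau + 1):
            y = naive_coarse(x, tau, k)
            if y.size < m + 1:
                continue
            n_m, n_m1 = counter(y, m, r)
            tot_m += n_m
            tot_m1 += n_m1
        out[tau] = (_neg_log(tot_m1, tot_m, base), tot_m, tot_m1)
    return out


# --- discrete information theory ------------------------------------------


def naive_entropy(codes):
    codes = list(codes)
    n = len(codes)
    h = 0.0
    for v in set(codes):
        p = codes.count(v) / n
        h -= p * math.log2(p)
    return h


def naive_joint_entropy(*columns):
    pairs = list(zip(*columns))
    return naive_entropy(pairs)


def naive_mi(f, g):
    """Direct double summation over the joint probability table."""
    f, g = list(f), list(g)
    n = len(f)
    mi = 0.0
    for a in set(f):
        pa = f.count(a) / n
        for b in set(g):
            pb = g.count(b) / n
            pab = sum(1 for x, y in zip(f, g) if x == a and y == b) / n
            if pab > 0:
                mi += pab * math.log2(pab / (pa * pb))
    return mi


def naive_cmi(f, c, g):
    """Direct triple summation: I(f;c|g) = sum p(f,c,g) log [p(g)p(f,c,g) /
    (p(f,g) p(c,g))]."""
    f, c, g = list(f), list(c), list(g)
    n = len(f)
    triples = list(zip(f, c, g))
    cmi = 0.0
    for a in set(f):
        for b in set(c):
            for d in set(g):
                pabd = triples.count((a, b, d)) / n
                if pabd == 0:
                    continue
                pd = g.count(d) / n
                pad = sum(1 for x, z in zip(f, g) if x == a and z == d) / n
                pbd = sum(1 for y, z in zip(c, g) if y == b and z == d) / n
                cmi += pabd * math.log2(pd * pabd / (pad * pbd))
    return cmi


def naive_step_score(codes, y, candidate, selected, criterion, beta=0.5):
    """Greedy-step criterion score evaluated straight from the formulas."""
    f = codes[candidate]
    if not selected:
        return naive_mi(f, y)
    if criterion == "IG":
        return naive_mi(f, y)
    if criterion == "MIFS":
        return naive_mi(f, y) - beta * sum(naive_mi(f, codes[s]) for s in selected)
    if criterion == "MIFS-U":
        return naive_mi(f, y) - beta * sum(
            naive_mi(codes[s], y) / naive_entropy(codes[s]) * naive_mi(f, codes[s])
            for s in selected
        )
    if criterion == "mRMR":
        return naive_mi(f, y) - sum(naive_mi(f, codes[s]) for s in selected) / len(selected)
    if criterion == "NMIFS":
        return naive_mi(f, y) - sum(
            naive_mi(f, codes[s]) / min(naive_entropy(f), naive_entropy(codes[s]))
            for s in selected
        ) / len(selected)
    if criterion == "CR-MIFS":
        rel = sum(naive_cmi(f, y, codes[s]) for s in selected) / len(selected)
        red = sum(naive_mi(f, codes[s]) for s in selected) / len(selected)
        return rel - red
    raise ValueError(criterion)


# --- misc ------------------------------------------------------------------


def same_float(a, b):
    """Equality that treats two NaNs as equal (undefined == undefined)."""
    if math.isnan(a) and math.isnan(b):
        return True
    return a == b
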