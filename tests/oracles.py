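"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written as plain explicit loops, separate
from the package's vectorized code paths, so the two routes can be compared.
"""

import numpy as np


def oracle_modwt_forward(x, g, h, levels):
    """MODWT by explicit circular convolution, one coefficient at a time."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    v = x.copy()
    details = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        w_new = np.zeros(n)
        v_new = np.zeros(n)
        for t in range(n):
            acc_w = 0.0
            acc_v = 0.0
            for l in range(len(g)):
                idx = (t - step * l) % n
                acc_w += h[l] * v[idx]
                acc_v += g[l] * v[idx]
            w_new[t] = acc_w
            v_new[t] = acc_v
        details.append(w_new)
        v = v_new
    return details, v


def oracle_modwt_mra(x, g, h, levels):
    """MRA via the inverse cascade applied to each band in isolation."""

    def synth_one(band, taps_first, j):
        out = band.copy()
        n = len(out)
        taps = taps_first
        for k in range(j, 0, -1):
            step = 2 ** (k - 1)
            nxt = np.zeros(n)
            for t in range(n):
                acc = 0.0
                for l in range(len(taps)):
                    acc += taps[l] * out[(t + step * l) % n]
                nxt[t] = acc
            out = nxt
            taps = g  # after the first (deepest) stage only scaling taps
        return out

    coeffs, v = oracle_modwt_forward(x, g, h, levels)
    details = [synth_one(w, h, j) for j, w in enumerate(coeffs, start=1)]
    smooth = synth_one(v, g, levels)
    return details, smooth


def oracle_ra(values, window):
    """Sliding-window Ra with explicit per-position loops and truncation."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = np.zeros(n)
    for i in range(n):
        lo = max(i - window // 2, 0)
        hi = min(i - window // 2 + window, n)
        win = values[lo:hi]
        out[i] = np.mean(np.abs(win - win.mean()))
    return out


def oracle_ranks(pooled):
    """Midranks by explicit comparison counting."""
    pooled = np.asarray(pooled, dtype=float)
    n = len(pooled)
    ranks = np.zeros(n)
    for i in range(n):
        less = sum(1 for v in pooled if v < pooled[i])
        equal = sum(1 for v in pooled if v == pooled[i])
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def oracle_kruskal_h(groups):
    """Tie-corrected H from first principles."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = oracle_ranks(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    ties = 0.0
    for v in set(pooled.tolist()):
        t = sum(1 for u in pooled if u == v)
        ties += t ** 3 - t
    correction = 1.0 - ties / (n ** 3 - n)
    return h / correction if correction > 0 else 0.0


def oracle_mwu_exact_p(x, y):
    """Exact two-sided Mann-Whitney p by full labeling enumeration."""
    import itertools

    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.array(x + y)
    ranks = oracle_ranks(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    n = len(pooled)
    mean_w = nx * (n + 1) / 2.0
    count_le = count_ge = total = 0
    for combo in itertools.combinations(range(n), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= w_obs + 1e-12:
            count_le += 1
        if w >= w_obs - 1e-12:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / total)
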