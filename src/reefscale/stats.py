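"""Nonparametric comparison battery and simple OLS regression.

Implements the Mann-Whitney U test (exact permutation distribution for
small samples, tie- and continuity-corrected normal approximation
otherwise), the Kruskal-Wallis H test with tie correction, Dunn's post-hoc
pairwise z tests with Bonferroni adjustment, and ordinary least-squares
regression with an optional log transform of the predictor.

The rank machinery is written out explicitly (midranks, tie terms) rather
than delegated to scipy so the exact/approximate switching and tie handling
match the documented contracts; scipy supplies only the reference
distributions (normal, chi-square, t).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatReport",
    "RegressionResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "linear_regression",
]

# Exact Mann-Whitney permutation distribution is used below this size.
EXACT_MIN_N = 8
EXACT_TOTAL_CAP = 500


@dataclass
class StatReport:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    group_labels: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_labels": list(self.group_labels),
            "extras": _jsonable(self.extras),
        }


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "p_value": self.p_value, "n": self.n,
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties assigned their average (mid) rank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_rank_sum_tail(pooled_ranks: np.ndarray, nx: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum W of an nx-subset of pooled ranks.

    Enumerates the permutation distribution of W by a subset-count dynamic
    program over doubled midranks (doubling makes half-integer midranks
    integral).  Two-sided p = 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    doubled = np.rint(2 * pooled_ranks).astype(int)
    w2 = int(round(2 * w_obs))
    total = int(doubled.sum())
    # counts[k][s] = number of k-subsets with doubled rank sum s
    counts = np.zeros((nx + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in doubled:
        upper = min(nx, len(doubled))
        for k in range(upper - 1, -1, -1):
            row = counts[k]
            nz = np.flatnonzero(row)
            if nz.size:
                counts[k + 1, nz + r] += row[nz]
    dist = counts[nx]
    n_subsets = dist.sum()
    p_le = dist[: w2 + 1].sum() / n_subsets
    p_ge = dist[w2:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney_u(x, y, method: str = "auto") -> StatReport:
    """Two-sided Mann-Whitney U test.

    ``method`` is ``"exact"``, ``"asymptotic"`` or ``"auto"`` (default):
    exact when the smaller sample has at most 8 observations and the pooled
    size is small enough to enumerate, otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rank_sum_x = float(ranks[:nx].sum())
    u_x = rank_sum_x - nx * (nx + 1) / 2.0
    u_y = nx * ny - u_x

    if method == "auto":
        method = (
            "exact"
            if min(nx, ny) <= EXACT_MIN_N and nx + ny <= EXACT_TOTAL_CAP
            else "asymptotic"
        )

    mean_u = nx * ny / 2.0
    if method == "exact":
        p = _exact_rank_sum_tail(ranks, nx, rank_sum_x)
        statistic = u_x
        z = None
    elif method == "asymptotic":
        n = nx + ny
        tie = _tie_term(pooled)
        var_u = nx * ny / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var_u <= 0:  # all values tied
            z, p = 0.0, 1.0
        else:
            diff = u_x - mean_u
            # continuity correction shrinks |diff| by 1/2
            cc = min(0.5, abs(diff))
            z = (diff - math.copysign(cc, diff)) / math.sqrt(var_u) if diff else 0.0
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        statistic = u_x
    else:
        raise ValueError(f"unknown method {method!r}")

    extras = {"U_x": u_x, "U_y": u_y, "method": method,
              "n_x": nx, "n_y": ny}
    if z is not None:
        extras["z"] = z
    return StatReport(
        test_name="mann_whitney_u",
        statistic=statistic,
        p_value=p,
        extras=extras,
    )


def _rank_groups(groups: list[np.ndarray]):
    pooled = np.concatenate(groups)
    ranks = _midranks(pooled)
    split_points = np.cumsum([g.size for g in groups])[:-1]
    return pooled, np.split(ranks, split_points)


def kruskal_wallis(groups, labels=None) -> StatReport:
    """Kruskal-Wallis H test with tie correction; p from chi-square(k-1)."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    labels = list(labels) if labels is not None else [
        f"group{i}" for i in range(len(groups))
    ]
    n_total = sum(g.size for g in groups)
    pooled, group_ranks = _rank_groups(groups)
    mean_rank = (n_total + 1) / 2.0
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        g.size * (r.mean() - mean_rank) ** 2
        for g, r in zip(groups, group_ranks)
    )
    correction = 1.0 - _tie_term(pooled) / (n_total ** 3 - n_total)
    if correction <= 0:  # every observation tied
        h_corrected, p = 0.0, 1.0
    else:
        h_corrected = h / correction
        p = float(sps.chi2.sf(h_corrected, len(groups) - 1))
    return StatReport(
        test_name="kruskal_wallis",
        statistic=float(h_corrected),
        p_value=p,
        group_labels=labels,
        extras={
            "df": len(groups) - 1,
            "n": n_total,
            "tie_correction": correction,
            "group_n": [int(g.size) for g in groups],
            "mean_ranks": [float(r.mean()) for r in group_ranks],
        },
    )


def dunn_posthoc(groups, labels=None) -> StatReport:
    """Dunn's pairwise post-hoc z tests with Bonferroni adjustment.

    For each pair the statistic is the difference of mean pooled ranks over
    a pooled standard error including the tie correction; each two-sided p
    is multiplied by the number of pairs and capped at 1.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    labels = list(labels) if labels is not None else [
        f"group{i}" for i in range(len(groups))
    ]
    n_total = sum(g.size for g in groups)
    pooled, group_ranks = _rank_groups(groups)
    tie = _tie_term(pooled)
    base_var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    pairs = []
    max_abs_z = 0.0
    min_adj_p = 1.0
    for i, j in itertools.combinations(range(k), 2):
        ni, nj = groups[i].size, groups[j].size
        se = math.sqrt(base_var * (1.0 / ni + 1.0 / nj))
        z = 0.0 if se == 0 else (group_ranks[i].mean() - group_ranks[j].mean()) / se
        p_adj = float(min(1.0, n_pairs * 2.0 * sps.norm.sf(abs(z))))
        pairs.append({
            "group_i": labels[i], "group_j": labels[j],
            "z": float(z), "p_adjusted": p_adj,
        })
        if abs(z) >= max_abs_z:
            max_abs_z = abs(z)
            min_adj_p = min(min_adj_p, p_adj)
    return StatReport(
        test_name="dunn_posthoc",
        statistic=float(max_abs_z),
        p_value=float(min_adj_p),
        group_labels=labels,
        extras={"pairs": pairs, "n_pairs": n_pairs, "bonferroni_m": n_pairs},
    )


def linear_regression(x, y, log_x: bool = False, log_base: float = math.e
                      ) -> RegressionResult:
    """Ordinary least squares of y on x (optionally log-transformed x).

    With ``log_x`` true, non-positive predictor values are dropped with a
    warning.  The slope p-value comes from the t distribution with n - 2
    degrees of freedom; R-squared is the explained fraction of the total
    sum of squares.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if log_x:
        keep = x > 0
        if not np.all(keep):
            import warnings

            warnings.warn(
                f"dropping {int((~keep).sum())} non-positive x values "
                "before log transform", stacklevel=2,
            )
        x, y = x[keep], y[keep]
        x = np.log(x) / math.log(log_base)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("x has zero variance")
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy == 0:
        r2 = 0.0
    else:
        r2 = sxy ** 2 / (sxx * syy)
    resid_ss = max(syy - slope * sxy, 0.0)
    if resid_ss == 0:
        # perfect fit: degenerate t; a zero slope (constant y) is not evidence
        p = 0.0 if slope != 0 else 1.0
    else:
        se = math.sqrt(resid_ss / (n - 2) / sxx)
        t = slope / se if se > 0 else 0.0
        p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2)))
    return RegressionResult(
        slope=float(slope), intercept=float(intercept),
        r_squared=float(r2), p_value=p, n=int(n),
    )
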