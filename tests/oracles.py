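"""Independent brute-force oracles used by the unit and acceptance suites.

Each function re-derives a statistic from first principles (explicit risk-set
enumeration, hypergeometric tail sums, manual rank arithmetic, adjacency
recounts) so that the package implementations can be checked against a second,
unrelated code path.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, hypergeom


def logrank_oracle(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank chi-square from an explicit risk-set table.

    Walks the pooled distinct event times, accumulating observed-minus-expected
    events in group A and the hypergeometric variance at each time.
    """
    times = np.concatenate([np.asarray(times_a, float), np.asarray(times_b, float)])
    events = np.concatenate([np.asarray(events_a, int), np.asarray(events_b, int)])
    group_a = np.concatenate([np.ones(len(times_a), bool), np.zeros(len(times_b), bool)])
    o_minus_e = 0.0
    variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & group_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & group_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)
    if variance == 0.0:  # degenerate: groups never co-occur in a risk set
        return float("nan"), float("nan")
    stat = o_minus_e**2 / variance
    return float(stat), float(chi2.sf(stat, 1))


def fisher_oracle(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric tail enumeration.

    Sums the probabilities of every table (with the observed margins) whose
    point probability does not exceed the observed table's.
    """
    total = n11 + n10 + n01 + n00
    row1 = n11 + n10
    col1 = n11 + n01
    rv = hypergeom(total, row1, col1)
    k = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    pmf = rv.pmf(k)
    p_obs = rv.pmf(n11)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def spearman_rho_oracle(x, y) -> float:
    """Spearman rho by manual average ranks and the Pearson formula."""

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # average 1-based rank
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def degree_oracle(edge_pairs, candidates) -> dict[str, int]:
    """Node degrees within the candidate-induced subgraph by direct recount."""
    candidates = set(candidates)
    seen = set()
    degrees = {c: 0 for c in candidates}
    for a, b in edge_pairs:
        key = (a, b) if a < b else (b, a)
        if a in candidates and b in candidates and a != b and key not in seen:
            seen.add(key)
            degrees[a] += 1
            degrees[b] += 1
    return degrees


def edge_filter_oracle(rows, min_confidence: float) -> set[tuple[str, str]]:
    """Expected kept-edge set for a raw (nodeA, nodeB, score) table."""
    scores = [s for _, _, s in rows]
    scale = 1000.0 if any(s > 1 for s in scores) else 1.0
    kept = {}
    for a, b, s in rows:
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        conf = s / scale
        kept[key] = max(kept.get(key, 0.0), conf)
    return {k for k, c in kept.items() if c >= min_confidence}
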