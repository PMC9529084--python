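"""Validation battery for candidate genes: anchor correlation, stage trend,
alteration co-occurrence, degree-based hub ranking, and the four-criteria
intersection.

Co-occurrence of two genes' alteration status across samples is summarised by
a 2x2 table, a log2 odds ratio (Haldane-Anscombe +0.5 correction when any cell
is zero, keeping the log finite) and a two-sided Fisher exact p-value. Hubs are
the highest-degree nodes of the candidate-induced interaction subgraph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import EdgeList, ExpressionMatrix, GisticMatrix, MISSING


def spearman_anchor(
    expr: ExpressionMatrix,
    anchor: str,
    genes: Sequence[str],
    cancer: str | None = None,
) -> pd.DataFrame:
    """Spearman rank correlation of each gene with the anchor across tumour samples.

    Returns columns ``rho``, ``p_value``, ``evaluable`` indexed by gene; a gene
    (or anchor) with constant expression is reported as not-evaluable rather
    than raising.
    """
    samples = expr.samples(cancer=cancer, tumour=True)
    if len(samples) < 5:
        raise ValueError("need at least 5 tumour samples for correlation")
    x = expr.values.loc[anchor, samples].to_numpy(dtype=float)
    rows = []
    for g in genes:
        y = expr.values.loc[g, samples].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"gene": g, "rho": math.nan, "p_value": math.nan, "evaluable": False})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"gene": g, "rho": float(rho), "p_value": float(p), "evaluable": True})
    return pd.DataFrame(rows).set_index("gene")


def _collapse_stage(stage: str) -> str:
    """Sub-stages collapse to their parent: IIIa -> III, IVB -> IV."""
    s = stage.strip().upper()
    while s and s[-1] not in "IV":
        s = s[:-1]
    return s


def stage_anova(
    expr: ExpressionMatrix,
    gene: str,
    stages: pd.Series,
    cancer: str | None = None,
) -> tuple[float, float]:
    """One-way ANOVA of a gene's tumour expression across pathological stages.

    ``stages`` maps sample id -> stage label (I-IV, sub-stages collapsed,
    missing token skipped). Requires >=2 stage groups with >=2 samples each.
    """
    samples = [s for s in expr.samples(cancer=cancer, tumour=True) if s in stages.index]
    labels = stages.loc[samples].map(lambda s: _collapse_stage(s) if s != MISSING else MISSING)
    groups = []
    for level in sorted(set(labels) - {MISSING}):
        ids = [s for s, l in labels.items() if l == level]
        if len(ids) >= 2:
            groups.append(expr.values.loc[gene, ids].to_numpy(dtype=float))
    if len(groups) < 2:
        raise ValueError("need >=2 stage groups with >=2 samples each")
    f, p = stats.f_oneway(*groups)
    if math.isnan(f):  # all group means equal with zero within-group variance
        f, p = 0.0, 1.0
    return float(f), float(p)


@dataclass
class CooccurrenceResult:
    """2x2 alteration co-occurrence between two genes."""

    gene_a: str
    gene_b: str
    both_altered: int
    a_only: int
    b_only: int
    neither: int
    log2_odds_ratio: float
    p_value: float

    @property
    def n(self) -> int:
        return self.both_altered + self.a_only + self.b_only + self.neither


def cooccurrence_test(
    calls_a, calls_b, gene_a: str = "A", gene_b: str = "B"
) -> CooccurrenceResult:
    """Fisher exact test of joint alteration status for two genes.

    ``calls_a``/``calls_b`` are per-sample binary alteration indicators. The
    odds ratio uses the Haldane-Anscombe +0.5 correction whenever any cell is
    zero, so the log2 odds ratio is always finite; the p-value is the
    two-sided Fisher exact probability (point-probability method).
    """
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("calls must be two equal-length 1-d vectors")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    cells = (n11, n10, n01, n00)
    if min(cells) == 0:
        c = [x + 0.5 for x in cells]
    else:
        c = list(cells)
    log2_or = math.log2((c[0] * c[3]) / (c[1] * c[2]))
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return CooccurrenceResult(gene_a, gene_b, n11, n10, n01, n00, log2_or, float(p))


def alteration_calls(matrix: GisticMatrix, mode: str = "deep") -> pd.DataFrame:
    """Binary per-(gene, sample) alteration indicators from GISTIC calls.

    ``deep``: only +/-2 count as altered; ``any``: any non-zero call.
    """
    v = matrix.values
    if mode == "deep":
        return (v.abs() == 2).astype(int)
    if mode == "any":
        return (v != 0).astype(int)
    raise ValueError("mode must be 'deep' or 'any'")


def hub_rank(
    network: EdgeList, candidates: Iterable[str], min_degree: int = 1
) -> pd.DataFrame:
    """Degree-based hub ranking within the candidate-induced subgraph.

    Degree is computed on the subgraph induced by ``candidates``; nodes with
    degree >= ``min_degree`` are returned sorted by degree descending, ties
    alphabetical, with 1-based competition ranks.
    """
    if len(network.edges) == 0:
        raise ValueError("network is empty")
    g = nx.Graph()
    g.add_nodes_from(candidates)
    for a, b, _ in network.edges.itertuples(index=False):
        if a in g and b in g:
            g.add_edge(a, b)
    rows = [
        {"node": n, "degree": d}
        for n, d in g.degree()
        if d >= min_degree
    ]
    df = pd.DataFrame(rows, columns=["node", "degree"])
    df = df.sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    df["rank"] = df["degree"].rank(method="min", ascending=False).astype(int) if len(df) else pd.Series(dtype=int)
    return df


def criteria_intersect(
    survival_pass: Set[str],
    stage_pass: Set[str],
    correlation_pass: Set[str],
    cooccurrence_pass: Set[str],
) -> tuple[list[str], pd.DataFrame]:
    """Exact four-way intersection of the validation criteria.

    Returns the alphabetically sorted intersection plus a per-gene audit table
    of pass flags over the union of all four sets.
    """
    sets = {
        "survival": set(survival_pass),
        "stage": set(stage_pass),
        "correlation": set(correlation_pass),
        "cooccurrence": set(cooccurrence_pass),
    }
    universe = sorted(set().union(*sets.values()))
    audit = pd.DataFrame(
        {name: [g in s for g in universe] for name, s in sets.items()},
        index=pd.Index(universe, name="gene"),
    )
    audit["all_four"] = audit.all(axis=1)
    final = sorted(audit.index[audit["all_four"]])
    return final, audit
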