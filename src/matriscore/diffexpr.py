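"""Two-group differential expression, the copy-number/expression concordance
filter, and cross-cancer overlap.

Fold changes are computed on the log2(TPM+1)-like scale as a difference of
group means, so "fold change > 2" means ``|log2FC| >= 1``. The default test is
Welch's t (unequal variances); a Mann-Whitney alternative is available. A gene
is called ``up`` iff ``log2FC >= log2(threshold)`` and ``p <= alpha``, ``down``
symmetrically, else ``none``. Raw p-values drive the direction calls (the
screen's convention); a BH-FDR column is emitted alongside for transparency.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix
from .survival_stats import EXCLUDED, HIGH, LOW, assign_groups

logger = logging.getLogger("matriscore")


def _two_group_table(
    a: np.ndarray, b: np.ndarray, genes: Sequence[str],
    fc_threshold: float, alpha: float, test: str,
    mean_a: str, mean_b: str,
) -> pd.DataFrame:
    """Per-gene two-group comparison of the rows of ``a`` (group A) vs ``b``."""
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    log2fc = ma - mb
    if test == "welch":
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # near-constant rows degenerate to the zero-variance convention below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError("test must be 'welch' or 'wilcoxon'")
    # zero variance in both groups: p undefined; equal means -> 1 by convention
    var0 = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(var0 & (log2fc == 0), 1.0, p)
    p = np.where(var0 & (log2fc != 0), 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    cut = math.log2(fc_threshold)
    direction = np.where(
        (log2fc >= cut) & (p <= alpha), "up",
        np.where((log2fc <= -cut) & (p <= alpha), "down", "none"),
    )
    return pd.DataFrame(
        {
            mean_a: ma,
            mean_b: mb,
            "log2_fold_change": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        },
        index=pd.Index(genes, name="gene"),
    )


def tumour_vs_normal(
    expr: ExpressionMatrix,
    cancer: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Tumour-vs-normal differential expression for one cancer type.

    log2FC = mean(tumour) - mean(normal) on the log2 scale. Requires at least
    two tumour and two normal samples.
    """
    t_ids = expr.samples(cancer=cancer, tumour=True)
    n_ids = expr.samples(cancer=cancer, tumour=False)
    if len(t_ids) < 2 or len(n_ids) < 2:
        raise ValueError(
            f"{cancer}: need >=2 tumour and >=2 normal samples "
            f"(got {len(t_ids)}/{len(n_ids)})"
        )
    a = expr.values[t_ids].to_numpy(dtype=float)
    b = expr.values[n_ids].to_numpy(dtype=float)
    return _two_group_table(
        a, b, list(expr.values.index), fc_threshold, alpha, test,
        "mean_tumour", "mean_normal",
    )


def concordance_filter(shortlist: pd.DataFrame, deg: pd.DataFrame) -> pd.DataFrame:
    """Keep shortlisted genes whose copy-number direction agrees with expression.

    Amplified genes are retained iff called ``up``, deleted genes iff ``down``.
    Shortlist genes absent from the DEG table are dropped with a warning.
    """
    keep_rows = []
    for _, row in shortlist.iterrows():
        gene = row["gene"]
        if gene not in deg.index:
            logger.warning("concordance_filter: %s absent from DEG table; dropped", gene)
            continue
        call = deg.loc[gene, "direction"]
        if (row["direction"] == "amplified" and call == "up") or (
            row["direction"] == "deleted" and call == "down"
        ):
            r = row.to_dict()
            r["log2_fold_change"] = float(deg.loc[gene, "log2_fold_change"])
            r["p_value"] = float(deg.loc[gene, "p_value"])
            keep_rows.append(r)
    cols = list(shortlist.columns) + ["log2_fold_change", "p_value"]
    return pd.DataFrame(keep_rows, columns=cols)


def anchor_stratified_deg(
    expr: ExpressionMatrix,
    anchor: str,
    cancer: str,
    high_cut: float = 0.75,
    low_cut: float = 0.25,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Differential expression between anchor-high and anchor-low tumour cohorts.

    Tumour samples are split by the anchor gene's expression (above the high
    percentile vs below the low percentile; middle excluded) and every other
    gene is compared between the two cohorts. The anchor itself is excluded
    from the output.
    """
    t_ids = expr.samples(cancer=cancer, tumour=True)
    if len(t_ids) < 4:
        raise ValueError(f"{cancer}: need >=4 tumour samples")
    if anchor not in expr.values.index:
        raise KeyError(f"anchor gene {anchor!r} not in expression matrix")
    anchor_vals = expr.values.loc[anchor, t_ids]
    groups = assign_groups(anchor_vals, high_cut, low_cut)  # raises if constant
    hi = [s for s in t_ids if groups[s] == HIGH]
    lo = [s for s in t_ids if groups[s] == LOW]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError(f"{cancer}: anchor split left <2 samples in a group")
    others = [g for g in expr.values.index if g != anchor]
    a = expr.values.loc[others, hi].to_numpy(dtype=float)
    b = expr.values.loc[others, lo].to_numpy(dtype=float)
    return _two_group_table(a, b, others, fc_threshold, alpha, test, "mean_high", "mean_low")


def top_fraction_deg(deg: pd.DataFrame, fraction: float) -> tuple[set[str], set[str]]:
    """Top fraction of up- and down-regulated genes by |log2FC| (ceiling, ties kept)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    out = []
    for call in ("up", "down"):
        sub = deg[deg["direction"] == call]
        if sub.empty:
            out.append(set())
            continue
        mag = sub["log2_fold_change"].abs().sort_values(ascending=False, kind="mergesort")
        k = math.ceil(fraction * len(mag))
        boundary = mag.iloc[min(k, len(mag)) - 1]
        out.append(set(mag[mag >= boundary].index))
    return out[0], out[1]


def cross_cancer_overlap(
    gene_sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    min_cancers: int = 3,
) -> pd.DataFrame:
    """Genes appearing in at least ``min_cancers`` of the per-cancer sets.

    Returns a DataFrame with columns ``gene``, ``n_cancers``, ``cancers``,
    sorted by count descending then symbol.
    """
    if isinstance(gene_sets, Mapping):
        items = list(gene_sets.items())
    else:
        items = [(str(i), s) for i, s in enumerate(gene_sets)]
    if len(items) < min_cancers:
        raise ValueError(
            f"need at least min_cancers={min_cancers} gene sets, got {len(items)}"
        )
    membership: dict[str, list[str]] = {}
    for label, genes in items:
        for g in set(genes):
            membership.setdefault(g, []).append(label)
    rows = [
        {"gene": g, "n_cancers": len(labels), "cancers": ",".join(sorted(labels))}
        for g, labels in membership.items()
        if len(labels) >= min_cancers
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_cancers", "cancers"])
    return df.sort_values(["n_cancers", "gene"], ascending=[False, True], ignore_index=True)
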