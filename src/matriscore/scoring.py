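"""Rank-sum gene scoring and the pan/individual intersection.

Genes are ranked by breadth — the percentage of cancers where their expression
change is concordant and significant, and the percentage where they
significantly affect survival. Each ranking assigns score 1 to the top gene,
increasing by one per position (competition ranking: tied values share the
minimal position of their tie block). The two scores are summed; a low total
marks a strong candidate. Upregulated and downregulated genes are scored in
separate tables and never mixed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Set

import pandas as pd

logger = logging.getLogger("matriscore")


def rank_scores(values: pd.Series) -> pd.Series:
    """1-based competition ranks of ``values`` sorted descending.

    The top value scores 1; ties share the minimal position of their block and
    the next distinct value resumes at its actual position, e.g.
    (90, 70, 70, 50) -> (1, 2, 2, 4).
    """
    if len(values) == 0:
        raise ValueError("need at least one gene to rank")
    return values.rank(method="min", ascending=False).astype(int)


def combined_score(expr_scores: pd.Series, surv_scores: pd.Series) -> pd.DataFrame:
    """Sum the expression and survival rank scores over a common gene universe.

    Returns a table with columns ``expression_rank_score``,
    ``survival_rank_score`` and ``total_score``, sorted ascending by total
    (ties broken alphabetically). Genes present in only one input raise.
    """
    only = set(expr_scores.index) ^ set(surv_scores.index)
    if only:
        raise ValueError(f"genes present in only one ranking: {sorted(only)}")
    df = pd.DataFrame(
        {
            "expression_rank_score": expr_scores.astype(int),
            "survival_rank_score": surv_scores.reindex(expr_scores.index).astype(int),
        }
    )
    df["total_score"] = df["expression_rank_score"] + df["survival_rank_score"]
    df.index.name = "gene"
    return df.sort_values(["total_score", "gene"], kind="mergesort")


def score_direction_group(
    expression_breadth: pd.Series, survival_breadth: pd.Series
) -> pd.DataFrame:
    """Score one direction group (up- or down-regulated genes) from breadths.

    Both inputs are percent-of-cancers breadth values over the same genes.
    Genes present in only one breadth table are dropped with a log message
    (a gene significant for expression but never for survival has no defined
    position in the survival graph).
    """
    common = expression_breadth.index.intersection(survival_breadth.index)
    dropped = set(expression_breadth.index).symmetric_difference(survival_breadth.index)
    if dropped:
        logger.info("score_direction_group: dropping genes without both breadths: %s", sorted(dropped))
    if len(common) == 0:
        return pd.DataFrame(
            columns=["expression_breadth", "survival_breadth",
                     "expression_rank_score", "survival_rank_score", "total_score"]
        )
    eb = expression_breadth.loc[common]
    sb = survival_breadth.loc[common]
    table = combined_score(rank_scores(eb), rank_scores(sb))
    table.insert(0, "expression_breadth", eb.reindex(table.index))
    table.insert(1, "survival_breadth", sb.reindex(table.index))
    return table


def pan_individual_intersect(
    pan_genes: Iterable[str],
    per_cancer_hits: Mapping[str, Set[str]],
    min_cancers: int = 2,
) -> pd.DataFrame:
    """Final selection: pan-shortlisted genes hit in >= ``min_cancers`` individual cancers.

    ``per_cancer_hits`` maps gene -> set of cancers where the gene was both
    shortlisted and survival-significant. Returns columns ``gene``,
    ``n_cancers``, ``cancers`` sorted by count descending then symbol.
    """
    rows = []
    for gene in sorted(set(pan_genes)):
        cancers = sorted(per_cancer_hits.get(gene, set()))
        if len(cancers) >= min_cancers:
            rows.append({"gene": gene, "n_cancers": len(cancers), "cancers": ",".join(cancers)})
    df = pd.DataFrame(rows, columns=["gene", "n_cancers", "cancers"])
    return df.sort_values(["n_cancers", "gene"], ascending=[False, True], ignore_index=True)
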