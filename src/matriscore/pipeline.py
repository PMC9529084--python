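"""End-to-end prioritization: copy number -> expression concordance -> survival
-> rank scoring -> pan/individual intersection.

Two parallel analyses feed the final selection:

* **Individual-cancer track.** Per cancer: top-fraction deep-alteration
  shortlist, concordance with that cancer's tumour-vs-normal expression calls,
  then a high/low log-rank survival screen. A gene "hits" a cancer when it
  survives all three filters there.
* **Pan-cancer track.** The per-cancer GISTIC matrices are pooled; the
  top-fraction shortlist per direction is kept where its pooled expression
  breadth (percentage of cancers with a concordant significant change) is
  non-zero, then rank-scored by expression and survival breadth.

The final gene list is the pan-shortlisted genes hit in at least
``min_cancers_individual`` individual cancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Set

import pandas as pd

from .cna_select import count_alterations, shortlist_both_directions
from .data_io import ClinicalTable, ExpressionMatrix, GisticMatrix, PipelineConfig
from .diffexpr import concordance_filter, tumour_vs_normal
from .scoring import pan_individual_intersect, score_direction_group
from .survival_stats import assign_groups, logrank_test, percent_affected

logger = logging.getLogger("matriscore")


@dataclass
class PipelineResult:
    per_cancer_hits: Dict[str, Set[str]]  # gene -> cancers where shortlisted + survival-significant
    pan_shortlist: pd.DataFrame
    scores_up: pd.DataFrame
    scores_down: pd.DataFrame
    final: pd.DataFrame
    deg_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def final_genes(self) -> list[str]:
        return list(self.final["gene"])


class _SurvivalScreenCache:
    """Log-rank p of the high/low screen per (gene, cancer), computed lazily."""

    def __init__(self, expr: ExpressionMatrix, clinical: ClinicalTable, config: PipelineConfig):
        self._expr = expr
        self._clinical = clinical
        self._config = config
        self._cache: Dict[tuple[str, str], float] = {}
        self._cohorts: Dict[str, tuple] = {}

    def _cohort(self, cancer: str):
        if cancer not in self._cohorts:
            t_ids = [
                s for s in self._expr.samples(cancer=cancer, tumour=True)
                if s in self._clinical.data.index
            ]
            clin = self._clinical.data.loc[t_ids]
            self._cohorts[cancer] = (
                t_ids, clin["time_days"].to_numpy(), clin["event"].to_numpy()
            )
        return self._cohorts[cancer]

    def p_value(self, gene: str, cancer: str) -> float:
        key = (gene, cancer)
        if key not in self._cache:
            t_ids, times, events = self._cohort(cancer)
            if len(t_ids) < 4:
                self._cache[key] = 1.0
            else:
                values = self._expr.values.loc[gene, t_ids]
                try:
                    groups = assign_groups(values, self._config.high_cutoff, self._config.low_cutoff)
                    _, p = logrank_test(times, events, groups)
                except ValueError:
                    p = 1.0
                self._cache[key] = p
        return self._cache[key]


def run_prioritization(
    gistic: Dict[str, GisticMatrix],
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full multi-stage prioritization over a multi-cancer cohort."""
    config = config or PipelineConfig()
    cancers = sorted(gistic)

    deg_tables = {
        c: tumour_vs_normal(expression, c, config.fold_change_threshold, config.alpha)
        for c in cancers
    }
    screen = _SurvivalScreenCache(expression, clinical, config)

    # ---- individual-cancer track ------------------------------------------
    per_cancer_hits: Dict[str, Set[str]] = {}
    for cancer in cancers:
        counts = count_alterations(gistic[cancer])
        shortlist = shortlist_both_directions(counts, config.top_fraction, source=cancer)
        concordant = concordance_filter(shortlist, deg_tables[cancer])
        for gene in concordant["gene"].unique():
            if screen.p_value(gene, cancer) < config.alpha:
                per_cancer_hits.setdefault(gene, set()).add(cancer)

    # ---- pan-cancer track --------------------------------------------------
    pooled = GisticMatrix(pd.concat([gistic[c].values for c in cancers], axis=1))
    pan_counts = count_alterations(pooled)
    pan_shortlist = shortlist_both_directions(pan_counts, config.top_fraction, source="pan")

    breadth_rows = []
    for _, row in pan_shortlist.iterrows():
        gene, direction = row["gene"], row["direction"]
        want = "up" if direction == "amplified" else "down"
        expr_hits = sum(deg_tables[c].loc[gene, "direction"] == want for c in cancers)
        surv_hits = sum(screen.p_value(gene, c) < config.alpha for c in cancers)
        breadth_rows.append(
            {
                "gene": gene,
                "direction": direction,
                "expression_breadth": percent_affected(expr_hits, len(cancers)),
                "survival_breadth": percent_affected(surv_hits, len(cancers)),
            }
        )
    breadth = pd.DataFrame(
        breadth_rows, columns=["gene", "direction", "expression_breadth", "survival_breadth"]
    )

    scores: Dict[str, pd.DataFrame] = {}
    for direction, key in (("amplified", "up"), ("deleted", "down")):
        sub = breadth[(breadth["direction"] == direction) & (breadth["expression_breadth"] > 0)]
        sub = sub.drop_duplicates("gene").set_index("gene")
        scores[key] = score_direction_group(sub["expression_breadth"], sub["survival_breadth"])

    pan_concordant = list(scores["up"].index) + list(scores["down"].index)
    final = pan_individual_intersect(pan_concordant, per_cancer_hits, config.min_cancers_individual)
    return PipelineResult(
        per_cancer_hits=per_cancer_hits,
        pan_shortlist=pan_shortlist,
        scores_up=scores["up"],
        scores_down=scores["down"],
        final=final,
        deg_tables=deg_tables,
    )
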