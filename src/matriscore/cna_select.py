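"""Deep-event counting and top-fraction gene selection.

The first stage of the prioritization: per gene, count deep deletions (calls of
-2) and amplifications (+2) across samples — shallow +/-1 calls contribute to
neither — and shortlist the top fraction of genes per direction. Selection uses
ceiling rounding (top 5% of a 1027-gene universe = 52 genes per direction),
includes all genes tied with the boundary count, and never selects a gene with
zero events.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .data_io import GisticMatrix

logger = logging.getLogger("matriscore")

DIRECTIONS = ("amplified", "deleted")


def count_alterations(matrix: GisticMatrix) -> pd.DataFrame:
    """Per-gene deep-event counts.

    Returns a DataFrame indexed by gene with columns ``n_deep_deletion``
    (calls equal to -2), ``n_amplification`` (+2) and ``n_samples``.
    """
    v = matrix.values
    return pd.DataFrame(
        {
            "n_deep_deletion": (v == -2).sum(axis=1),
            "n_amplification": (v == 2).sum(axis=1),
            "n_samples": v.shape[1],
        },
        index=v.index,
    )


def top_fraction(
    counts: pd.DataFrame,
    fraction: float,
    direction: str,
    source: str = "pan",
    of_altered: bool = False,
) -> pd.DataFrame:
    """Shortlist the top ``fraction`` of genes by deep-event count in one direction.

    ``k = ceil(fraction * n)`` genes are selected where ``n`` is the size of the
    gene universe (or, with ``of_altered``, the number of genes with at least
    one event in the direction). All genes tied with the k-th count are
    included, so the shortlist may exceed ``k``. Genes with zero events are
    never selected.

    Returns a DataFrame with columns ``gene``, ``direction``, ``count``,
    ``n_samples``, ``source``, sorted by count descending then symbol.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    col = "n_amplification" if direction == "amplified" else "n_deep_deletion"
    series = counts[col]
    altered = series[series > 0]
    if altered.empty:
        logger.warning("top_fraction: no %s events in any gene (source=%s)", direction, source)
        return pd.DataFrame(columns=["gene", "direction", "count", "n_samples", "source"])
    n_universe = len(altered) if of_altered else len(series)
    k = math.ceil(fraction * n_universe)
    ranked = altered.sort_values(ascending=False, kind="mergesort")
    if k >= len(ranked):
        boundary = int(ranked.iloc[-1])
    else:
        boundary = int(ranked.iloc[k - 1])
    selected = ranked[ranked >= boundary]
    out = pd.DataFrame(
        {
            "gene": selected.index,
            "direction": direction,
            "count": selected.to_numpy(dtype=int),
            "n_samples": counts.loc[selected.index, "n_samples"].to_numpy(dtype=int),
            "source": source,
        }
    )
    return out.sort_values(["count", "gene"], ascending=[False, True], ignore_index=True)


def shortlist_both_directions(
    counts: pd.DataFrame, fraction: float, source: str = "pan", of_altered: bool = False
) -> pd.DataFrame:
    """Amplified and deleted shortlists concatenated (a gene may appear once per direction)."""
    parts = [
        top_fraction(counts, fraction, d, source=source, of_altered=of_altered)
        for d in DIRECTIONS
    ]
    return pd.concat(parts, ignore_index=True)
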