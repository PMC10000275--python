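"""Rank-sum consensus of ensemble importances: core age-related sncRNAs.

Each tree-ensemble method (adaptive boosting, gradient boosting, random
forest) supplies an impurity-importance vector. Genes with nonzero importance
in a method are ranked (1 = most important, ties broken lexicographically by
gene id for determinism); genes ranked by all three methods get a rank sum,
and the smallest sums define the core set -- features the ensembles agree on.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["importance_ranks", "rank_sum_core", "METHOD_COLUMNS"]

METHOD_COLUMNS = {
    "adaptive_boosting": "adaboost",
    "gradient_boosting": "gb",
    "random_forest": "rf",
}


def importance_ranks(importances: pd.Series) -> pd.Series:
    """Rank genes by importance, descending; zero-importance genes get no rank.

    Ties share no rank: the lexicographically smaller gene id ranks first.
    """
    imp = pd.Series(importances).astype(float)
    if imp.empty:
        raise ValueError("empty importance vector")
    if (imp < 0).any():
        raise ValueError("importances must be non-negative")
    nz = imp[imp > 0]
    ordered = nz.sort_index().sort_values(ascending=False, kind="stable")
    return pd.Series(range(1, len(ordered) + 1), index=ordered.index, dtype=int)


def rank_sum_core(
    ranks: dict[str, pd.Series], top_n: int | None = None
) -> pd.DataFrame:
    """Combine per-method rank mappings into the consensus table.

    ``ranks`` maps method name -> gene->rank Series (typically three ensemble
    methods). A gene is ``in_all_three`` when every method ranked it; its
    rank_sum is the sum of those ranks. The table is sorted by rank_sum
    ascending (ties by gene id) and ``core`` flags the in-all-methods genes,
    optionally truncated to the ``top_n`` smallest rank sums.
    """
    if not ranks:
        raise ValueError("at least one rank mapping is required")
    frame = pd.DataFrame({m: pd.Series(r) for m, r in ranks.items()})
    frame.index.name = "gene_id"
    frame["in_all_three"] = frame.notna().all(axis=1)
    frame["rank_sum"] = frame[list(ranks)].sum(axis=1).where(frame["in_all_three"])
    frame = frame.sort_index().sort_values("rank_sum", na_position="last", kind="stable")
    frame["core"] = frame["in_all_three"]
    if top_n is not None:
        in_core = frame.index[frame["core"]][:top_n]
        frame["core"] = frame.index.isin(in_core) & frame["in_all_three"]
    return frame
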