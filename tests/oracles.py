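"""Independent brute-force reference implementations for ranked-retrieval
metrics, written directly from the textbook definitions.  These are the
oracles the metric implementations are checked against; they share no
code with the package.
"""

from __future__ import annotations

import math


def brute_average_precision(ranked: list[str], relevant: set[str]) -> float:
    """AP = (1/|relevant|) * sum over relevant ranks of P@rank."""
    total = 0.0
    for rank in range(1, len(ranked) + 1):
        if ranked[rank - 1] in relevant:
            hits_upto = sum(1 for d in ranked[:rank] if d in relevant)
            total += hits_upto / rank
    return total / len(relevant)


def brute_reciprocal_rank(ranked: list[str], relevant: set[str]) -> float:
    for rank in range(1, len(ranked) + 1):
        if ranked[rank - 1] in relevant:
            return 1.0 / rank
    return 0.0


def brute_ndcg(ranked: list[str], relevant: set[str], cutoff: int | None = None) -> float:
    upto = len(ranked) if cutoff is None else min(cutoff, len(ranked))
    dcg = 0.0
    for rank in range(1, upto + 1):
        gain = 1.0 if ranked[rank - 1] in relevant else 0.0
        dcg += gain / math.log2(rank + 1)
    n_ideal = len(relevant) if cutoff is None else min(len(relevant), upto)
    idcg = 0.0
    for rank in range(1, n_ideal + 1):
        idcg += 1.0 / math.log2(rank + 1)
    return dcg / idcg if idcg else 0.0


def brute_restricted_pr(
    ranked: list[str], relevant: set[str], irrelevant: set[str], k: int
):
    restricted = [d for d in ranked if d in relevant or d in irrelevant]
    if k > len(restricted) or k < 1:
        return None, None
    hits = sum(1 for d in restricted[:k] if d in relevant)
    return hits / k, hits / len(relevant)


def brute_chi2_tables(present_rows: list[list[int]], y: list) -> list[float]:
    """Chi-square per feature from explicit present/absent x class tables
    via scipy's contingency test (no continuity correction)."""
    from scipy.stats import chi2_contingency

    classes = sorted(set(y))
    n_feat = len(present_rows[0])
    stats = []
    for j in range(n_feat):
        table = []
        for val in (1, 0):
            table.append(
                [
                    sum(1 for i, lab in enumerate(y) if lab == c and present_rows[i][j] == val)
                    for c in classes
                ]
            )
        row_tot = [sum(r) for r in table]
        if 0 in row_tot:
            stats.append(0.0)
            continue
        stat, _, _, _ = chi2_contingency(table, correction=False)
        stats.append(float(stat))
    return stats
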