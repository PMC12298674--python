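"""Homoeolog pairing and subgenome expression-bias analysis.

Homoeologs (the A- and B-subgenome copies of a duplicated gene) are
paired by reciprocal best hit over a BLAST tabular table with a percent
identity floor.  Per condition, each pair is classified from the log2
ratio of normalized A/B expression means as A-bias, B-bias, balanced, or
low-expression; transitions of those classes between conditions quantify
bias reprogramming.  Chi-square (with Yates continuity correction) and
Mann–Whitney helpers support the subgenome asymmetry tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ValidationError

BIAS_CLASSES = ("A-bias", "B-bias", "balanced", "low-expression")


@dataclass(frozen=True)
class HomoeologPair:
    pair_id: str
    gene_a: str
    gene_b: str
    identity_pct: float


def reciprocal_best_hits(
    hits: pd.DataFrame, min_identity: float = 90.0
) -> list[HomoeologPair]:
    """1:1 homoeolog pairs by mutual best BLAST hit.

    For each query the best cross-direction hit is chosen by bitscore
    (ties: higher pident, then lexicographically smaller subject id); a
    pair is kept iff the best hits are mutual and pident >= min_identity
    in both directions.  ``hits`` must contain both directions
    (A-as-query and B-as-query rows).
    """
    if hits.empty:
        return []
    best: dict[str, tuple[str, float]] = {}
    ranked = hits.sort_values(
        ["qseqid", "bitscore", "pident", "sseqid"],
        ascending=[True, False, False, True],
    )
    for _, row in ranked.drop_duplicates("qseqid", keep="first").iterrows():
        best[row["qseqid"]] = (row["sseqid"], float(row["pident"]))
    pairs = []
    for q, (s, pid_q) in best.items():
        if q >= s:  # emit each mutual pair once, from the smaller id
            continue
        back = best.get(s)
        if back is None or back[0] != q:
            continue
        if pid_q < min_identity or back[1] < min_identity:
            continue
        gene_a, gene_b = (q, s) if _is_a(q, s) else (s, q)
        pairs.append(
            HomoeologPair(
                pair_id=f"{gene_a}|{gene_b}",
                gene_a=gene_a,
                gene_b=gene_b,
                identity_pct=min(pid_q, back[1]),
            )
        )
    return sorted(pairs, key=lambda p: p.pair_id)


def _is_a(q: str, s: str) -> bool:
    """Heuristic orientation: the member whose id sorts first is reported
    as gene_a unless ids carry an explicit A/B marker."""
    for marker_a, marker_b in (("A", "B"),):
        if marker_a in q and marker_b in s and q.replace(marker_a, marker_b, 1) == s:
            return True
        if marker_b in q and marker_a in s and s.replace(marker_a, marker_b, 1) == q:
            return False
    return q < s


def classify_bias(
    expr_means: pd.DataFrame,
    pairs: list[HomoeologPair],
    log2_cut: float = 1.0,
    floor: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-pair, per-condition bias class from A/B expression means.

    ``expr_means`` is a gene × condition matrix of normalized expression
    means.  A pair is *low-expression* in a condition when both members
    are below ``floor``; otherwise the log2 ratio
    ``log2((mean_a + c) / (mean_b + c))`` decides A-bias (>= +cut),
    B-bias (<= -cut), or balanced.
    """
    rows = []
    for pair in pairs:
        for gene in (pair.gene_a, pair.gene_b):
            if gene not in expr_means.index:
                raise ValidationError(f"pair member {gene} missing from expression matrix")
        for cond in expr_means.columns:
            mean_a = float(expr_means.at[pair.gene_a, cond])
            mean_b = float(expr_means.at[pair.gene_b, cond])
            ratio = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
            if mean_a < floor and mean_b < floor:
                klass = "low-expression"
            elif ratio <= -log2_cut:
                klass = "B-bias"
            elif ratio >= log2_cut:
                klass = "A-bias"
            else:
                klass = "balanced"
            rows.append(
                {
                    "pair_id": pair.pair_id,
                    "condition": cond,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "log2_ratio": ratio,
                    "klass": klass,
                }
            )
    return pd.DataFrame(rows)


def transition_table(
    bias_calls: pd.DataFrame,
    cond_from: str,
    cond_to: str,
    subset: set[str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulation of bias classes between two conditions.

    ``subset`` restricts to a pair-id subset (e.g. pairs touching a DEG).
    Pairs classified low-expression in either condition are excluded and
    reported under the ``n_low_expression`` attribute; percentages are
    over the retained total.
    """
    calls = bias_calls.pivot(index="pair_id", columns="condition", values="klass")
    if subset is not None:
        calls = calls.loc[sorted(set(calls.index) & subset)]
    calls = calls[[cond_from, cond_to]].dropna()
    low = (calls == "low-expression").any(axis=1)
    n_low = int(low.sum())
    calls = calls[~low]
    total = len(calls)
    rows = []
    for cf in ("A-bias", "B-bias", "balanced"):
        for ct in ("A-bias", "B-bias", "balanced"):
            n = int(((calls[cond_from] == cf) & (calls[cond_to] == ct)).sum())
            rows.append(
                {
                    "condition_pair": f"{cond_from}->{cond_to}",
                    "class_from": cf,
                    "class_to": ct,
                    "count": n,
                    "total": total,
                    "pct": 100.0 * n / total if total else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_low_expression"] = n_low
    return out


def chisq_2x2(
    deg_a: int, expressed_a: int, deg_b: int, expressed_b: int, yates: bool = True
) -> tuple[float, int, float]:
    """Chi-square on the (DEG vs non-DEG) × (A vs B) 2×2 table.

    Returns (chi2, dof, p).  Yates continuity correction by default.
    """
    if not (0 <= deg_a <= expressed_a and 0 <= deg_b <= expressed_b):
        raise ValidationError("DEG counts must lie within expressed totals")
    table = np.array(
        [[deg_a, expressed_a - deg_a], [deg_b, expressed_b - deg_b]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero marginal in 2x2 table")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mann_whitney(
    values_x, values_y, two_sided: bool = True, exact_max_n: int = 20
) -> tuple[float, float]:
    """Mann–Whitney U with average ranks on ties.

    Exact enumeration when n1 + n2 <= ``exact_max_n`` and the data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.  Returns (U of the x sample, p).
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty sample in Mann-Whitney test")
    alternative = "two-sided" if two_sided else "greater"
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
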