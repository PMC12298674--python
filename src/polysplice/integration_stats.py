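"""Integration of the splicing and expression layers.

Covers ΔPSI–log2FC correlation per event type, overlaps between DEG and
DAG sets, the per-gene event-count vs isoform-count correlation, and
hypergeometric term enrichment with BH correction.

GeneRatio convention: k/M — the overlap of the query list with a term
divided by the term's background annotation count (not k over the list
size, which many tools report).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import EventCatalog, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int
    ok: bool = True
    note: str = ""


def _spearman(x, y) -> tuple[float, float]:
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_dpsi_expression(
    dse: pd.DataFrame, degs: pd.DataFrame, etype_of: pd.Series, min_n: int = 10
) -> dict[str, CorrelationResult]:
    """Spearman correlation of event ΔPSI with host-gene log2FC, per type.

    ``dse`` is a differential-splicing table indexed or keyed by
    event_id with a ``delta_psi`` column; ``degs`` a gene-indexed table
    with ``log2fc``; ``etype_of`` maps event_id -> event type.  Events
    are joined to their gene via the event-id prefix (``gene;...``).
    """
    df = dse.copy()
    if "event_id" in df.columns:
        df = df.set_index("event_id")
    df["gene_id"] = [e.split(";", 1)[0] for e in df.index]
    df["etype"] = etype_of.reindex(df.index)
    df = df.join(degs["log2fc"], on="gene_id").dropna(subset=["log2fc", "delta_psi"])
    out = {}
    for etype, block in df.groupby("etype"):
        n = len(block)
        if n < min_n:
            out[etype] = CorrelationResult("spearman", np.nan, np.nan, n, ok=False,
                                           note=f"insufficient events (n={n} < {min_n})")
            continue
        r, p = _spearman(block["delta_psi"], block["log2fc"])
        out[etype] = CorrelationResult("spearman", r, p, n)
    return out


def overlap_sets(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """All intersection cardinalities for up to four named gene sets.

    One row per nonempty combination of set names: the size of the
    intersection of the named sets (``intersection``) and the size of the
    exclusive region belonging to exactly those sets (``exclusive``).
    """
    if not 1 <= len(named_sets) <= 4:
        raise ValidationError("overlap_sets supports 1-4 sets")
    names = list(named_sets)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(named_sets[c] for c in combo))
            others = set().union(*(named_sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            rows.append(
                {
                    "sets": "&".join(combo),
                    "n_sets": k,
                    "intersection": len(inter),
                    "exclusive": len(inter - others),
                }
            )
    return pd.DataFrame(rows)


def hypergeom_enrich(
    gene_list: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    fdr_cut: float = 0.05,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a gene list.

    For a term annotating M of the N background genes, of which k fall in
    the size-n list, p = P(X >= k) (upper tail).  Terms with M below
    ``min_term_size`` or k = 0 are excluded from BH correction.
    GeneRatio is k/M.
    """
    stray = gene_list - background
    if stray:
        raise ValidationError(f"genes absent from background: {sorted(stray)[:10]}")
    N, n = len(background), len(gene_list)
    rows = []
    for term, genes in sorted(term_map.items()):
        members = genes & background
        M = len(members)
        k = len(members & gene_list)
        p = float(stats.hypergeom.sf(k - 1, N, M, n))
        rows.append(
            {"term_id": term, "k": k, "M": M, "n": n, "N": N,
             "gene_ratio": k / M if M else np.nan, "p": p}
        )
    df = pd.DataFrame(rows, columns=["term_id", "k", "M", "n", "N", "gene_ratio", "p"])
    tested = (df["M"] >= min_term_size) & (df["k"] > 0)
    df["fdr"] = np.nan
    if tested.any():
        df.loc[tested, "fdr"] = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] < fdr_cut
    return df


def event_isoform_correlation(
    catalog: EventCatalog,
    isoform_counts: pd.Series,
    active_events: set[str] | None = None,
) -> CorrelationResult:
    """Spearman correlation of per-gene active-event count with
    expressed-isoform count within one sample group.

    ``isoform_counts`` maps gene_id -> number of expressed isoforms.
    Flagged undefined when either variable is constant.
    """
    per_gene: dict[str, int] = {}
    for ev in catalog:
        if active_events is not None and ev.event_id not in active_events:
            continue
        per_gene[ev.gene_id] = per_gene.get(ev.gene_id, 0) + 1
    genes = [g for g in per_gene if g in isoform_counts.index]
    if len(genes) < 3:
        return CorrelationResult("spearman", np.nan, np.nan, len(genes), ok=False,
                                 note="fewer than 3 genes with events")
    x = np.array([per_gene[g] for g in genes], dtype=float)
    y = isoform_counts.loc[genes].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult("spearman", np.nan, np.nan, len(genes), ok=False,
                                 note="degenerate variance")
    r, p = _spearman(x, y)
    return CorrelationResult("spearman", r, p, len(genes))
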