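"""Differential gene expression with a transparent negative-binomial test.

Normalization uses DESeq-style median-of-ratios size factors.  Per-gene
NB dispersion is estimated by the method of moments on normalized counts
(floored at 1e-8), and a Wald-type z statistic on the log2 fold change is
formed with a delta-method standard error.  Genes with
|log2FC| >= lfc_min and BH-adjusted q < alpha are called differentially
expressed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import sample_groups
from .models import ValidationError

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValidationError("no gene has nonzero counts in all samples")
    ref = counts[positive]
    log_geo = np.log(ref).mean(axis=1)
    factors = np.exp(np.log(ref).sub(log_geo, axis=0).median(axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def test_de(
    counts: pd.DataFrame,
    contrast: tuple[str, str],
    lfc_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential-expression table for (treatment, control).

    Returns columns gene_id, contrast, base_mean, log2fc, p, q, status
    (up / down / ns).
    """
    treatment, control = contrast
    groups = sample_groups(counts.columns)
    for g in contrast:
        if g not in groups or len(groups[g]) < 2:
            raise ValidationError(f"contrast group {g!r} missing or has < 2 replicates")
    sf = size_factors(counts)
    norm = counts / sf
    t_block = norm[groups[treatment]].to_numpy(float)
    c_block = norm[groups[control]].to_numpy(float)
    n_t, n_c = t_block.shape[1], c_block.shape[1]

    mu_t = t_block.mean(axis=1) + PSEUDOCOUNT
    mu_c = c_block.mean(axis=1) + PSEUDOCOUNT
    log2fc = np.log2(mu_t) - np.log2(mu_c)
    base_mean = norm.mean(axis=1).to_numpy()

    # method-of-moments dispersion pooled across both groups:
    # var = mu + alpha * mu^2  =>  alpha = (var - mu) / mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_t = (t_block.var(axis=1, ddof=1) - mu_t) / mu_t**2
        disp_c = (c_block.var(axis=1, ddof=1) - mu_c) / mu_c**2
    disp = np.maximum(np.nanmax(np.c_[disp_t, disp_c], axis=1), DISPERSION_FLOOR)

    # delta-method variance of log2 of a group mean of NB counts
    var_t = (mu_t + disp * mu_t**2) / n_t / (mu_t**2) / np.log(2) ** 2
    var_c = (mu_c + disp * mu_c**2) / n_c / (mu_c**2) / np.log(2) ** 2
    se = np.sqrt(var_t + var_c)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]

    status = np.where(
        (np.abs(log2fc) >= lfc_min) & (q < alpha),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "contrast": f"{treatment}vs{control}",
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "status": status,
        }
    ).set_index("gene_id")


def deg_summary_by_subgenome(
    degs: pd.DataFrame,
    subgenome: pd.Series,
    counts: pd.DataFrame,
    expressed_min_norm_count: float = 1.0,
) -> pd.DataFrame:
    """DEG and expressed-gene totals per subgenome for one contrast.

    "Expressed" means mean normalized count >= ``expressed_min_norm_count``
    across all samples.  The returned 2-row table feeds
    :func:`polysplice.subgenome_bias.chisq_2x2`.
    """
    unlabeled = set(degs.index) - set(subgenome.index)
    if unlabeled:
        raise ValidationError(f"genes without subgenome labels: {sorted(unlabeled)[:5]}")
    norm = counts / size_factors(counts)
    expressed = norm.mean(axis=1) >= expressed_min_norm_count
    rows = []
    for sub in ("A", "B"):
        genes = subgenome.index[subgenome == sub]
        n_expr = int(expressed.reindex(genes).fillna(False).sum())
        deg_genes = degs.index[(degs["status"] != "ns")]
        n_deg = int(subgenome.loc[list(set(deg_genes) & set(genes))].size)
        rows.append({"subgenome": sub, "n_deg": n_deg, "n_expressed": n_expr})
    return pd.DataFrame(rows)
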