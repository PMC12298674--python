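"""Differential-splicing quantification and gained/lost/DAS classification.

For a contrast (treatment, control), ΔPSI = mean PSI in treatment minus
mean PSI in control.  Significance comes from an exact two-sided binomial
test on the pooled treatment inclusion/exclusion reads against the pooled
control PSI as the null proportion.  Significant events
(|ΔPSI| > dpsi_min and p < alpha) are classified:

* **gain** — control PSI nearly 0 or 1 (outside [psi_low, psi_high]) while
  treatment PSI is intermediate: the event newly appears.
* **lost** — mirrored: treatment PSI nearly 0 or 1, control intermediate.
* **DAS** — any other significant quantitative shift.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import sample_groups
from .models import ValidationError

PER_GENE_BINS = ("1", "2", "3", "4", "5", ">5")


@dataclass(frozen=True)
class DseThresholds:
    """Cutoffs for differential-splicing calls."""

    dpsi_min: float = 0.20
    alpha: float = 0.05
    psi_low: float = 0.05
    psi_high: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.psi_low < self.psi_high < 1.0):
            raise ValidationError("require 0 < psi_low < psi_high < 1")


def delta_psi(
    psi: pd.DataFrame, contrast: tuple[str, str], min_replicates: int = 2
) -> pd.DataFrame:
    """Per-event (psi_control, psi_treatment, delta_psi) for a contrast.

    ``contrast`` is (treatment, control).  Events with fewer than
    ``min_replicates`` defined replicate PSIs in either group are skipped.
    """
    treatment, control = contrast
    groups = sample_groups(psi.columns)
    for g in contrast:
        if g not in groups:
            raise ValidationError(f"unknown contrast group {g!r}")
    t_block, c_block = psi[groups[treatment]], psi[groups[control]]
    ok = (t_block.notna().sum(axis=1) >= min_replicates) & (
        c_block.notna().sum(axis=1) >= min_replicates
    )
    out = pd.DataFrame(
        {
            "psi_control": c_block.mean(axis=1)[ok],
            "psi_treatment": t_block.mean(axis=1)[ok],
        }
    )
    out["delta_psi"] = out["psi_treatment"] - out["psi_control"]
    out.index.name = "event_id"
    return out


def binomial_test_event(
    inc_treat: int, exc_treat: int, psi_control_pooled: float
) -> float:
    """Exact two-sided binomial p for the pooled treatment inclusion count.

    Null proportion is the pooled control PSI clipped to [0.01, 0.99];
    two-sided by summing all outcomes with probability ≤ P(observed).
    Returns NaN when there are no treatment reads.
    """
    n = int(inc_treat) + int(exc_treat)
    if n == 0:
        return float("nan")
    p0 = float(np.clip(psi_control_pooled, 0.01, 0.99))
    return float(stats.binomtest(int(inc_treat), n, p0).pvalue)


def classify_dse(
    psi_control: float,
    psi_treatment: float,
    delta: float,
    p: float,
    thresholds: DseThresholds = DseThresholds(),
) -> str:
    """Assign gain / lost / DAS / ns to one event of a contrast."""
    th = thresholds
    if not (abs(delta) > th.dpsi_min and p < th.alpha):
        return "ns"
    ctrl_extreme = psi_control > th.psi_high or psi_control < th.psi_low
    trt_extreme = psi_treatment > th.psi_high or psi_treatment < th.psi_low
    trt_mid = th.psi_low <= psi_treatment <= th.psi_high
    ctrl_mid = th.psi_low <= psi_control <= th.psi_high
    if ctrl_extreme and trt_mid:
        return "gain"
    if trt_extreme and ctrl_mid:
        return "lost"
    return "DAS"


def test_differential_splicing(
    psi: pd.DataFrame,
    counts: pd.DataFrame,
    contrast: tuple[str, str],
    thresholds: DseThresholds = DseThresholds(),
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Full per-event differential-splicing table for one contrast.

    ``psi`` drives ΔPSI and the gain/lost boundaries; ``counts`` (the
    long-form event read-count table) drives the pooled binomial test.
    """
    treatment, control = contrast
    dp = delta_psi(psi, contrast, min_replicates=min_replicates)
    total = counts.assign(
        group=[s.rsplit("_rep", 1)[0] for s in counts["sample"]]
    )
    pooled = (
        total[total["group"].isin(contrast)]
        .groupby(["event_id", "group"])[["inclusion_reads", "exclusion_reads"]]
        .sum()
    )
    records = []
    for event_id, row in dp.iterrows():
        try:
            inc_t, exc_t = pooled.loc[(event_id, treatment)]
            inc_c, exc_c = pooled.loc[(event_id, control)]
        except KeyError:
            continue
        n_c = inc_c + exc_c
        if n_c == 0 or (inc_t + exc_t) == 0:
            continue
        p = binomial_test_event(inc_t, exc_t, inc_c / n_c)
        category = classify_dse(
            row["psi_control"], row["psi_treatment"], row["delta_psi"], p, thresholds
        )
        records.append(
            {
                "event_id": event_id,
                "contrast": f"{treatment}vs{control}",
                "psi_control": row["psi_control"],
                "psi_treatment": row["psi_treatment"],
                "delta_psi": row["delta_psi"],
                "p": p,
                "category": category,
            }
        )
    return pd.DataFrame(
        records,
        columns=["event_id", "contrast", "psi_control", "psi_treatment",
                 "delta_psi", "p", "category"],
    )


def summarize_dse_composition(records: pd.DataFrame) -> pd.DataFrame:
    """Percentages of DAS / gain / lost among significant events, per contrast."""
    sig = records[records["category"] != "ns"]
    rows = []
    for contrast, block in sig.groupby("contrast"):
        total = len(block)
        for cat in ("DAS", "gain", "lost"):
            n = int((block["category"] == cat).sum())
            rows.append(
                {"contrast": contrast, "category": cat, "count": n,
                 "pct": 100.0 * n / total}
            )
    return pd.DataFrame(rows, columns=["contrast", "category", "count", "pct"])


def count_novel_isoforms(
    support: pd.DataFrame,
    transcript_gene: pd.Series,
    baseline: str,
    target: str,
    min_reads: int = 3,
) -> pd.DataFrame:
    """Per-gene counts of isoforms novel in ``target`` relative to ``baseline``.

    A transcript is novel iff it has ``>= min_reads`` in every target
    replicate and ``< min_reads`` in every baseline replicate.  Counts are
    binned over {1,2,3,4,5,>5}.
    """
    groups = sample_groups(support.columns)
    passes_target = (support[groups[target]] >= min_reads).all(axis=1)
    fails_baseline = (support[groups[baseline]] < min_reads).all(axis=1)
    novel = support.index[passes_target & fails_baseline]
    per_gene = transcript_gene.loc[novel].value_counts()
    hist = {b: 0 for b in PER_GENE_BINS}
    for n in per_gene:
        hist[str(n) if n <= 5 else ">5"] += 1
    return pd.DataFrame(
        {"bin": list(PER_GENE_BINS), "n_genes": [hist[b] for b in PER_GENE_BINS]}
    )
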