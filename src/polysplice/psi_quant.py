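"""Percent-spliced-in (PSI) quantification and support filters.

PSI for an event in a sample is the inclusion-form share of the event's
transcript abundance,

    PSI = TPM(inclusion) / (TPM(inclusion) + TPM(exclusion)),

undefined when the denominator is below a small floor.  A count-based
variant (inclusion reads over total event reads) backs the binomial
differential-splicing test.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import sample_groups
from .models import EventCatalog, ValidationError

PSI_TPM_FLOOR = 1e-9


def filter_transcripts_by_support(
    support: pd.DataFrame, min_reads: int = 3, require_all_groups: bool = False
) -> set[str]:
    """Retain transcripts with ``>= min_reads`` in every replicate of at
    least one sample group (default), or of every group if
    ``require_all_groups``.

    ``support`` is a transcript × sample read-count matrix with
    ``GROUP_rep{i}`` column names.
    """
    if (support < 0).any().any():
        raise ValidationError("negative transcript support counts")
    groups = sample_groups(support.columns)
    per_group = pd.DataFrame(
        {g: (support[cols] >= min_reads).all(axis=1) for g, cols in groups.items()}
    )
    keep = per_group.all(axis=1) if require_all_groups else per_group.any(axis=1)
    return set(support.index[keep])


def filter_events_by_support(
    counts: pd.DataFrame, min_reads: int = 3
) -> set[str]:
    """Retain events unless some group has total reads ``<= min_reads`` in
    every replicate.

    ``counts`` is the long-form event read-count table (event_id, sample,
    inclusion_reads, exclusion_reads).
    """
    total = counts.assign(total=counts["inclusion_reads"] + counts["exclusion_reads"])
    wide = total.pivot(index="event_id", columns="sample", values="total")
    groups = sample_groups(wide.columns)
    discard = pd.Series(False, index=wide.index)
    for cols in groups.values():
        discard |= (wide[cols] <= min_reads).all(axis=1)
    return set(wide.index[~discard])


def compute_psi(catalog: EventCatalog, abundance: pd.DataFrame) -> pd.DataFrame:
    """Event × sample PSI matrix from a transcript × sample TPM matrix.

    Missing (NaN) where the event's total abundance is below the floor.
    Raises if an event references a transcript absent from the matrix.
    """
    if (abundance < 0).any().any():
        raise ValidationError("negative abundances")
    known = set(abundance.index)
    rows = {}
    for ev in catalog:
        missing = (ev.inclusion_transcripts | ev.exclusion_transcripts) - known
        if missing:
            raise ValidationError(
                f"event {ev.event_id} references unknown transcripts {sorted(missing)}"
            )
        inc = abundance.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        exc = abundance.loc[sorted(ev.exclusion_transcripts)].sum(axis=0)
        denom = inc + exc
        psi = inc / denom.where(denom >= PSI_TPM_FLOOR)
        rows[ev.event_id] = psi
    out = pd.DataFrame(rows).T
    out.index.name = "event_id"
    return out.reindex(columns=abundance.columns)


def psi_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Count-based PSI: inclusion / (inclusion + exclusion), NaN when no reads."""
    total = counts["inclusion_reads"] + counts["exclusion_reads"]
    psi = counts["inclusion_reads"] / total.where(total > 0)
    wide = counts.assign(psi=psi).pivot(index="event_id", columns="sample", values="psi")
    wide.index.name = "event_id"
    return wide


def tally_active_events(psi: pd.DataFrame) -> pd.DataFrame:
    """Count events with 0 < PSI < 1, per sample and per group.

    The group-level count uses the group-mean PSI over defined replicates
    (the per-group number reported from triplicates); per-sample counts
    are also emitted with ``replicate='rep<i>'`` rows.
    """
    rows = []
    for s in psi.columns:
        n = int(((psi[s] > 0) & (psi[s] < 1)).sum())
        rows.append({"group": s.rsplit("_rep", 1)[0], "sample": s, "n_active": n})
    for g, cols in sample_groups(psi.columns).items():
        mean = psi[cols].mean(axis=1)
        n = int(((mean > 0) & (mean < 1)).sum())
        rows.append({"group": g, "sample": "group_mean", "n_active": n})
    return pd.DataFrame(rows)


def active_event_mask(psi: pd.DataFrame) -> dict[str, set[str]]:
    """Group label -> ids of events with group-mean PSI strictly in (0, 1)."""
    out = {}
    for g, cols in sample_groups(psi.columns).items():
        mean = psi[cols].mean(axis=1)
        out[g] = set(mean.index[(mean > 0) & (mean < 1)])
    return out


def psi_correlation(
    psi: pd.DataFrame, method: str = "pearson", min_events: int = 3
) -> pd.DataFrame:
    """Sample × sample correlation on pairwise-complete PSI values.

    Cells with fewer than ``min_events`` complete event pairs are NaN.
    """
    if psi.shape[1] < 2:
        raise ValidationError("need at least two samples")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    corr = psi.corr(method=method, min_periods=min_events)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def ks_compare_psi(
    psi: pd.DataFrame, group_x: str, group_y: str, min_events: int = 10
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on per-event group-mean PSI.

    Returns (D, asymptotic p).  Requires at least ``min_events`` defined
    group-mean values per group.
    """
    groups = sample_groups(psi.columns)
    for g in (group_x, group_y):
        if g not in groups:
            raise ValidationError(f"unknown group {g!r}")
    x = psi[groups[group_x]].mean(axis=1).dropna().to_numpy()
    y = psi[groups[group_y]].mean(axis=1).dropna().to_numpy()
    if len(x) < min_events or len(y) < min_events:
        raise ValidationError(
            f"need >= {min_events} defined PSI values per group (got {len(x)}, {len(y)})"
        )
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
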