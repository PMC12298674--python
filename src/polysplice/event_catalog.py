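"""Enumeration of local alternative-splicing events from transcript models.

Four event types are called from pairwise differences between the exon
chains of a gene's transcripts:

* **ES** (exon skipping): one form splices an internal exon in, the other
  joins the flanking exons directly.
* **IR** (intron retention): one form retains an intron inside a single
  exon that exactly spans the outer boundaries of the two flanking exons
  of the splicing form (strict rule; a relaxed covering-exon rule is
  available via ``strict_ir=False``).
* **A5** (alternative donor) / **A3** (alternative acceptor): two introns
  share one boundary and differ at the other, with the exons on the
  differing side overlapping.  Donor/acceptor are resolved by strand: on
  the plus strand the intron start is the donor, on the minus strand the
  intron end is.  The inclusion form is the shorter intron (more exonic
  sequence retained).

Events are deduplicated by ``(gene, type, anchor)``; inclusion/exclusion
sets contain every transcript of the gene exhibiting the respective
structure.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    EVENT_TYPES,
    EventCatalog,
    GeneModel,
    SpliceEvent,
    ValidationError,
    format_event_id,
)

__all__ = [
    "enumerate_events",
    "summarize_event_frequencies",
    "events_per_gene_distribution",
    "aggregate_events",
]

PER_GENE_BINS = ("1", "2", "3", "4", "5", ">5")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _enumerate_gene(gene: GeneModel, strict_ir: bool) -> list[SpliceEvent]:
    # collapse structurally identical transcripts before enumeration
    structures: dict[tuple, list[str]] = defaultdict(list)
    for t in gene.transcripts:
        structures[t.structure].append(t.transcript_id)
    chains = list(structures)

    junctions: dict[tuple, set[tuple[int, int]]] = {
        c: set((c[i][1], c[i + 1][0]) for i in range(len(c) - 1)) for c in chains
    }
    all_junctions: set[tuple[int, int]] = set().union(*junctions.values()) if chains else set()

    events: dict[tuple, tuple[str, set[str], set[str]]] = {}

    def members(pred) -> set[str]:
        out: set[str] = set()
        for chain, tids in structures.items():
            if pred(chain):
                out.update(tids)
        return out

    # --- ES ---------------------------------------------------------------
    for chain in chains:
        for i in range(1, len(chain) - 1):
            c1e = chain[i - 1][1]
            a_s, a_e = chain[i]
            c2s = chain[i + 1][0]
            if (c1e, c2s) in all_junctions:
                anchor = (c1e, a_s, a_e, c2s)
                key = ("ES", anchor)
                if key in events:
                    continue
                inc = members(
                    lambda c: any(
                        c[j] == (a_s, a_e)
                        and j > 0
                        and j < len(c) - 1
                        and c[j - 1][1] == c1e
                        and c[j + 1][0] == c2s
                        for j in range(len(c))
                    )
                )
                exc = members(lambda c: (c1e, c2s) in junctions[c])
                events[key] = ("ES", inc, exc)

    # --- IR ---------------------------------------------------------------
    for chain in chains:
        for i in range(len(chain) - 1):
            a, c1e = chain[i]
            c2s, b = chain[i + 1]
            anchor = (a, c1e, c2s, b)
            key = ("IR", anchor)
            if key in events:
                continue
            if strict_ir:
                retains = members(lambda c: (a, b) in c)
            else:
                retains = members(
                    lambda c: any(x <= c1e and y >= c2s for x, y in c)
                )
            if not retains:
                continue
            exc = members(
                lambda c: any(
                    c[j] == (a, c1e) and c[j + 1] == (c2s, b)
                    for j in range(len(c) - 1)
                )
            )
            events[key] = ("IR", retains, exc)

    # --- A5 / A3 ----------------------------------------------------------
    # occurrence = (intron, upstream exon, downstream exon)
    occ: dict[tuple[int, int], list[tuple[tuple, tuple]]] = defaultdict(list)
    for chain in chains:
        for i in range(len(chain) - 1):
            intron = (chain[i][1], chain[i + 1][0])
            occ[intron].append((chain[i], chain[i + 1]))

    by_end: dict[int, set] = defaultdict(set)
    by_start: dict[int, set] = defaultdict(set)
    for intron in occ:
        by_start[intron[0]].add(intron)
        by_end[intron[1]].add(intron)

    def emit_alt(i1: tuple[int, int], i2: tuple[int, int], shared: str) -> None:
        """i1, i2 share one boundary; emit A5/A3 if variable-side exons overlap."""
        side = 0 if shared == "end" else 1  # exon index within occurrence tuple
        if not any(
            _overlap(o1[side], o2[side])
            for o1 in occ[i1]
            for o2 in occ[i2]
        ):
            return
        # shared end => introns differ at their start; on '+' the start is
        # the donor, hence A5; mirrored on '-'
        if shared == "end":
            etype = "A5" if gene.strand == "+" else "A3"
        else:
            etype = "A3" if gene.strand == "+" else "A5"
        short, long_ = sorted((i1, i2), key=lambda iv: iv[1] - iv[0])
        first, second = sorted((i1, i2))
        anchor = (*first, *second)
        key = (etype, anchor)
        if key in events:
            return
        inc = members(lambda c: short in junctions[c])
        exc = members(lambda c: long_ in junctions[c])
        events[key] = (etype, inc, exc)

    for introns in by_end.values():
        group = sorted(introns)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                emit_alt(group[i], group[j], "end")
    for introns in by_start.values():
        group = sorted(introns)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                emit_alt(group[i], group[j], "start")

    out = []
    for (etype, anchor), (_, inc, exc) in sorted(events.items()):
        out.append(
            SpliceEvent(
                event_id=format_event_id(gene.gene_id, etype, gene.chrom, anchor, gene.strand),
                gene_id=gene.gene_id,
                etype=etype,
                chrom=gene.chrom,
                strand=gene.strand,
                anchor=anchor,
                inclusion_transcripts=frozenset(inc),
                exclusion_transcripts=frozenset(exc),
            )
        )
    return out


def enumerate_events(genes: Iterable[GeneModel], strict_ir: bool = True) -> EventCatalog:
    """Enumerate IR/ES/A5/A3 events across a set of gene models.

    Parameters
    ----------
    genes
        Gene models whose transcripts have validated exon chains.
    strict_ir
        If True (default), an intron-retention call requires the retaining
        exon to span exactly the outer boundaries of the two flanking
        exons of the splicing form; if False, any exon covering the intron
        qualifies.
    """
    events: list[SpliceEvent] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        events.extend(_enumerate_gene(gene, strict_ir))
    return EventCatalog(events)


def _active_ids(catalog: EventCatalog, mask: Mapping[str, Iterable[str]] | None, group: str) -> set[str]:
    if mask is None:
        return set(catalog.event_ids)
    return set(mask[group]) & set(catalog.event_ids)


def summarize_event_frequencies(
    catalog: EventCatalog, mask: Mapping[str, Iterable[str]] | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group counts and percentages of active events by type.

    ``mask`` maps group label -> iterable of active event ids (e.g. the
    events with 0 < PSI < 1 in that group).  With ``mask=None`` a single
    row labelled ``all`` summarizes the whole catalog.
    """
    if mask is None:
        groups = ["all"]
        mask = {"all": catalog.event_ids}
    elif groups is None:
        groups = list(mask)
    etype_of = {ev.event_id: ev.etype for ev in catalog}
    rows = []
    for g in groups:
        ids = _active_ids(catalog, mask, g)
        counts = {t: 0 for t in EVENT_TYPES}
        for eid in ids:
            counts[etype_of[eid]] += 1
        total = sum(counts.values())
        for t in EVENT_TYPES:
            pct = 100.0 * counts[t] / total if total else np.nan
            rows.append({"group": g, "etype": t, "count": counts[t], "pct": pct, "total": total})
    return pd.DataFrame(rows)


def events_per_gene_distribution(
    catalog: EventCatalog, mask: Mapping[str, Iterable[str]] | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Histogram of active events per gene over bins {1,2,3,4,5,>5}.

    Returned long-form with one row per (group, etype-or-'all', bin);
    histogram mass per (group, etype) equals the number of active genes
    carrying at least one event of that type.
    """
    if mask is None:
        groups = ["all"]
        mask = {"all": catalog.event_ids}
    elif groups is None:
        groups = list(mask)
    info = {ev.event_id: (ev.gene_id, ev.etype) for ev in catalog}
    rows = []
    for g in groups:
        ids = _active_ids(catalog, mask, g)
        per_gene: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        for eid in ids:
            gene, etype = info[eid]
            per_gene[gene][etype] += 1
            per_gene[gene]["all"] += 1
        for etype in ("all",) + tuple(EVENT_TYPES):
            hist = {b: 0 for b in PER_GENE_BINS}
            for gene, counts in per_gene.items():
                n = counts.get(etype, 0)
                if n == 0:
                    continue
                hist[str(n) if n <= 5 else ">5"] += 1
            for b in PER_GENE_BINS:
                rows.append({"group": g, "etype": etype, "bin": b, "n_genes": hist[b]})
    return pd.DataFrame(rows)


def aggregate_events(
    catalog: EventCatalog, mask: Mapping[str, Iterable[str]] | None = None,
    bin_size: int = 1_000_000, groups: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Aggregate active events by chromosome, subgenome and genomic bin.

    Chromosome names must end in ``A`` or ``B`` (the subgenome suffix).
    Returns three long-form tables keyed ``chromosome``, ``subgenome`` and
    ``bins``; per-bin counts sum to chromosome counts and subgenome totals
    to the sum of member chromosomes.
    """
    if mask is None:
        groups = ["all"]
        mask = {"all": catalog.event_ids}
    elif groups is None:
        groups = list(mask)
    by_id = {ev.event_id: ev for ev in catalog}
    for ev in catalog:
        if ev.chrom[-1] not in ("A", "B"):
            raise ValidationError(f"chromosome {ev.chrom!r} lacks an A/B subgenome suffix")
    chrom_rows, sub_rows, bin_rows = [], [], []
    for g in groups:
        ids = _active_ids(catalog, mask, g)
        chrom_counts: dict[tuple, int] = defaultdict(int)
        bin_counts: dict[tuple, int] = defaultdict(int)
        for eid in ids:
            ev = by_id[eid]
            chrom_counts[(ev.chrom, ev.etype)] += 1
            bin_counts[(ev.chrom, ev.anchor[0] // bin_size, ev.etype)] += 1
        sub_counts: dict[tuple, int] = defaultdict(int)
        for (chrom, etype), n in sorted(chrom_counts.items()):
            chrom_rows.append({"group": g, "chrom": chrom, "etype": etype, "count": n})
            sub_counts[(chrom[-1], etype)] += n
        for (sub, etype), n in sorted(sub_counts.items()):
            sub_rows.append({"group": g, "subgenome": sub, "etype": etype, "count": n})
        for (chrom, b, etype), n in sorted(bin_counts.items()):
            bin_rows.append(
                {"group": g, "chrom": chrom, "bin_start": b * bin_size, "etype": etype, "count": n}
            )
    return {
        "chromosome": pd.DataFrame(chrom_rows),
        "subgenome": pd.DataFrame(sub_rows),
        "bins": pd.DataFrame(bin_rows),
    }
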