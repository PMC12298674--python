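"""Readers and writers for the pipeline's on-disk formats.

Formats: GTF (1-based inclusive, ``gene_id``/``transcript_id`` attributes),
TSV matrices with a header row of sample names ``GROUP_rep{i}``, a long-form
event read-count table, 12-column BLAST tabular (outfmt 6), a two-column
gene→term map, and an ioe-like event-catalog TSV.
"""
from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .models import EventCatalog, GeneModel, SpliceEvent, TranscriptModel, ValidationError

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_sample_name(sample: str) -> tuple[str, int]:
    """Split ``GROUP_rep{i}`` into (group, replicate index)."""
    m = re.fullmatch(r"(.+)_rep(\d+)", sample)
    if m is None:
        raise ValidationError(f"sample name {sample!r} does not match 'GROUP_rep<i>'")
    return m.group(1), int(m.group(2))


def sample_groups(samples: Iterable[str]) -> dict[str, list[str]]:
    """Map group label -> ordered sample names."""
    out: dict[str, list[str]] = defaultdict(list)
    for s in samples:
        out[parse_sample_name(s)[0]].append(s)
    return dict(out)


# --- GTF -------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file (exon features only).

    GTF coordinates are 1-based inclusive; they are converted to the
    library's 0-based half-open convention.
    """
    exons: dict[str, list] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValidationError(f"malformed GTF line: {line!r}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "exon":
                continue
            d = dict(_ATTR_RE.findall(attrs))
            try:
                gid, tid = d["gene_id"], d["transcript_id"]
            except KeyError as exc:
                raise ValidationError(f"GTF attributes missing {exc} in: {line!r}")
            exons[tid].append((int(start) - 1, int(end)))
            meta[tid] = (gid, chrom, strand)
    genes: dict[str, list[TranscriptModel]] = defaultdict(list)
    for tid, ivs in exons.items():
        gid, chrom, strand = meta[tid]
        genes[gid].append(
            TranscriptModel(tid, gid, chrom, strand, tuple(sorted(ivs)))
        )
    return [
        GeneModel(gid, ts[0].chrom, ts[0].strand, tuple(sorted(ts, key=lambda t: t.transcript_id)))
        for gid, ts in sorted(genes.items())
    ]


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: g.gene_id):
            for t in gene.transcripts:
                for start, end in t.exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                    fh.write(
                        "\t".join(
                            [gene.chrom, "polysplice", "exon", str(start + 1), str(end),
                             ".", gene.strand, ".", attrs]
                        )
                        + "\n"
                    )


# --- matrices --------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature × sample TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for s in df.columns:
        parse_sample_name(s)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


# --- event read counts ------------------------------------------------------

def read_event_counts(path: str | Path) -> pd.DataFrame:
    """Long-form table: event_id, sample, inclusion_reads, exclusion_reads."""
    df = pd.read_csv(path, sep="\t")
    expected = {"event_id", "sample", "inclusion_reads", "exclusion_reads"}
    if set(df.columns) != expected:
        raise ValidationError(f"event-count table columns {list(df.columns)} != {sorted(expected)}")
    if (df[["inclusion_reads", "exclusion_reads"]] < 0).any().any():
        raise ValidationError("negative event read counts")
    return df


def write_event_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- BLAST tabular ---------------------------------------------------------

def read_blast6(path: str | Path) -> pd.DataFrame:
    """Read a headerless 12-column BLAST outfmt-6 hit table."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed BLAST tabular file {path}: {exc}") from exc
    if df["pident"].isna().any() or df["bitscore"].isna().any():
        bad = int(df.index[df["pident"].isna() | df["bitscore"].isna()][0]) + 1
        raise ValidationError(f"malformed BLAST tabular row at line {bad}")
    return df


def write_blast6(df: pd.DataFrame, path: str | Path) -> None:
    df[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# --- gene → term map --------------------------------------------------------

def read_gene2term(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> term_id -> gene set."""
    out: dict[str, set[str]] = defaultdict(set)
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValidationError(f"gene2term line {i}: expected 2 columns")
            gene, term = parts
            out[term].add(gene)
    return dict(out)


def write_gene2term(term_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{gene}\t{term}\n")


# --- event catalog ----------------------------------------------------------

def write_catalog(catalog: EventCatalog, path: str | Path) -> None:
    """ioe-like TSV: event_id, gene_id, etype, inclusion and total transcripts."""
    rows = []
    for ev in catalog:
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "etype": ev.etype,
                "inclusion_transcripts": ",".join(sorted(ev.inclusion_transcripts)),
                "total_transcripts": ",".join(
                    sorted(ev.inclusion_transcripts | ev.exclusion_transcripts)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> EventCatalog:
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, row in df.iterrows():
        gene_part, rest = row["event_id"].split(";", 1)
        etype, chrom, p1, p2, strand = rest.split(":")
        a, b = map(int, p1.split("-"))
        c, d = map(int, p2.split("-"))
        inc = frozenset(str(row["inclusion_transcripts"]).split(","))
        tot = frozenset(str(row["total_transcripts"]).split(","))
        events.append(
            SpliceEvent(
                event_id=row["event_id"], gene_id=gene_part, etype=etype,
                chrom=chrom, strand=strand, anchor=(a, b, c, d),
                inclusion_transcripts=inc, exclusion_transcripts=tot - inc,
            )
        )
    return EventCatalog(events)
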