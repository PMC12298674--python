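"""Synthetic allotetraploid transcriptome generator.

Emulates the study design the pipeline targets: a two-subgenome (A/B)
genome with 1:1 homoeolog pairs, transcript isoforms realizing planted
IR/ES/A5/A3 events, three condition groups (healthy AG, lesion-adjacent
BG, lesion-core CG) with replicated negative-binomial counts, planted
differential-splicing events (gained / lost / DAS / stable), planted
DEGs at a stated fold change, and planted subgenome-bias transitions.
The planted-effect ledger (:class:`SimTruth`) is the oracle for recovery
tests.

Planted splicing and bias effects are placed in CG relative to AG, with
BG matching AG unless a bias transition label says otherwise, so the
CG-vs-AG contrast carries every planted effect.

Counts use a shared-dispersion negative-binomial noise model; event
read counts are binomial draws around the planted PSI at a configured
coverage depth (the pipeline consumes counts, not reads).  A noise-free
mode substitutes deterministic means for draws, for exact classifier
round-trips.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .models import GeneModel, TranscriptModel, ValidationError, format_event_id
from .subgenome_bias import HomoeologPair

DEFAULT_EVENTS_PER_CATEGORY = {"IR": 8, "ES": 8, "A5": 8, "A3": 8}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator."""

    n_genes_per_subgenome: int = 200
    n_chromosomes_per_subgenome: int = 2
    groups: tuple[str, ...] = ("AG", "BG", "CG")
    replicates_per_group: int = 3
    planted_event_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            cat: dict(DEFAULT_EVENTS_PER_CATEGORY)
            for cat in ("gain", "lost", "das", "stable")
        }
    )
    planted_deg_count: int = 60
    planted_bias_shift_counts: dict[str, int] = field(
        default_factory=lambda: {
            "AG_balanced->CG_B-bias": 20,
            "AG_balanced->CG_A-bias": 12,
            "AG_A-bias->CG_B-bias": 8,
            "AG_balanced->CG_balanced": 20,
        }
    )
    nb_dispersion: float = 0.05
    library_size: int = 1_000_000
    deg_log2fc: float = 3.0
    das_delta_psi: float = 0.4
    event_coverage: int = 50
    a_surplus: float = 0.10
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_per_subgenome < 1 or self.n_chromosomes_per_subgenome < 1:
            raise ConfigurationError("gene and chromosome counts must be positive")
        if self.replicates_per_group < 1:
            raise ConfigurationError("replicates_per_group must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        if self.deg_log2fc < 2:
            raise ConfigurationError("deg_log2fc must be >= 2")
        if not (0.2 < self.das_delta_psi <= 0.9):
            raise ConfigurationError("das_delta_psi must lie in (0.2, 0.9]")
        for cat, per_type in self.planted_event_counts.items():
            if cat not in ("gain", "lost", "das", "stable"):
                raise ConfigurationError(f"unknown planted event category {cat!r}")
            for etype, n in per_type.items():
                if etype not in ("IR", "ES", "A5", "A3") or n < 0:
                    raise ConfigurationError(f"bad planted count {etype}={n} in {cat!r}")
        if self.planted_deg_count < 0:
            raise ConfigurationError("planted_deg_count must be >= 0")
        for label, n in self.planted_bias_shift_counts.items():
            _parse_transition_label(label, self.groups)
            if n < 0:
                raise ConfigurationError(f"negative bias-shift count for {label!r}")

    @property
    def n_a(self) -> int:
        return round(self.n_genes_per_subgenome * (1 + self.a_surplus))

    @property
    def n_b(self) -> int:
        return self.n_genes_per_subgenome

    @property
    def samples(self) -> list[str]:
        return [
            f"{g}_rep{i}" for g in self.groups
            for i in range(1, self.replicates_per_group + 1)
        ]


@dataclass
class SimTruth:
    """Planted-effect ledger: the oracle for recovery tests."""

    events: pd.DataFrame   # event_id, gene_id, etype, category, contrast, psi per group, delta
    genes: pd.DataFrame    # gene_id, contrast, log2fc, is_deg
    pairs: pd.DataFrame    # pair_id, gene_a, gene_b, klass_<group>..., transition labels


@dataclass
class SimData:
    """Complete synthetic dataset."""

    genes: list[GeneModel]
    pairs: list[HomoeologPair]
    truth: SimTruth
    abundance: pd.DataFrame          # transcript x sample TPM
    gene_counts: pd.DataFrame        # gene x sample integer counts
    event_counts: pd.DataFrame       # long-form inclusion/exclusion reads
    transcript_support: pd.DataFrame  # transcript x sample read counts
    hits: pd.DataFrame               # BLAST outfmt-6 table
    term_map: dict[str, set[str]]
    config: SimConfig


_CLASS_ALIASES = {"balance": "balanced", "balanced": "balanced",
                  "A-bias": "A-bias", "B-bias": "B-bias",
                  "low-expression": "low-expression"}


def _parse_transition_label(label: str, groups: tuple[str, ...]) -> tuple[str, str, str, str]:
    try:
        left, right = label.split("->")
        g1, c1 = left.split("_", 1)
        g2, c2 = right.split("_", 1)
        c1, c2 = _CLASS_ALIASES[c1], _CLASS_ALIASES[c2]
    except (ValueError, KeyError):
        raise ConfigurationError(f"cannot parse bias transition label {label!r}")
    if g1 not in groups or g2 not in groups:
        raise ConfigurationError(f"transition label {label!r} names unknown groups")
    return g1, c1, g2, c2


# --- transcript templates ---------------------------------------------------
# Exon chains (relative to the gene start) realizing exactly one event of
# the requested type; inclusion transcript first.

def _event_template(etype: str, strand: str) -> tuple[list, list, tuple]:
    es = ([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)], (100, 200, 300, 400))
    ir = ([(0, 300)], [(0, 100), (200, 300)], (0, 100, 200, 300))
    # introns sharing their end (150,200) vs (100,200): A5 on '+', A3 on '-'
    shared_end = ([(0, 150), (200, 300)], [(0, 100), (200, 300)], (100, 200, 150, 200))
    # introns sharing their start (100,150) vs (100,200): A3 on '+', A5 on '-'
    shared_start = ([(0, 100), (150, 300)], [(0, 100), (200, 300)], (100, 150, 100, 200))
    if etype == "ES":
        return es
    if etype == "IR":
        return ir
    if etype == "A5":
        return shared_end if strand == "+" else shared_start
    if etype == "A3":
        return shared_start if strand == "+" else shared_end
    raise ValidationError(f"unknown event type {etype!r}")


def _shift(exons: list, base: int) -> tuple:
    return tuple((s + base, e + base) for s, e in exons)


def generate_annotation(
    config: SimConfig,
) -> tuple[list[GeneModel], list[HomoeologPair], SimTruth]:
    """Lay out the synthetic genome and decide all planted effects.

    Genes are placed on chromosomes ``chr01A..chrNNA`` / ``chr01B..``;
    each planted-event gene carries an inclusion and an exclusion
    transcript realizing exactly the planted event type.  Homoeolog
    pairs are 1:1 across subgenomes.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    contrast = f"{config.groups[-1]}vs{config.groups[0]}"  # CGvsAG by default

    n_pairs_planted = sum(config.planted_bias_shift_counts.values())
    n_events = sum(sum(d.values()) for d in config.planted_event_counts.values())
    n_pairs_extra = min(10, max(0, config.n_b - n_pairs_planted - 1))
    n_pairs = n_pairs_planted + n_pairs_extra

    # capacity: pairs occupy the leading indices of both subgenomes; event
    # and DEG genes take fresh indices, alternating subgenomes
    need_b = n_pairs + math.ceil(n_events / 2) + math.ceil(config.planted_deg_count / 2)
    need_a = n_pairs + math.ceil(n_events / 2) + math.ceil(config.planted_deg_count / 2)
    if need_a > config.n_a or need_b > config.n_b:
        raise ConfigurationError(
            f"planted effects need {max(need_a, need_b)} genes per subgenome but "
            f"capacity is A={config.n_a}, B={config.n_b} "
            f"(pairs={n_pairs}, events={n_events}, degs={config.planted_deg_count})"
        )

    gene_ids = {
        "A": [f"gA{i:04d}" for i in range(1, config.n_a + 1)],
        "B": [f"gB{i:04d}" for i in range(1, config.n_b + 1)],
    }

    # --- assign roles ------------------------------------------------------
    pair_rows = []
    idx = 0
    for label, count in sorted(config.planted_bias_shift_counts.items()):
        g1, c1, g2, c2 = _parse_transition_label(label, config.groups)
        for _ in range(count):
            classes = {}
            for g in config.groups:
                if g == g2:
                    classes[g] = c2
                elif g == g1:
                    classes[g] = c1
                else:
                    classes[g] = c1  # unnamed groups track the "from" state
            pair_rows.append(
                {"pair_id": f"{gene_ids['A'][idx]}|{gene_ids['B'][idx]}",
                 "gene_a": gene_ids["A"][idx], "gene_b": gene_ids["B"][idx],
                 "label": label, **{f"klass_{g}": classes[g] for g in config.groups}}
            )
            idx += 1
    for _ in range(n_pairs_extra):
        pair_rows.append(
            {"pair_id": f"{gene_ids['A'][idx]}|{gene_ids['B'][idx]}",
             "gene_a": gene_ids["A"][idx], "gene_b": gene_ids["B"][idx],
             "label": "unplanted",
             **{f"klass_{g}": "balanced" for g in config.groups}}
        )
        idx += 1
    pairs_df = pd.DataFrame(
        pair_rows,
        columns=["pair_id", "gene_a", "gene_b", "label"]
        + [f"klass_{g}" for g in config.groups],
    )
    if not pairs_df.empty:
        ctrl, trt = config.groups[0], config.groups[-1]
        pairs_df[f"transition_{contrast}"] = [
            f"{ctrl}_{r[f'klass_{ctrl}']}->{trt}_{r[f'klass_{trt}']}"
            for _, r in pairs_df.iterrows()
        ]

    next_idx = {"A": n_pairs, "B": n_pairs}
    alternator = 0

    def fresh_gene(sub: str | None = None) -> str:
        nonlocal alternator
        if sub is None:
            sub = "A" if alternator % 2 == 0 else "B"
            alternator += 1
        gid = gene_ids[sub][next_idx[sub]]
        next_idx[sub] += 1
        return gid

    event_rows = []
    for cat in ("gain", "lost", "das", "stable"):
        per_type = config.planted_event_counts.get(cat, {})
        for etype in ("IR", "ES", "A5", "A3"):
            for _ in range(per_type.get(etype, 0)):
                event_rows.append({"gene_id": fresh_gene(), "etype": etype, "category": cat})

    gene_rows = []
    for k, row in enumerate(event_rows):
        sign = 1 if k % 2 == 0 else -1
        cat = row["category"]
        d = config.das_delta_psi
        if cat == "gain":
            psi_ctrl = 0.98 if sign > 0 else 0.02
            psi_trt = 0.5
        elif cat == "lost":
            psi_ctrl = 0.5
            psi_trt = 0.98 if sign > 0 else 0.02
        elif cat == "das":
            lo, hi = 0.5 - d / 2, 0.5 + d / 2
            lo, hi = max(lo, 0.055), min(hi, 0.945)
            psi_ctrl, psi_trt = (lo, hi) if sign > 0 else (hi, lo)
        else:  # stable
            psi_ctrl = psi_trt = float(rng.uniform(0.25, 0.75))
        row.update(
            {"contrast": contrast, "psi_control": psi_ctrl, "psi_treatment": psi_trt,
             "planted_delta_psi": psi_trt - psi_ctrl}
        )

    deg_rows = []
    for k in range(config.planted_deg_count):
        sign = 1 if k % 2 == 0 else -1
        deg_rows.append(
            {"gene_id": fresh_gene(), "contrast": contrast,
             "log2fc": sign * config.deg_log2fc, "is_deg": True}
        )

    # --- build gene models -------------------------------------------------
    event_by_gene = {r["gene_id"]: r for r in event_rows}
    genes: list[GeneModel] = []
    positions = {"A": {}, "B": {}}
    for sub in ("A", "B"):
        n_chrom = config.n_chromosomes_per_subgenome
        cursor = {c: 1000 for c in range(n_chrom)}
        for i, gid in enumerate(gene_ids[sub]):
            c = i % n_chrom
            chrom = f"chr{c + 1:02d}{sub}"
            base = cursor[c]
            cursor[c] += 10_000
            positions[sub][gid] = (chrom, base)

    for sub in ("A", "B"):
        for gid in gene_ids[sub]:
            chrom, base = positions[sub][gid]
            strand = "+" if rng.random() < 0.5 else "-"
            if gid in event_by_gene:
                row = event_by_gene[gid]
                inc, exc, anchor = _event_template(row["etype"], strand)
                anchor = tuple(a + base for a in anchor)
                t_inc = TranscriptModel(f"{gid}.t1", gid, chrom, strand, _shift(inc, base))
                t_exc = TranscriptModel(f"{gid}.t2", gid, chrom, strand, _shift(exc, base))
                genes.append(GeneModel(gid, chrom, strand, (t_inc, t_exc)))
                row["event_id"] = format_event_id(gid, row["etype"], chrom, anchor, strand)
                row["inclusion_transcript"] = t_inc.transcript_id
                row["exclusion_transcript"] = t_exc.transcript_id
            else:
                n_exons = int(rng.integers(1, 5))
                exons, pos = [], base
                for _ in range(n_exons):
                    length = int(rng.integers(80, 300))
                    exons.append((pos, pos + length))
                    pos += length + int(rng.integers(60, 200))
                t = TranscriptModel(f"{gid}.t1", gid, chrom, strand, tuple(exons))
                genes.append(GeneModel(gid, chrom, strand, (t,)))

    pairs = [
        HomoeologPair(r["pair_id"], r["gene_a"], r["gene_b"],
                      identity_pct=float(rng.uniform(91.0, 99.0)))
        for _, r in pairs_df.iterrows()
    ]
    events_df = pd.DataFrame(
        event_rows,
        columns=["event_id", "gene_id", "etype", "category", "contrast",
                 "psi_control", "psi_treatment", "planted_delta_psi",
                 "inclusion_transcript", "exclusion_transcript"],
    )
    genes_df = pd.DataFrame(deg_rows, columns=["gene_id", "contrast", "log2fc", "is_deg"])
    truth = SimTruth(events=events_df, genes=genes_df, pairs=pairs_df)
    return genes, pairs, truth


_BIAS_SPLIT = {
    # (share of pair total for A, for B); log2 ratio = ±2 for biased classes
    "balanced": (1.0, 1.0),
    "A-bias": (1.6, 0.4),
    "B-bias": (0.4, 1.6),
}


def generate_expression(
    genes: list[GeneModel],
    pairs: list[HomoeologPair],
    truth: SimTruth,
    config: SimConfig,
) -> SimData:
    """Realize count, abundance and event-read matrices around the truth.

    Gene counts are negative-binomial around group means built from a
    common baseline, the planted fold changes, and the planted bias
    ratios; per-sample expected totals are normalized to
    ``library_size``.  Event inclusion reads are binomial around the
    planted PSI at ``event_coverage`` depth; transcript abundances are
    split by the realized PSI so abundance-derived and count-derived PSI
    agree.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = config.samples
    group_of = {s: s.rsplit("_rep", 1)[0] for s in samples}
    gene_index = [g.gene_id for g in genes]
    n_genes = len(gene_index)

    # baseline relative expression
    base = rng.gamma(shape=2.0, scale=1.0, size=n_genes)
    base = np.maximum(base, 0.05)
    base_s = pd.Series(base, index=gene_index)

    # group mean matrix before normalization
    mean = pd.DataFrame(
        {g: base_s.copy() for g in config.groups}, index=gene_index, dtype=float
    )

    contrast = f"{config.groups[-1]}vs{config.groups[0]}"
    trt = config.groups[-1]
    for _, row in truth.genes.iterrows():
        mean.at[row["gene_id"], trt] = base_s[row["gene_id"]] * 2.0 ** row["log2fc"]

    for _, row in truth.pairs.iterrows():
        for g in config.groups:
            klass = row[f"klass_{g}"]
            total = base_s[row["gene_a"]] + base_s[row["gene_b"]]
            if klass == "low-expression":
                # both members far below the expression floor
                mean.at[row["gene_a"], g] = 1e-3
                mean.at[row["gene_b"], g] = 1e-3
            else:
                fa, fb = _BIAS_SPLIT[klass]
                mean.at[row["gene_a"], g] = total / 2 * fa
                mean.at[row["gene_b"], g] = total / 2 * fb

    # normalize each group's expected total to the library size
    mu = pd.DataFrame(index=gene_index, columns=samples, dtype=float)
    for s in samples:
        col = mean[group_of[s]]
        mu[s] = col / col.sum() * config.library_size

    if config.noise_free:
        counts = mu.round().astype(int)
    else:
        r = 1.0 / config.nb_dispersion
        p = r / (r + mu.to_numpy())
        counts = pd.DataFrame(
            rng.negative_binomial(r, p), index=gene_index, columns=samples
        )
    counts.index.name = "gene_id"

    # --- event read counts and realized PSI --------------------------------
    ev_rows = []
    psi_realized: dict[tuple[str, str], float] = {}
    control = config.groups[0]
    for _, row in truth.events.iterrows():
        for s in samples:
            g = group_of[s]
            target = row["psi_treatment"] if g == trt else row["psi_control"]
            if config.noise_free:
                depth = config.event_coverage
                inc = int(round(depth * target))
            else:
                depth = max(1, int(rng.poisson(config.event_coverage)))
                inc = int(rng.binomial(depth, target))
            ev_rows.append(
                {"event_id": row["event_id"], "sample": s,
                 "inclusion_reads": inc, "exclusion_reads": depth - inc}
            )
            psi_realized[(row["gene_id"], s)] = inc / depth
    event_counts = pd.DataFrame(
        ev_rows, columns=["event_id", "sample", "inclusion_reads", "exclusion_reads"]
    )

    # --- transcript abundance (TPM) and support ----------------------------
    totals = counts.sum(axis=0).astype(float)
    tpm_gene = counts / totals * 1e6
    t_rows: dict[str, dict[str, float]] = {}
    s_rows: dict[str, dict[str, int]] = {}
    for gene in genes:
        gid = gene.gene_id
        if len(gene.transcripts) == 2 and (gid, samples[0]) in psi_realized:
            t_inc, t_exc = gene.transcripts
            for s in samples:
                psi = psi_realized[(gid, s)]
                t_rows.setdefault(t_inc.transcript_id, {})[s] = tpm_gene.at[gid, s] * psi
                t_rows.setdefault(t_exc.transcript_id, {})[s] = tpm_gene.at[gid, s] * (1 - psi)
                s_rows.setdefault(t_inc.transcript_id, {})[s] = int(round(counts.at[gid, s] * psi))
                s_rows.setdefault(t_exc.transcript_id, {})[s] = int(round(counts.at[gid, s] * (1 - psi)))
        else:
            for t in gene.transcripts:
                share = 1.0 / len(gene.transcripts)
                for s in samples:
                    t_rows.setdefault(t.transcript_id, {})[s] = tpm_gene.at[gid, s] * share
                    s_rows.setdefault(t.transcript_id, {})[s] = int(round(counts.at[gid, s] * share))
    abundance = pd.DataFrame(t_rows).T[samples]
    abundance.index.name = "transcript_id"
    support = pd.DataFrame(s_rows).T[samples]
    support.index.name = "transcript_id"

    hits = _make_hit_table(pairs, gene_index, rng)
    term_map = _make_term_map(truth, gene_index, rng)

    return SimData(
        genes=genes, pairs=pairs, truth=truth, abundance=abundance,
        gene_counts=counts, event_counts=event_counts,
        transcript_support=support, hits=hits, term_map=term_map, config=config,
    )


def _make_hit_table(
    pairs: list[HomoeologPair], gene_index: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Both-direction BLAST rows for every pair, plus weaker decoy hits."""
    rows = []

    def hit(q, s, pident, bitscore):
        length = 400
        mismatch = int(round(length * (100 - pident) / 100))
        rows.append(
            {"qseqid": q, "sseqid": s, "pident": round(pident, 2), "length": length,
             "mismatch": mismatch, "gapopen": 0, "qstart": 1, "qend": length,
             "sstart": 1, "send": length, "evalue": 1e-50, "bitscore": round(bitscore, 1)}
        )

    for k, pair in enumerate(pairs):
        score = float(rng.uniform(600, 900))
        hit(pair.gene_a, pair.gene_b, pair.identity_pct, score)
        hit(pair.gene_b, pair.gene_a, pair.identity_pct, score)
        # weaker off-target hit against a neighboring pair's partner
        if k + 1 < len(pairs):
            other = pairs[k + 1]
            hit(pair.gene_a, other.gene_b, float(rng.uniform(60, 85)), score * 0.5)
    # a non-reciprocal decoy: high identity one way only
    unpaired = [g for g in gene_index if not any(g in (p.gene_a, p.gene_b) for p in pairs)]
    if len(unpaired) >= 2 and pairs:
        hit(unpaired[0], pairs[0].gene_b, 95.0, 100.0)
    return pd.DataFrame(rows, columns=psio.BLAST6_COLUMNS)


def _make_term_map(
    truth: SimTruth, gene_index: list[str], rng: np.random.Generator
) -> dict[str, set[str]]:
    """Gene→term annotation with one term enriched among planted DEGs."""
    term_map: dict[str, set[str]] = {}
    deg_genes = list(truth.genes["gene_id"]) if not truth.genes.empty else []
    if deg_genes:
        n_core = max(3, int(0.6 * len(deg_genes)))
        extras = [g for g in gene_index if g not in deg_genes]
        pad = list(rng.choice(extras, size=min(5, len(extras)), replace=False))
        term_map["TERM_DEG_RESPONSE"] = set(deg_genes[:n_core]) | set(pad)
    for i in range(8):
        size = int(rng.integers(5, max(6, len(gene_index) // 10)))
        members = rng.choice(gene_index, size=min(size, len(gene_index)), replace=False)
        term_map[f"TERM{i:03d}"] = set(members)
    return term_map


def simulate(config: SimConfig) -> SimData:
    """Convenience: annotation + expression in one call."""
    genes, pairs, truth = generate_annotation(config)
    return generate_expression(genes, pairs, truth, config)


def write_fixture_bundle(data: SimData, directory: str | Path) -> dict[str, Path]:
    """Write the full fixture set; files round-trip through the readers."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {d}: {exc}") from exc
    paths = {
        "gtf": d / "annotation.gtf",
        "abundance": d / "abundance.tsv",
        "gene_counts": d / "gene_counts.tsv",
        "event_counts": d / "event_counts.tsv",
        "transcript_support": d / "transcript_support.tsv",
        "hits": d / "hits.tsv",
        "gene2term": d / "gene2term.tsv",
        "truth_events": d / "truth_events.tsv",
        "truth_genes": d / "truth_genes.tsv",
        "truth_pairs": d / "truth_pairs.tsv",
        "config": d / "sim_config.json",
    }
    psio.write_gtf(data.genes, paths["gtf"])
    psio.write_matrix(data.abundance, paths["abundance"], index_label="transcript_id")
    psio.write_matrix(data.gene_counts, paths["gene_counts"], index_label="gene_id")
    psio.write_event_counts(data.event_counts, paths["event_counts"])
    psio.write_matrix(data.transcript_support, paths["transcript_support"],
                      index_label="transcript_id")
    psio.write_blast6(data.hits, paths["hits"])
    psio.write_gene2term(data.term_map, paths["gene2term"])
    data.truth.events.to_csv(paths["truth_events"], sep="\t", index=False)
    data.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    data.truth.pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(data.config), fh, indent=2, default=list)
        fh.write("\n")
    return paths


# --- random gene models for enumeration stress tests ------------------------

def random_gene_models(
    rng: np.random.Generator, n_genes: int, chrom_pool: tuple[str, ...] = ("chr01A", "chr01B")
) -> list[GeneModel]:
    """Small random genes with rich alternative structure, both strands.

    Each gene has 2–5 transcripts derived from a base exon chain of 2–8
    exons by randomly skipping internal exons, retaining introns, and
    shifting donor/acceptor boundaries — the raw material for every event
    type the catalog enumerates.
    """
    genes = []
    for i in range(n_genes):
        gid = f"rg{i:05d}"
        chrom = chrom_pool[int(rng.integers(len(chrom_pool)))]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        base, pos = [], int(rng.integers(0, 1000))
        for _ in range(n_exons):
            length = int(rng.integers(60, 200))
            base.append([pos, pos + length])
            pos += length + int(rng.integers(80, 200))
        n_tx = int(rng.integers(2, 6))
        transcripts = []
        for t in range(n_tx):
            exons = [list(e) for e in base]
            # skip an internal exon
            if len(exons) >= 3 and rng.random() < 0.4:
                del exons[int(rng.integers(1, len(exons) - 1))]
            # retain an intron (merge neighbours)
            if len(exons) >= 2 and rng.random() < 0.3:
                j = int(rng.integers(0, len(exons) - 1))
                exons[j][1] = exons[j + 1][1]
                del exons[j + 1]
            # shift a donor (exon end) or acceptor (exon start)
            if len(exons) >= 2 and rng.random() < 0.5:
                j = int(rng.integers(0, len(exons) - 1))
                shift = int(rng.integers(10, 40))
                if rng.random() < 0.5:
                    exons[j][1] = min(exons[j][1] + shift, exons[j + 1][0] - 10)
                else:
                    exons[j + 1][0] = max(exons[j + 1][0] - shift, exons[j][1] + 10)
            transcripts.append(
                TranscriptModel(f"{gid}.t{t + 1}", gid, chrom, strand,
                                tuple(tuple(e) for e in exons))
            )
        genes.append(GeneModel(gid, chrom, strand, tuple(transcripts)))
    return genes
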