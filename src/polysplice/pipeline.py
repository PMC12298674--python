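"""End-to-end orchestration: filters → catalog → PSI → DSE → DE →
bias/transitions → integration, with a run manifest for reproducibility.

Contrast naming is ``TREATvsCTRL``; ΔPSI and log2FC are always
treatment-minus (or over) control.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_expression as de
from . import diff_splicing as ds
from . import event_catalog as ec
from . import integration_stats as ist
from . import io as psio
from . import psi_quant as pq
from . import subgenome_bias as sb
from .models import EventCatalog, ValidationError

log = logging.getLogger("polysplice")

DEFAULT_CONTRASTS = (("CG", "AG"), ("CG", "BG"), ("BG", "AG"))


@dataclass
class PipelineConfig:
    """Input paths, thresholds, contrasts and output directory."""

    gtf: str
    abundance: str
    gene_counts: str
    event_counts: str
    out_dir: str
    transcript_support: str | None = None
    hits: str | None = None
    gene2term: str | None = None
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    dpsi_min: float = 0.20
    alpha: float = 0.05
    lfc_min: float = 2.0
    q_cut: float = 0.05
    psi_low: float = 0.05
    psi_high: float = 0.95
    min_reads: int = 3
    min_identity: float = 90.0
    log2_cut: float = 1.0
    floor: float = 1.0
    fdr_cut: float = 0.05
    bin_size: int = 1_000_000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        out = {
            "gtf": self.gtf, "abundance": self.abundance,
            "gene_counts": self.gene_counts, "event_counts": self.event_counts,
        }
        for name in ("transcript_support", "hits", "gene2term"):
            if getattr(self, name):
                out[name] = getattr(self, name)
        return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage in dependency order; write report tables and a
    manifest under ``config.out_dir``.  Returns the in-memory tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, p in config.input_paths().items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} not found: {p}")

    results: dict[str, object] = {}
    thresholds = ds.DseThresholds(
        dpsi_min=config.dpsi_min, alpha=config.alpha,
        psi_low=config.psi_low, psi_high=config.psi_high,
    )

    # --- load -------------------------------------------------------------
    genes = psio.read_gtf(config.gtf)
    abundance = psio.read_matrix(config.abundance)
    gene_counts = psio.read_matrix(config.gene_counts)
    event_counts = psio.read_event_counts(config.event_counts)
    support = (
        psio.read_matrix(config.transcript_support)
        if config.transcript_support else None
    )
    log.info("loaded %d genes, %d transcripts", len(genes), len(abundance))

    # --- transcript support filter -----------------------------------------
    if support is not None:
        keep_tx = pq.filter_transcripts_by_support(support, min_reads=config.min_reads)
        filtered = []
        for g in genes:
            kept = tuple(t for t in g.transcripts if t.transcript_id in keep_tx)
            if kept:
                filtered.append(type(g)(g.gene_id, g.chrom, g.strand, kept))
        log.info("transcript filter: %d/%d genes retained", len(filtered), len(genes))
        genes = filtered

    # --- event catalog ------------------------------------------------------
    catalog = ec.enumerate_events(genes)
    keep_ev = pq.filter_events_by_support(event_counts, min_reads=config.min_reads)
    with_counts = set(event_counts["event_id"])
    retained = [
        ev for ev in catalog
        if ev.event_id not in with_counts or ev.event_id in keep_ev
    ]
    n_dropped = len(catalog) - len(retained)
    catalog = EventCatalog(retained)
    log.info("event catalog: %d events (%d dropped by support filter)", len(catalog), n_dropped)
    psio.write_catalog(catalog, out / "event_catalog.tsv")
    results["catalog"] = catalog

    # --- PSI ---------------------------------------------------------------
    cat_tx = set().union(
        *[ev.inclusion_transcripts | ev.exclusion_transcripts for ev in catalog]
    ) if len(catalog) else set()
    missing_tx = cat_tx - set(abundance.index)
    if missing_tx:
        raise ValidationError(f"abundance matrix missing transcripts {sorted(missing_tx)[:5]}")
    psi = pq.compute_psi(catalog, abundance)
    _write(psi, out / "psi.tsv")
    results["psi"] = psi

    corr = pq.psi_correlation(psi)
    _write(corr, out / "psi_correlation.tsv")
    results["psi_correlation"] = corr

    tally = pq.tally_active_events(psi)
    _write(tally, out / "active_event_tally.tsv", index=False)
    results["active_event_tally"] = tally

    mask = pq.active_event_mask(psi)
    freqs = ec.summarize_event_frequencies(catalog, mask)
    _write(freqs, out / "event_type_frequencies.tsv", index=False)
    results["event_type_frequencies"] = freqs

    per_gene = ec.events_per_gene_distribution(catalog, mask)
    _write(per_gene, out / "events_per_gene.tsv", index=False)
    results["events_per_gene"] = per_gene

    agg = ec.aggregate_events(catalog, mask, bin_size=config.bin_size)
    _write(agg["subgenome"], out / "events_by_subgenome.tsv", index=False)
    _write(agg["chromosome"], out / "events_by_chromosome.tsv", index=False)
    results["aggregation"] = agg

    ks_rows = []
    for trt, ctl in config.contrasts:
        try:
            d, p = pq.ks_compare_psi(psi, trt, ctl)
            ks_rows.append({"contrast": f"{trt}vs{ctl}", "D": d, "p": p})
        except ValidationError as exc:
            log.warning("KS %svs%s skipped: %s", trt, ctl, exc)
    results["ks"] = pd.DataFrame(ks_rows)
    _write(results["ks"], out / "psi_ks_tests.tsv", index=False)

    # --- differential splicing ----------------------------------------------
    dse_tables = []
    for contrast in config.contrasts:
        tbl = ds.test_differential_splicing(psi, event_counts, contrast, thresholds)
        dse_tables.append(tbl)
    dse = pd.concat(dse_tables, ignore_index=True) if dse_tables else pd.DataFrame()
    etype_of = pd.Series({ev.event_id: ev.etype for ev in catalog})
    if not dse.empty:
        dse.insert(1, "etype", etype_of.reindex(dse["event_id"]).to_numpy())
    _write(dse, out / "dse.tsv", index=False)
    results["dse"] = dse

    comp = ds.summarize_dse_composition(dse) if not dse.empty else pd.DataFrame()
    _write(comp, out / "dse_composition.tsv", index=False)
    results["dse_composition"] = comp

    if support is not None:
        tx_gene = pd.Series(
            {t.transcript_id: g.gene_id for g in genes for t in g.transcripts}
        )
        novel_rows = []
        baseline = config.contrasts[0][1] if config.contrasts else "AG"
        groups_present = set(pq.sample_groups(support.columns))
        for target in sorted(groups_present - {baseline}):
            hist = ds.count_novel_isoforms(
                support, tx_gene, baseline, target, min_reads=config.min_reads
            )
            hist.insert(0, "target", target)
            novel_rows.append(hist)
        novel = pd.concat(novel_rows, ignore_index=True) if novel_rows else pd.DataFrame()
        _write(novel, out / "novel_isoforms.tsv", index=False)
        results["novel_isoforms"] = novel

    # --- differential expression --------------------------------------------
    subgenome = pd.Series({g.gene_id: g.chrom[-1] for g in genes})
    deg_tables, chisq_rows = {}, []
    for contrast in config.contrasts:
        name = f"{contrast[0]}vs{contrast[1]}"
        degs = de.test_de(gene_counts, contrast, lfc_min=config.lfc_min, alpha=config.q_cut)
        deg_tables[name] = degs
        summary = de.deg_summary_by_subgenome(
            degs, subgenome.reindex(degs.index).dropna(), gene_counts
        )
        try:
            chi2, dof, p = sb.chisq_2x2(
                int(summary.loc[summary["subgenome"] == "A", "n_deg"].iloc[0]),
                int(summary.loc[summary["subgenome"] == "A", "n_expressed"].iloc[0]),
                int(summary.loc[summary["subgenome"] == "B", "n_deg"].iloc[0]),
                int(summary.loc[summary["subgenome"] == "B", "n_expressed"].iloc[0]),
            )
        except ValidationError:
            chi2, dof, p = np.nan, 1, np.nan
        chisq_rows.append(
            {"contrast": name, "chi2": chi2, "dof": dof, "p": p,
             **{f"{r.subgenome}_deg": r.n_deg for r in summary.itertuples()},
             **{f"{r.subgenome}_expressed": r.n_expressed for r in summary.itertuples()}}
        )
    deg_all = pd.concat(deg_tables.values())
    _write(deg_all, out / "deg.tsv")
    results["deg"] = deg_tables
    results["deg_subgenome_chisq"] = pd.DataFrame(chisq_rows)
    _write(results["deg_subgenome_chisq"], out / "deg_subgenome_chisq.tsv", index=False)

    # --- subgenome bias ------------------------------------------------------
    if config.hits:
        hits = psio.read_blast6(config.hits)
        pairs = sb.reciprocal_best_hits(hits, min_identity=config.min_identity)
        pd.DataFrame([vars(p) for p in pairs]).to_csv(
            out / "homoeolog_pairs.tsv", sep="\t", index=False
        )
        norm = gene_counts / de.size_factors(gene_counts)
        groups = pq.sample_groups(norm.columns)
        expr_means = pd.DataFrame({g: norm[cols].mean(axis=1) for g, cols in groups.items()})
        bias = sb.classify_bias(
            expr_means, pairs, log2_cut=config.log2_cut,
            floor=config.floor, pseudocount=1.0,
        )
        _write(bias, out / "bias_calls.tsv", index=False)
        results["bias_calls"] = bias

        trans_rows = []
        for trt, ctl in config.contrasts:
            name = f"{trt}vs{ctl}"
            degs = deg_tables[name]
            deg_genes = set(degs.index[degs["status"] != "ns"])
            subset = {
                p.pair_id for p in pairs
                if p.gene_a in deg_genes or p.gene_b in deg_genes
            }
            tt = sb.transition_table(bias, ctl, trt, subset=subset or None)
            tt.insert(0, "contrast", name)
            trans_rows.append(tt)
        transitions = pd.concat(trans_rows, ignore_index=True) if trans_rows else pd.DataFrame()
        _write(transitions, out / "bias_transitions.tsv", index=False)
        results["bias_transitions"] = transitions
        results["pairs"] = pairs

        # subgenome |log2FC| magnitude comparison per contrast
        mw_rows = []
        for name, degs in deg_tables.items():
            sig = degs[degs["status"] != "ns"]
            lab = subgenome.reindex(sig.index)
            a = sig["log2fc"].abs()[lab == "A"]
            b = sig["log2fc"].abs()[lab == "B"]
            if len(a) and len(b):
                u, p = sb.mann_whitney(a, b)
                mw_rows.append({"contrast": name, "U": u, "p": p,
                                "n_a": len(a), "n_b": len(b)})
        results["lfc_magnitude_mw"] = pd.DataFrame(mw_rows)
        _write(results["lfc_magnitude_mw"], out / "lfc_magnitude_mw.tsv", index=False)

    # --- integration ---------------------------------------------------------
    corr_rows = []
    for name, degs in deg_tables.items():
        block = dse[dse["contrast"] == name] if not dse.empty else pd.DataFrame()
        if block.empty:
            continue
        res = ist.correlate_dpsi_expression(block, degs, etype_of)
        for etype, r in res.items():
            corr_rows.append(
                {"contrast": name, "etype": etype, "r": r.r, "p": r.p,
                 "n": r.n, "ok": r.ok}
            )
    results["dpsi_expression_corr"] = pd.DataFrame(corr_rows)
    _write(results["dpsi_expression_corr"], out / "dpsi_expression_corr.tsv", index=False)

    named_sets: dict[str, set[str]] = {}
    for name, degs in list(deg_tables.items())[:2]:
        named_sets[f"DEG_{name}"] = set(degs.index[degs["status"] != "ns"])
        if not dse.empty:
            block = dse[(dse["contrast"] == name) & (dse["category"] != "ns")]
            named_sets[f"DAG_{name}"] = {
                e.split(";", 1)[0] for e in block["event_id"]
            }
    overlap = ist.overlap_sets(named_sets) if named_sets else pd.DataFrame()
    _write(overlap, out / "deg_dag_overlap.tsv", index=False)
    results["overlap"] = overlap

    if config.gene2term:
        term_map = psio.read_gene2term(config.gene2term)
        background = {g.gene_id for g in genes}
        enr_tables = []
        for name, degs in deg_tables.items():
            gene_list = set(degs.index[degs["status"] != "ns"]) & background
            if not gene_list:
                continue
            enr = ist.hypergeom_enrich(gene_list, background, term_map,
                                       fdr_cut=config.fdr_cut)
            enr.insert(0, "gene_set", f"DEG_{name}")
            enr_tables.append(enr)
        enrichment = pd.concat(enr_tables, ignore_index=True) if enr_tables else pd.DataFrame()
        _write(enrichment, out / "enrichment.tsv", index=False)
        results["enrichment"] = enrichment

    iso_rows = []
    groups = pq.sample_groups(abundance.columns)
    tx_gene = pd.Series({t.transcript_id: g.gene_id for g in genes for t in g.transcripts})
    for g, cols in groups.items():
        expressed = abundance[cols].gt(0).all(axis=1)
        iso_counts = tx_gene[expressed.reindex(tx_gene.index).fillna(False)].value_counts()
        res = ist.event_isoform_correlation(catalog, iso_counts, mask.get(g))
        iso_rows.append({"group": g, "r": res.r, "p": res.p, "n": res.n, "ok": res.ok})
    results["event_isoform_corr"] = pd.DataFrame(iso_rows)
    _write(results["event_isoform_corr"], out / "event_isoform_corr.tsv", index=False)

    # --- manifest -------------------------------------------------------------
    import polysplice

    manifest = {
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)}
                   for k, v in config.input_paths().items()},
        "thresholds": {
            k: getattr(config, k)
            for k in ("dpsi_min", "alpha", "lfc_min", "q_cut", "psi_low", "psi_high",
                      "min_reads", "min_identity", "log2_cut", "floor", "fdr_cut")
        },
        "contrasts": [list(c) for c in config.contrasts],
        "seed": config.seed,
        "versions": {"polysplice": polysplice.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "counts": {
            "events": len(catalog),
            "events_dropped_by_support": n_dropped,
            "genes": len(genes),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
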