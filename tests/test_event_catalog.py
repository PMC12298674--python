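"""Event enumeration: minimal constructions, a brute-force pairwise oracle,
and the strand/monotonicity invariants."""
import numpy as np
import pytest

from polysplice.event_catalog import (
    aggregate_events,
    enumerate_events,
    events_per_gene_distribution,
    summarize_event_frequencies,
)
from polysplice.models import (
    EventCatalog,
    GeneModel,
    TranscriptModel,
    ValidationError,
    format_event_id,
)
from polysplice.synthetic_data import random_gene_models


def make_gene(gene_id, exon_chains, strand="+", chrom="chr01A"):
    txs = tuple(
        TranscriptModel(f"{gene_id}.t{i + 1}", gene_id, chrom, strand, tuple(chain))
        for i, chain in enumerate(exon_chains)
    )
    return GeneModel(gene_id, chrom, strand, txs)


# --- brute-force oracle: tests every transcript pair against the textual
# definitions, independently of the production index-based implementation.

def _overlap(a, b):
    return a[0] < b[1] and b[0] < a[1]


def brute_force_events(gene):
    """(gene, type, anchor) triples by naive pairwise definition checking."""
    triples = set()
    for t1 in gene.transcripts:
        for t2 in gene.transcripts:
            if t1 is t2:
                continue
            ex1, ex2 = t1.exons, t2.exons
            introns2 = set(t2.introns)
            # exon skipping: internal exon of t1, direct flank junction in t2
            for i in range(1, len(ex1) - 1):
                c1e, (a_s, a_e), c2s = ex1[i - 1][1], ex1[i], ex1[i + 1][0]
                if (c1e, c2s) in introns2:
                    triples.add((gene.gene_id, "ES", (c1e, a_s, a_e, c2s)))
            # intron retention: t2 holds a single exon spanning t1's two
            # flanking exons exactly
            for i in range(len(ex1) - 1):
                (a, c1e), (c2s, b) = ex1[i], ex1[i + 1]
                if (a, b) in set(ex2):
                    triples.add((gene.gene_id, "IR", (a, c1e, c2s, b)))
            # alternative donor/acceptor: introns sharing one boundary with
            # overlapping exons on the differing side
            for i in range(len(ex1) - 1):
                i1 = (ex1[i][1], ex1[i + 1][0])
                for k in range(len(ex2) - 1):
                    i2 = (ex2[k][1], ex2[k + 1][0])
                    if i1 == i2:
                        continue
                    first, second = sorted((i1, i2))
                    if i1[1] == i2[1] and _overlap(ex1[i], ex2[k]):
                        etype = "A5" if gene.strand == "+" else "A3"
                        triples.add((gene.gene_id, etype, (*first, *second)))
                    if i1[0] == i2[0] and _overlap(ex1[i + 1], ex2[k + 1]):
                        etype = "A3" if gene.strand == "+" else "A5"
                        triples.add((gene.gene_id, etype, (*first, *second)))
    return triples


def catalog_triples(catalog):
    return {(ev.gene_id, ev.etype, ev.anchor) for ev in catalog}


def test_minimal_exon_skipping():
    gene = make_gene("g1", [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]])
    cat = enumerate_events([gene])
    assert len(cat) == 1
    ev = cat.events[0]
    assert ev.etype == "ES"
    assert ev.anchor == (100, 200, 300, 400)
    assert ev.inclusion_transcripts == {"g1.t1"}
    assert ev.exclusion_transcripts == {"g1.t2"}
    assert ev.event_id == format_event_id("g1", "ES", "chr01A", (100, 200, 300, 400), "+")


def test_minimal_intron_retention():
    gene = make_gene("g1", [[(0, 100), (200, 300)], [(0, 300)]])
    cat = enumerate_events([gene])
    assert len(cat) == 1
    ev = cat.events[0]
    assert ev.etype == "IR"
    assert ev.anchor == (0, 100, 200, 300)
    # the retaining form is the inclusion form
    assert ev.inclusion_transcripts == {"g1.t2"}
    assert ev.exclusion_transcripts == {"g1.t1"}


@pytest.mark.parametrize(
    "strand,expected",
    [("+", "A5"), ("-", "A3")],
)
def test_alternative_donor_shared_intron_end(strand, expected):
    # introns (100,200) and (150,200) share their end; donor side differs
    gene = make_gene(
        "g1", [[(0, 150), (200, 300)], [(0, 100), (200, 300)]], strand=strand
    )
    cat = enumerate_events([gene])
    assert len(cat) == 1
    ev = cat.events[0]
    assert ev.etype == expected
    # inclusion is the shorter intron (more exon retained)
    assert ev.inclusion_transcripts == {"g1.t1"}
    assert ev.exclusion_transcripts == {"g1.t2"}


@pytest.mark.parametrize("strand,expected", [("+", "A3"), ("-", "A5")])
def test_alternative_acceptor_shared_intron_start(strand, expected):
    gene = make_gene(
        "g1", [[(0, 100), (150, 300)], [(0, 100), (200, 300)]], strand=strand
    )
    cat = enumerate_events([gene])
    assert len(cat) == 1
    assert cat.events[0].etype == expected
    assert cat.events[0].inclusion_transcripts == {"g1.t1"}


def test_skipping_does_not_masquerade_as_alt_site():
    """The ES configuration shares intron boundaries between the skip and
    flank junctions, but the non-adjacent exons do not overlap, so no
    A5/A3 should be emitted alongside the ES call."""
    gene = make_gene("g1", [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]])
    cat = enumerate_events([gene])
    assert [ev.etype for ev in cat] == ["ES"]


def test_overlapping_exons_rejected():
    with pytest.raises(ValidationError, match="t1"):
        TranscriptModel("t1", "g1", "chr01A", "+", ((0, 100), (50, 200)))


def test_identical_transcripts_collapse():
    gene = make_gene(
        "g1",
        [[(0, 100), (200, 300)], [(0, 100), (200, 300)], [(0, 300)]],
    )
    cat = enumerate_events([gene])
    assert len(cat) == 1
    assert cat.events[0].exclusion_transcripts == {"g1.t1", "g1.t2"}


def test_oracle_equivalence_on_random_genes():
    """Index-based enumeration equals the brute-force pairwise oracle."""
    rng = np.random.default_rng(42)
    genes = random_gene_models(rng, 300)
    cat = enumerate_events(genes)
    expected = set().union(*(brute_force_events(g) for g in genes))
    assert catalog_triples(cat) == expected


def _reflect_genes(genes, C, flip_strand):
    out = []
    for gene in genes:
        strand = gene.strand
        if flip_strand:
            strand = "-" if strand == "+" else "+"
        txs = tuple(
            TranscriptModel(
                t.transcript_id, t.gene_id, t.chrom, strand,
                tuple(sorted((C - e, C - s) for s, e in t.exons)),
            )
            for t in gene.transcripts
        )
        out.append(GeneModel(gene.gene_id, gene.chrom, strand, txs))
    return out


def _map_triples(triples, C, swap):
    mapped = set()
    for gid, etype, anchor in triples:
        if etype == "IR":
            mapped.add((gid, "IR", tuple(sorted(C - x for x in anchor))))
        else:
            pairs = sorted(
                [(C - anchor[1], C - anchor[0]), (C - anchor[3], C - anchor[2])]
            )
            mapped.add((gid, swap[etype], (*pairs[0], *pairs[1])))
    return mapped


def test_mirror_swaps_alternative_donor_and_acceptor():
    """Mirroring coordinates on the same strand exchanges donor-side and
    acceptor-side choice, so A5 events map 1:1 onto A3 events (IR/ES
    anchors just reflect)."""
    rng = np.random.default_rng(7)
    genes = random_gene_models(rng, 120)
    C = 1_000_000
    fwd = catalog_triples(enumerate_events(genes))
    rev = catalog_triples(enumerate_events(_reflect_genes(genes, C, flip_strand=False)))
    swap = {"A5": "A3", "A3": "A5", "ES": "ES"}
    assert _map_triples(fwd, C, swap) == rev


def test_mirror_with_strand_flip_is_identity():
    """Mirroring coordinates and flipping strand yields the same gene read
    in the same transcriptional direction: event types are preserved."""
    rng = np.random.default_rng(8)
    genes = random_gene_models(rng, 120)
    C = 1_000_000
    fwd = catalog_triples(enumerate_events(genes))
    rev = catalog_triples(enumerate_events(_reflect_genes(genes, C, flip_strand=True)))
    same = {"A5": "A5", "A3": "A3", "ES": "ES"}
    assert _map_triples(fwd, C, same) == rev


def test_monotonicity_adding_transcript_never_removes_events():
    rng = np.random.default_rng(13)
    genes = random_gene_models(rng, 60)
    for gene in genes[:30]:
        before = catalog_triples(enumerate_events([gene]))
        extra = TranscriptModel(
            f"{gene.gene_id}.extra", gene.gene_id, gene.chrom, gene.strand,
            gene.transcripts[0].exons[:1],
        )
        grown = GeneModel(gene.gene_id, gene.chrom, gene.strand,
                          gene.transcripts + (extra,))
        after = catalog_triples(enumerate_events([grown]))
        assert before <= after


# --- summaries --------------------------------------------------------------

def _four_type_catalog():
    genes = [
        make_gene("g_es", [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]]),
        make_gene("g_ir", [[(0, 100), (200, 300)], [(0, 300)]]),
        make_gene("g_a5", [[(0, 150), (200, 300)], [(0, 100), (200, 300)]]),
        make_gene("g_a3", [[(0, 100), (150, 300)], [(0, 100), (200, 300)]]),
    ]
    return enumerate_events(genes)


def test_event_frequencies_one_per_type():
    cat = _four_type_catalog()
    tbl = summarize_event_frequencies(cat)
    assert tbl["pct"].tolist() == [25.0] * 4
    assert tbl["pct"].sum() == pytest.approx(100.0, abs=1e-9)


def test_event_frequencies_empty_group_flagged():
    cat = _four_type_catalog()
    tbl = summarize_event_frequencies(cat, {"empty": []})
    assert (tbl["count"] == 0).all()
    assert tbl["pct"].isna().all()


def test_event_frequencies_planted_composition():
    chains_by_type = {
        "IR": [[(0, 100), (200, 300)], [(0, 300)]],
        "A3": [[(0, 100), (150, 300)], [(0, 100), (200, 300)]],
        "A5": [[(0, 150), (200, 300)], [(0, 100), (200, 300)]],
        "ES": [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]],
    }
    genes = []
    for etype, n in [("IR", 40), ("A3", 30), ("A5", 20), ("ES", 10)]:
        for i in range(n):
            genes.append(make_gene(f"g{etype}{i}", chains_by_type[etype]))
    tbl = summarize_event_frequencies(enumerate_events(genes)).set_index("etype")
    assert tbl.loc["IR", "pct"] == pytest.approx(40.0)
    assert tbl.loc["A3", "pct"] == pytest.approx(30.0)
    assert tbl.loc["A5", "pct"] == pytest.approx(20.0)
    assert tbl.loc["ES", "pct"] == pytest.approx(10.0)


def test_events_per_gene_bins():
    # seven A3 events in one gene: a cascade of acceptor choices
    chains = [[(0, 100), (150 + 10 * k, 400)] for k in range(8)]
    gene = make_gene("g1", chains)
    cat = enumerate_events([gene])
    a3 = [ev for ev in cat if ev.etype == "A3"]
    assert len(a3) >= 7
    tbl = events_per_gene_distribution(cat)
    over5 = tbl[(tbl["etype"] == "A3") & (tbl["bin"] == ">5")]["n_genes"].iloc[0]
    assert over5 == 1
    allover = tbl[(tbl["etype"] == "all") & (tbl["bin"] == ">5")]["n_genes"].iloc[0]
    assert allover == 1


def test_events_per_gene_matches_recount_oracle(default_catalog):
    tbl = events_per_gene_distribution(default_catalog)
    per_gene = {}
    for ev in default_catalog:
        per_gene[ev.gene_id] = per_gene.get(ev.gene_id, 0) + 1
    overall = tbl[tbl["etype"] == "all"].set_index("bin")["n_genes"]
    for b in ("1", "2", "3", "4", "5"):
        assert overall[b] == sum(1 for n in per_gene.values() if n == int(b))
    assert overall[">5"] == sum(1 for n in per_gene.values() if n > 5)
    assert overall.sum() == len(per_gene)


def test_aggregate_events_subgenome_totals():
    genes = [
        make_gene("a1", [[(0, 100), (200, 300)], [(0, 300)]], chrom="chr01A"),
        make_gene("a2", [[(0, 100), (200, 300)], [(0, 300)]], chrom="chr01A"),
        make_gene("a3", [[(0, 100), (200, 300)], [(0, 300)]], chrom="chr01A"),
        make_gene("b1", [[(0, 100), (200, 300)], [(0, 300)]], chrom="chr01B"),
        make_gene("b2", [[(0, 100), (200, 300)], [(0, 300)]], chrom="chr01B"),
    ]
    agg = aggregate_events(enumerate_events(genes))
    sub = agg["subgenome"].groupby("subgenome")["count"].sum()
    assert sub["A"] == 3 and sub["B"] == 2
    # one huge bin holds everything
    assert agg["bins"]["count"].sum() == agg["chromosome"]["count"].sum() == 5


def test_aggregate_events_bin_recount(default_catalog):
    agg = aggregate_events(default_catalog, bin_size=50_000)
    per_chrom_from_bins = agg["bins"].groupby("chrom")["count"].sum()
    per_chrom = agg["chromosome"].groupby("chrom")["count"].sum()
    assert per_chrom_from_bins.sort_index().equals(per_chrom.sort_index())
    sub_total = agg["subgenome"]["count"].sum()
    assert sub_total == len(default_catalog)


def test_aggregate_events_requires_subgenome_suffix():
    gene = make_gene("g1", [[(0, 100), (200, 300)], [(0, 300)]], chrom="chr1")
    with pytest.raises(ValidationError, match="suffix"):
        aggregate_events(enumerate_events([gene]))
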