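"""PSI computation, support filters, tallies, correlation and KS checks."""
import numpy as np
import pandas as pd
import pytest

from polysplice.models import ValidationError
from polysplice.psi_quant import (
    compute_psi,
    filter_events_by_support,
    filter_transcripts_by_support,
    ks_compare_psi,
    psi_correlation,
    psi_from_counts,
    tally_active_events,
)
from test_event_catalog import make_gene
from polysplice.event_catalog import enumerate_events

SAMPLES = [f"{g}_rep{i}" for g in ("AG", "BG", "CG") for i in (1, 2, 3)]


def support_frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=SAMPLES)


class TestTranscriptFilter:
    def test_boundary_retained_when_one_group_fully_supported(self):
        df = support_frame({"t1": [3, 3, 3, 0, 0, 0, 0, 0, 0]})
        assert filter_transcripts_by_support(df) == {"t1"}

    def test_below_threshold_everywhere_removed(self):
        df = support_frame({"t1": [2] * 9})
        assert filter_transcripts_by_support(df) == set()

    def test_all_groups_mode_is_stricter(self):
        df = support_frame({"t1": [3, 3, 3, 0, 0, 0, 0, 0, 0], "t2": [4] * 9})
        assert filter_transcripts_by_support(df, require_all_groups=True) == {"t2"}

    def test_matches_direct_rule_reevaluation(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.integers(0, 6, size=(200, 9)),
            index=[f"t{i}" for i in range(200)], columns=SAMPLES,
        )
        got = filter_transcripts_by_support(df)
        expected = set()
        for t in df.index:
            for g in ("AG", "BG", "CG"):
                if all(df.at[t, f"{g}_rep{i}"] >= 3 for i in (1, 2, 3)):
                    expected.add(t)
                    break
        assert got == expected

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            rng.integers(0, 6, size=(50, 9)),
            index=[f"t{i}" for i in range(50)], columns=SAMPLES,
        )
        once = filter_transcripts_by_support(df)
        twice = filter_transcripts_by_support(df.loc[sorted(once)])
        assert twice == once


class TestEventFilter:
    @staticmethod
    def long_counts(totals: dict) -> pd.DataFrame:
        rows = []
        for eid, per_sample in totals.items():
            for s, tot in zip(SAMPLES, per_sample):
                rows.append(
                    {"event_id": eid, "sample": s,
                     "inclusion_reads": tot // 2, "exclusion_reads": tot - tot // 2}
                )
        return pd.DataFrame(rows)

    def test_discarded_when_one_group_all_low(self):
        counts = self.long_counts({"e1": [10, 10, 10, 10, 10, 10, 2, 3, 1]})
        assert filter_events_by_support(counts) == set()

    def test_retained_at_boundary_four_reads(self):
        counts = self.long_counts({"e1": [4] * 9})
        assert filter_events_by_support(counts) == {"e1"}

    def test_matches_direct_rule_reevaluation(self):
        rng = np.random.default_rng(9)
        totals = {f"e{i}": list(rng.integers(0, 8, size=9)) for i in range(150)}
        got = filter_events_by_support(self.long_counts(totals))
        expected = set()
        for eid, per_sample in totals.items():
            discard = False
            for gi, g in enumerate(("AG", "BG", "CG")):
                if all(t <= 3 for t in per_sample[3 * gi: 3 * gi + 3]):
                    discard = True
            if not discard:
                expected.add(eid)
        assert got == expected


@pytest.fixture()
def es_catalog():
    gene = make_gene("g1", [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]])
    return enumerate_events([gene])


def abundance_frame(inc, exc):
    return pd.DataFrame(
        {s: [inc, exc] for s in SAMPLES}, index=["g1.t1", "g1.t2"], dtype=float
    )


class TestComputePsi:
    def test_equal_abundance_gives_half(self, es_catalog):
        psi = compute_psi(es_catalog, abundance_frame(5.0, 5.0))
        assert (psi == 0.5).all().all()

    def test_zero_exclusion_gives_one(self, es_catalog):
        psi = compute_psi(es_catalog, abundance_frame(8.0, 0.0))
        assert (psi == 1.0).all().all()

    def test_multi_transcript_sums(self):
        # two inclusion isoforms at 2.5 each against one exclusion at 5.0
        g = make_gene(
            "g1",
            [
                [(0, 100), (200, 300), (400, 500)],
                [(0, 100), (200, 300), (400, 520)],
                [(0, 100), (400, 500)],
            ],
        )
        cat = enumerate_events([g])
        ab = pd.DataFrame(
            {s: [2.5, 2.5, 5.0] for s in SAMPLES},
            index=["g1.t1", "g1.t2", "g1.t3"],
        )
        psi = compute_psi(cat, ab)
        es_row = psi.loc[[e.event_id for e in cat if e.etype == "ES"][0]]
        assert es_row.tolist() == [0.5] * 9

    def test_zero_total_is_missing(self, es_catalog):
        psi = compute_psi(es_catalog, abundance_frame(0.0, 0.0))
        assert psi.isna().all().all()

    def test_unknown_transcript_rejected(self, es_catalog):
        ab = pd.DataFrame({s: [1.0] for s in SAMPLES}, index=["g1.t1"])
        with pytest.raises(ValidationError, match="unknown"):
            compute_psi(es_catalog, ab)

    def test_complementarity_under_form_swap(self, default_sim, default_catalog):
        from polysplice.models import EventCatalog, SpliceEvent

        swapped = EventCatalog(
            [
                SpliceEvent(
                    ev.event_id, ev.gene_id, ev.etype, ev.chrom, ev.strand, ev.anchor,
                    inclusion_transcripts=ev.exclusion_transcripts,
                    exclusion_transcripts=ev.inclusion_transcripts,
                )
                for ev in default_catalog
            ]
        )
        psi = compute_psi(default_catalog, default_sim.abundance)
        psi_swapped = compute_psi(swapped, default_sim.abundance)
        diff = (psi + psi_swapped - 1.0).abs()
        assert diff.max().max() < 1e-12

    def test_scale_invariance(self, default_sim, default_catalog):
        psi = compute_psi(default_catalog, default_sim.abundance)
        psi_scaled = compute_psi(default_catalog, default_sim.abundance * 37.5)
        pd.testing.assert_frame_equal(psi, psi_scaled)


class TestTally:
    def test_all_extreme_counts_zero(self, es_catalog):
        psi = compute_psi(es_catalog, abundance_frame(8.0, 0.0))
        tally = tally_active_events(psi)
        assert (tally["n_active"] == 0).all()

    def test_single_intermediate_sample(self, es_catalog):
        ab = abundance_frame(8.0, 0.0)
        ab.loc["g1.t2", "AG_rep1"] = 8.0
        tally = tally_active_events(compute_psi(es_catalog, ab)).set_index("sample")
        assert tally.loc["AG_rep1", "n_active"] == 1
        assert tally.loc["AG_rep2", "n_active"] == 0

    def test_recount_oracle(self, default_psi):
        tally = tally_active_events(default_psi)
        per_sample = tally[tally["sample"] != "group_mean"].set_index("sample")
        for s in default_psi.columns:
            expected = int(((default_psi[s] > 0) & (default_psi[s] < 1)).sum())
            assert per_sample.loc[s, "n_active"] == expected


class TestCorrelation:
    def test_duplicate_column_r_one(self):
        rng = np.random.default_rng(1)
        psi = pd.DataFrame(
            {"AG_rep1": rng.uniform(size=50)}, index=[f"e{i}" for i in range(50)]
        )
        psi["AG_rep2"] = psi["AG_rep1"]
        corr = psi_correlation(psi)
        assert corr.loc["AG_rep1", "AG_rep2"] == pytest.approx(1.0)

    def test_complement_column_r_minus_one(self):
        rng = np.random.default_rng(2)
        psi = pd.DataFrame({"AG_rep1": rng.uniform(size=50)})
        psi["BG_rep1"] = 1.0 - psi["AG_rep1"]
        corr = psi_correlation(psi)
        assert corr.loc["AG_rep1", "BG_rep1"] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(3)
        psi = pd.DataFrame(
            rng.uniform(size=(100, 6)),
            columns=[f"{g}_rep{i}" for g in ("AG", "BG") for i in (1, 2, 3)],
        )
        corr = psi_correlation(psi)
        x, y = psi["AG_rep1"], psi["BG_rep3"]
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert corr.loc["AG_rep1", "BG_rep3"] == pytest.approx(r, rel=1e-12)

    def test_insufficient_pairs_flagged_missing(self):
        psi = pd.DataFrame(
            {"AG_rep1": [0.1, np.nan, np.nan, 0.4], "BG_rep1": [np.nan, 0.2, 0.3, 0.5]}
        )
        corr = psi_correlation(psi)
        assert np.isnan(corr.loc["AG_rep1", "BG_rep1"])


class TestKs:
    @staticmethod
    def psi_two_groups(x, y):
        return pd.DataFrame(
            {"AG_rep1": x, "AG_rep2": x, "CG_rep1": y, "CG_rep2": y}
        )

    def test_identical_distributions_d_zero(self):
        v = np.linspace(0.05, 0.95, 20)
        d, p = ks_compare_psi(self.psi_two_groups(v, v), "CG", "AG")
        assert d == 0.0

    def test_fully_separated_d_one(self):
        x = np.linspace(0.01, 0.2, 15)
        y = np.linspace(0.8, 0.99, 15)
        d, _ = ks_compare_psi(self.psi_two_groups(x, y), "CG", "AG")
        assert d == 1.0

    def test_matches_ecdf_max_gap(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=40)
        y = rng.beta(2, 1, size=40)
        d, _ = ks_compare_psi(self.psi_two_groups(x, y), "CG", "AG")
        grid = np.concatenate([x, y])
        expected = max(abs((x <= g).mean() - (y <= g).mean()) for g in grid)
        assert d == pytest.approx(expected, rel=1e-12)

    def test_insufficient_data_rejected(self):
        v = np.linspace(0.1, 0.9, 5)
        with pytest.raises(ValidationError, match=">= 10"):
            ks_compare_psi(self.psi_two_groups(v, v), "CG", "AG")


def test_count_based_psi_matches_abundance_psi(default_sim, default_catalog, default_psi):
    """The generator splits abundance by realized event PSI, so the two
    quantification routes must agree on planted events."""
    count_psi = psi_from_counts(default_sim.event_counts)
    shared = count_psi.index.intersection(default_psi.index)
    assert len(shared) == len(default_sim.truth.events)
    diff = (count_psi.loc[shared] - default_psi.loc[shared][count_psi.columns]).abs()
    assert diff.max().max() < 1e-9
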