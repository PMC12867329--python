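import numpy as np
import pandas as pd
import pytest

from _oracles import (
    oracle_composition,
    oracle_coverage,
    oracle_neighbourhood,
    oracle_signal_mean,
)
from conftest import make_segmentation, random_genes, random_segmentation

from chromstates import states as sm
from chromstates.core import EmissionMatrix, GeneModel, GeneModelSet, GenomicInterval


class TestGenomeCoverage:
    def test_formula(self):
        seg = make_segmentation(
            [("c", 0, 2000, "A"), ("c", 2000, 10000, "B")], {"c": 10000}
        )
        cov = sm.genome_coverage(seg)
        assert cov["A"] == pytest.approx(20.0)

    def test_single_state_is_100(self):
        seg = make_segmentation([("c", 0, 5000, "A")], {"c": 5000})
        assert sm.genome_coverage(seg)["A"] == pytest.approx(100.0)

    def test_matches_perbp_oracle(self, rng):
        seg = random_segmentation(rng, {"c1": 20_000, "c2": 8_200}, gap_prob=0.2)
        pd.testing.assert_series_equal(
            sm.genome_coverage(seg), oracle_coverage(seg),
            check_names=False,
        )

    def test_sums_to_100(self, rng):
        seg = random_segmentation(rng, {"c1": 30_000}, n_states=5, gap_prob=0.1)
        assert sm.genome_coverage(seg).sum() == pytest.approx(100.0, abs=1e-9)


class TestFeatureComposition:
    def test_state_inside_gene(self):
        seg = make_segmentation(
            [("c", 0, 400, "A"), ("c", 400, 2000, "B")], {"c": 2000}
        )
        genes = GeneModelSet(
            [GeneModel("g1", GenomicInterval("c", 0, 600, "+"))]
        )
        comp = sm.feature_composition(seg, genes)
        assert comp.loc["A", "protein_coding"] == pytest.approx(1.0)
        assert comp.loc["B", "intergenic"] == pytest.approx(1400 / 1600)

    def test_matches_perbp_oracle(self, rng):
        seg = random_segmentation(rng, {"c1": 10_000, "c2": 6_000}, gap_prob=0.1)
        genes = random_genes(rng, seg.chrom_sizes, n=8)
        got = sm.feature_composition(seg, genes)
        want = oracle_composition(seg, genes)
        pd.testing.assert_frame_equal(got, want)

    def test_rows_sum_to_one(self, rng):
        seg = random_segmentation(rng, {"c1": 12_000})
        genes = random_genes(rng, seg.chrom_sizes, n=5)
        sums = sm.feature_composition(seg, genes).sum(axis=1).dropna()
        assert np.allclose(sums, 1.0)


def _anchor(chrom, pos, strand="+"):
    return (chrom, pos, strand)


class TestNeighbourhoodEnrichment:
    def test_uniform_genome_is_flat_one(self):
        seg = make_segmentation([("c", 0, 10_000, "A")], {"c": 10_000})
        nb = sm.neighbourhood_enrichment(seg, [_anchor("c", 5000)], L=3)
        assert np.allclose(nb.enrichment.loc["A"], 1.0)

    def test_forced_ratio_at_plus_one(self):
        # E1 occupies exactly the bin downstream of the anchor; genome
        # fraction of E1 is 1/10 so enrichment at +1 must be 10
        spec = [("c", 0, 1200, "B"), ("c", 1200, 1400, "E1"),
                ("c", 1400, 2000, "B")]
        seg = make_segmentation(spec, {"c": 2000})
        nb = sm.neighbourhood_enrichment(seg, [_anchor("c", 1000)], L=2)
        assert nb.enrichment.loc["E1", 1] == pytest.approx(10.0)
        assert nb.enrichment.loc["E1", 0] == 0.0

    def test_matches_anchor_walk_oracle(self, rng):
        seg = random_segmentation(rng, {"c1": 20_000, "c2": 10_000},
                                  n_states=4, gap_prob=0.15)
        anchors = [
            (c, int(rng.integers(seg.chrom_sizes[c])),
             "+" if rng.random() < 0.5 else "-")
            for c in ["c1", "c2"] for _ in range(15)
        ]
        got = sm.neighbourhood_enrichment(seg, anchors, L=5).enrichment
        want = oracle_neighbourhood(seg, anchors, L=5)
        pd.testing.assert_frame_equal(got, want)

    def test_invariant_to_anchor_order_and_chrom_rename(self, rng):
        seg = random_segmentation(rng, {"c1": 10_000})
        anchors = [("c1", int(rng.integers(10_000)), s)
                   for s in "++--" for _ in range(5)]
        a = sm.neighbourhood_enrichment(seg, anchors, L=4).enrichment
        b = sm.neighbourhood_enrichment(seg, anchors[::-1], L=4).enrichment
        pd.testing.assert_frame_equal(a, b)
        renamed = make_segmentation(
            [("X" + iv.chrom, iv.start, iv.end, lab)
             for iv, lab in seg.intervals()],
            {"Xc1": 10_000}, states=seg.states,
        )
        c = sm.neighbourhood_enrichment(
            renamed, [("X" + ch, p, s) for ch, p, s in anchors], L=4
        ).enrichment
        pd.testing.assert_frame_equal(a, c)

    def test_total_probability_law(self, rng):
        """sum_s fraction(s) * enrichment(s, k) == 1 at complete offsets."""
        seg = random_segmentation(rng, {"c1": 20_000}, n_states=5)
        anchors = [("c1", int(rng.integers(2000, 18_000)), "+")
                   for _ in range(30)]
        nb = sm.neighbourhood_enrichment(seg, anchors, L=5)
        total = nb.enrichment.mul(nb.genome_fraction, axis=0).sum(axis=0)
        assert np.allclose(total, 1.0)

    def test_zero_fraction_state_reported_missing(self):
        seg = make_segmentation([("c", 0, 2000, "A")], {"c": 2000},
                                states=["A", "ghost"])
        nb = sm.neighbourhood_enrichment(seg, [_anchor("c", 1000)], L=1)
        assert nb.enrichment.loc["ghost"].isna().all()


class TestDomainsAndNomenclature:
    @staticmethod
    def _emissions(rows):
        return EmissionMatrix(p=pd.DataFrame(rows).T)

    def test_rule_cascade(self):
        em = self._emissions({
            "h": {"H3K9me2": 0.9, "H3K27me3": 0.0, "H3K36me3": 0.1},
            "i": {"H3K9me2": 0.05, "H3K27me3": 0.1, "H3K36me3": 0.15},
            "f": {"H3K9me2": 0.0, "H3K27me3": 0.8, "H3K36me3": 0.1},
            "e": {"H3K9me2": 0.0, "H3K27me3": 0.1, "H3K36me3": 0.9},
        })
        comp = pd.DataFrame(
            {"TE": [0.8, 0.0, 0.0, 0.0]}, index=["h", "i", "f", "e"]
        )
        dom = sm.classify_domains(em, comp)
        assert dom.domains.to_dict() == {"h": "H", "i": "I", "f": "F", "e": "E"}

    def test_heterochromatin_needs_te_overlap(self):
        em = self._emissions({"x": {"H3K9me2": 0.9, "H3K27me3": 0.0}})
        comp = pd.DataFrame({"TE": [0.0]}, index=["x"])
        assert sm.classify_domains(em, comp).domains["x"] == "E"

    def test_missing_rule_marks_error(self):
        em = self._emissions({"x": {"H3K4me3": 0.9}})
        with pytest.raises(ValueError, match="rule marks"):
            sm.classify_domains(em, pd.DataFrame({"TE": [0.0]}, index=["x"]))

    def test_planted_palette_fully_recovered(self, small_study):
        comp = sm.feature_composition(small_study.segmentation,
                                      small_study.genes)
        dom = sm.classify_domains(small_study.emissions, comp)
        planted = small_study.truth.state_table["domain"]
        assert dom.domains.to_dict() == planted.to_dict()

    def test_numbering_by_tss_argmax(self):
        enr = pd.DataFrame(
            [[0.1, 0.2, 5.0, 0.1], [0.1, 0.2, 0.1, 5.0]],
            index=["late", "later"], columns=[-1, 0, 1, 4],
        )
        # 'later' peaks at +4, 'late' at +1 -> E1 = late, E2 = later
        nb = sm.NeighbourhoodMatrix(enrichment=enr, anchor_kind="TSS", L=4)
        seg = make_segmentation(
            [("c", 0, 1000, "late"), ("c", 1000, 2000, "later")], {"c": 2000}
        )
        table = pd.DataFrame(
            {"domain": ["E", "E"], "rule": ["", ""], "name": ["late", "later"]},
            index=["late", "later"],
        )
        named = sm.assign_nomenclature(sm.DomainAssignment(table), nb, seg)
        assert named.names.to_dict() == {"late": "E1", "later": "E2"}

    def test_h_numbering_by_centromere_distance(self):
        seg = make_segmentation(
            [("c", 0, 1000, "far"), ("c", 1000, 2000, "near"),
             ("c", 2000, 4000, "e")],
            {"c": 4000},
        )
        enr = pd.DataFrame(
            [[1.0], [1.0], [1.0]], index=["far", "near", "e"], columns=[0]
        )
        nb = sm.NeighbourhoodMatrix(enrichment=enr, anchor_kind="TSS", L=0)
        table = pd.DataFrame(
            {"domain": ["H", "H", "E"], "rule": "", "name": ""},
            index=["far", "near", "e"],
        )
        named = sm.assign_nomenclature(
            sm.DomainAssignment(table), nb, seg, centromeres={"c": 1600}
        )
        assert named.names["near"] == "H1"
        assert named.names["far"] == "H2"

    def test_planted_order_recovered(self, small_study):
        seg = small_study.segmentation
        pc = small_study.genes.subset("protein_coding")
        comp = sm.feature_composition(seg, small_study.genes)
        nb = sm.neighbourhood_enrichment(seg, pc, L=10)
        dom = sm.classify_domains(small_study.emissions, comp)
        named = sm.assign_nomenclature(dom, nb, seg)
        # the palette is already named in planted order (E1 at +1, etc.)
        for state in ["E1", "E2", "E3", "I1", "F1"]:
            assert named.names[state] == state


class TestChromosomalDistribution:
    def test_confined_state_single_window(self):
        seg = make_segmentation(
            [("c", 0, 40_000, "A"), ("c", 40_000, 100_000, "B")],
            {"c": 100_000},
        )
        dist = sm.chromosomal_distribution(seg, ["A"], binwidth=50_000)
        counts = dist.set_index("window_start")["count"]
        assert counts[0] == 200 and counts[50_000] == 0

    def test_empty_subset_zero(self):
        seg = make_segmentation([("c", 0, 10_000, "A")], {"c": 10_000})
        dist = sm.chromosomal_distribution(seg, [], binwidth=5000)
        assert dist.empty

    def test_matches_direct_tally(self, rng):
        seg = random_segmentation(rng, {"c1": 30_000}, n_states=3)
        dist = sm.chromosomal_distribution(seg, binwidth=7_000)
        codes = seg.bin_codes("c1")
        for row in dist.itertuples(index=False):
            w0 = row.window_start // seg.bin_size
            w1 = min((row.window_start + 7_000), 30_000) // seg.bin_size
            want = int(
                np.sum(codes[w0:w1] == seg.state_code(row.state))
            )
            assert row.count == want


class TestSignalAggregation:
    def test_constant_signal(self):
        seg = make_segmentation(
            [("c", 0, 2000, "A"), ("c", 2000, 6000, "B")], {"c": 6000}
        )
        signal = pd.DataFrame(
            [("c", 0, 6000, 1.0)], columns=["chrom", "start", "end", "value"]
        )
        agg = sm.aggregate_signal_by_state(seg, signal)
        assert np.allclose(agg["mean"], 1.0)

    def test_signal_restricted_to_one_state(self):
        seg = make_segmentation(
            [("c", 0, 2000, "A"), ("c", 2000, 6000, "B")], {"c": 6000}
        )
        signal = pd.DataFrame(
            [("c", 0, 2000, 2.0)], columns=["chrom", "start", "end", "value"]
        )
        agg = sm.aggregate_signal_by_state(seg, signal)
        assert agg.loc["A", "mean"] == pytest.approx(2.0)
        assert agg.loc["B", "mean"] == pytest.approx(0.0)

    def test_weighted_mean_matches_perbp_oracle(self, rng):
        seg = random_segmentation(rng, {"c1": 10_000}, n_states=3)
        cuts = np.sort(rng.choice(np.arange(1, 10_000), 20, replace=False))
        bounds = np.concatenate([[0], cuts, [10_000]])
        signal = pd.DataFrame(
            [("c1", int(s), int(e), float(rng.random()))
             for s, e in zip(bounds[:-1], bounds[1:])],
            columns=["chrom", "start", "end", "value"],
        )
        agg = sm.aggregate_signal_by_state(seg, signal)
        want = oracle_signal_mean(seg, signal)
        assert np.allclose(agg["mean"], want.loc[agg.index])

    def test_unknown_chromosome_skipped(self):
        seg = make_segmentation([("c", 0, 1000, "A")], {"c": 1000})
        signal = pd.DataFrame(
            [("nope", 0, 100, 9.0)], columns=["chrom", "start", "end", "value"]
        )
        agg = sm.aggregate_signal_by_state(seg, signal)
        assert agg.loc["A", "mean"] == pytest.approx(0.0)
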