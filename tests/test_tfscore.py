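import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from conftest import make_segmentation, small_config

from chromstates import tfscore as tf
from chromstates.core import GeneModel, GeneModelSet, GenomicInterval, PeakSet
from chromstates.synth import generate_study


def enumeration_pvalue(k: int, m: int, q: int, N: int) -> float:
    """One-sided (greater) p by exhaustive enumeration of all 2x2 tables
    with margins (m, N-m) x (q, N-q): sum the probabilities of every table
    whose top-left cell is >= k."""
    denom = math.comb(N, m)
    total = 0
    for j in range(k, min(m, q) + 1):
        total += math.comb(q, j) * math.comb(N - q, m - j)
    return total / denom


class TestAssignPeakStates:
    def test_center_bin_arithmetic(self):
        seg = make_segmentation(
            [("c", 0, 200, "A"), ("c", 200, 400, "B"), ("c", 400, 600, "C")],
            {"c": 600},
        )
        ps = PeakSet("T", "chip", [GenomicInterval("c", 100, 301)])
        # center floor((100+301)/2) = 200 -> second bin
        assert tf.assign_peak_states(ps, seg) == ["B"]

    def test_single_bin_peak(self):
        seg = make_segmentation(
            [("c", 0, 200, "A"), ("c", 200, 400, "B")], {"c": 400}
        )
        ps = PeakSet("T", "chip", [GenomicInterval("c", 200, 400)])
        assert tf.assign_peak_states(ps, seg) == ["B"]

    def test_matches_direct_lookup(self, rng):
        from conftest import random_segmentation

        seg = random_segmentation(rng, {"c1": 20_000}, n_states=4)
        peaks = []
        for _ in range(50):
            s = int(rng.integers(0, 19_500))
            peaks.append(GenomicInterval("c1", s, s + int(rng.integers(50, 400))))
        ps = PeakSet("T", "chip", peaks)
        got = tf.assign_peak_states(ps, seg)
        for p, lab in zip(ps.peaks, got):
            center = (p.start + p.end) // 2
            assert seg.states[int(seg.state_at("c1", center)[0])] == lab


class TestOccupancy:
    def test_formula_arithmetic(self):
        # a_s=100, b=200, c_s=1000, d=10000 -> (100/200)/(1000/10000) = 5
        seg = make_segmentation(
            [("c", 0, 1000, "S"), ("c", 1000, 10_000, "O")], {"c": 10_000},
            bin_size=100,
        )
        ps = PeakSet("T", "chip", [GenomicInterval("c", 900, 1100)])
        occ = tf.occupancy_enrichment(ps, seg)
        assert occ.loc["S", "a_s"] == 100 and occ.loc["S", "b"] == 200
        assert occ.loc["S", "enrichment"] == pytest.approx(5.0)

    def test_genome_tiling_peaks_give_one(self, rng):
        from conftest import random_segmentation

        seg = random_segmentation(rng, {"c1": 8_000}, n_states=3)
        ps = PeakSet("T", "chip", [GenomicInterval("c1", 0, 8_000)])
        occ = tf.occupancy_enrichment(ps, seg)
        assert np.allclose(occ["enrichment"], 1.0)

    def test_conservation_of_totals(self, small_study):
        occ = tf.occupancy_enrichment(small_study.peaks[0],
                                      small_study.segmentation)
        assert occ["a_s"].sum() == occ["b"].iloc[0]
        assert occ["c_s"].sum() == occ["d"].iloc[0]

    def test_uniform_peaks_near_one(self):
        """preference 0: Monte-Carlo CI over seeds covers enrichment 1."""
        enr = []
        for seed in range(8):
            study = generate_study(small_config(
                seed=seed,
                tf_specs=[__import__("chromstates.synth", fromlist=["TFSpec"])
                          .TFSpec("T", n_peaks=80, preferred_state="E1",
                                  preference_weight=0.0)],
            ))
            occ = tf.occupancy_enrichment(study.peaks[0], study.segmentation)
            enr.append(occ["enrichment"])
        enr = pd.concat(enr, axis=1)
        mean = enr.mean(axis=1)
        sem = enr.std(axis=1, ddof=1) / np.sqrt(enr.shape[1])
        lo, hi = mean - 1.96 * sem, mean + 1.96 * sem
        assert ((lo <= 1.0) & (1.0 <= hi)).all()


class TestAnnotateTargets:
    def _setup(self):
        seg = make_segmentation([("c", 0, 40_000, "S")], {"c": 40_000})
        genes = GeneModelSet([
            GeneModel("g1", GenomicInterval("c", 5000, 7000, "+")),
            GeneModel("g2", GenomicInterval("c", 20_000, 22_000, "-")),
        ])
        return seg, genes

    def test_promoter_rule(self):
        seg, genes = self._setup()
        ps = PeakSet("T", "chip", [GenomicInterval("c", 4700, 4900)])
        df, targets = tf.annotate_targets(ps, ["S"], genes)
        assert df.iloc[0]["gene_id"] == "g1" and df.iloc[0]["rule"] == "promoter"

    def test_minus_strand_promoter_is_downstream_in_genomic_coords(self):
        seg, genes = self._setup()
        ps = PeakSet("T", "chip", [GenomicInterval("c", 22_100, 22_300)])
        df, _ = tf.annotate_targets(ps, ["S"], genes)
        assert df.iloc[0]["gene_id"] == "g2" and df.iloc[0]["rule"] == "promoter"

    def test_gene_body_rule(self):
        seg, genes = self._setup()
        ps = PeakSet("T", "chip", [GenomicInterval("c", 6500, 6700)])
        df, _ = tf.annotate_targets(ps, ["S"], genes)
        assert df.iloc[0]["gene_id"] == "g1" and df.iloc[0]["rule"] == "gene_body"

    def test_gene_desert_unassigned(self):
        seg, genes = self._setup()
        ps = PeakSet("T", "chip", [GenomicInterval("c", 35_000, 35_200)])
        df, targets = tf.annotate_targets(ps, ["S"], genes, max_distance=5000)
        assert df.iloc[0]["gene_id"] is None
        assert targets == {}

    def test_planted_targets_recovered(self):
        # generous intergenic spacing removes promoter/body ambiguity between
        # neighbouring genes, so recovery of planted targets must be complete
        study = generate_study(
            small_config(seed=0, gene_count=40, min_spacing_bins=5)
        )
        seg = study.segmentation
        pc = study.genes.subset("protein_coding")
        for ps in study.peaks[:3]:
            labels = tf.assign_peak_states(ps, seg)
            _, targets = tf.annotate_targets(ps, labels, pc)
            found = set().union(*targets.values()) if targets else set()
            planted = set(study.truth.tf_targets[ps.tf_id])
            assert planted <= found


class TestCoexpressionFilter:
    def test_strict_positive_boundary(self):
        s = pd.Series({"g1": 100, "g2": 1999, "g3": 2000, "g4": 5000})
        pos, neg = tf.coexpression_filter(s)
        assert pos == {"g1", "g2"}

    def test_negative_tail_from_tf_max(self):
        s = pd.Series({"g1": 100, "g2": 4200, "g3": 5000})
        _, neg = tf.coexpression_filter(s)
        assert neg == {"g2", "g3"}  # > 5000 - 1000

    def test_functional_targets_all_positive(self, small_study):
        tf_id = small_study.truth.tf_table.index[0]
        scores = small_study.coexpression.for_tf(tf_id)
        ceiling = small_study.config.coexpr.functional_rank_ceiling
        pos, _ = tf.coexpression_filter(scores, positive_threshold=ceiling)
        assert set(small_study.truth.tf_targets[tf_id]) <= pos


class TestActivityScore:
    def test_forced_score_points(self):
        assert tf.raw_score(1.0, 0.0) == pytest.approx(0.0)
        assert tf.raw_score(0.1, 1.0) == pytest.approx(2.0)

    def test_no_targets_state(self):
        res = tf.activity_score({"s": set()}, {"g1"}, 10, states=["s"])
        row = res.loc["s"]
        assert row["p_value"] == 1.0 and row["odds_ratio"] == 0.0
        assert row["raw_score"] == 0.0

    @pytest.mark.parametrize(
        "k,m,q,N",
        [(5, 10, 10, 100), (0, 7, 30, 60), (3, 3, 3, 12), (12, 25, 40, 200),
         (1, 50, 2, 120)],
    )
    def test_p_matches_exhaustive_enumeration(self, k, m, q, N):
        genes = [f"g{i}" for i in range(N)]
        targets = {"s": set(genes[:k]) | set(genes[q:q + m - k])}
        coexpr = set(genes[:q])
        res = tf.activity_score(targets, coexpr, N, states=["s"])
        assert res.loc["s", "p_value"] == pytest.approx(
            enumeration_pvalue(k, m, q, N), abs=1e-12
        )
        # and agrees with the independent exact-test implementation
        table = [[k, m - k], [q - k, N - m - q + k]]
        assert res.loc["s", "p_value"] == pytest.approx(
            fisher_exact(table, alternative="greater")[1], abs=1e-12
        )

    def test_score_monotone_in_k(self):
        N, m, q = 80, 12, 20
        genes = [f"g{i}" for i in range(N)]
        coexpr = set(genes[:q])
        scores = []
        for k in range(0, min(m, q) + 1):
            targets = {"s": set(genes[:k]) | set(genes[q:q + m - k])}
            res = tf.activity_score(targets, coexpr, N, states=["s"])
            scores.append(res.loc["s", "raw_score"])
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_haldane_correction_on_zero_cell(self):
        genes = [f"g{i}" for i in range(20)]
        # k = m = 3: the (m - k) cell is zero -> all cells get +0.5
        res = tf.activity_score(
            {"s": set(genes[:3])}, set(genes[:5]), 20, states=["s"]
        )
        expected_or = (3.5 * 15.5) / (0.5 * 2.5)
        assert res.loc["s", "odds_ratio"] == pytest.approx(expected_or)


class TestScoreMatrixAndClustering:
    def _results(self, rows):
        out = {}
        for tf_id, scores in rows.items():
            out[tf_id] = pd.DataFrame(
                {"raw_score": pd.Series(scores)}
            ).rename_axis("state")
        return out

    def test_strict_filter_boundary(self):
        res = self._results({"lo": {"a": 7.99}, "hi": {"a": 8.0}})
        mat, dropped = tf.build_score_matrix(res)
        assert list(mat.index) == ["hi"] and list(dropped.index) == ["lo"]

    def test_rows_normalised_to_unit_max(self):
        res = self._results({"t": {"a": 16.0, "b": 4.0}})
        mat, _ = tf.build_score_matrix(res)
        assert mat.loc["t", "a"] == 1.0 and mat.loc["t", "b"] == 0.25

    def test_all_dropped_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            tf.build_score_matrix(self._results({"t": {"a": 1.0}}))

    def test_identical_rows_cluster_together(self):
        mat = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]],
            index=["t1", "t2", "t3"], columns=["a", "b"],
        )
        model = tf.cluster_tfs(mat, k=2)
        assert model.labels["t1"] == model.labels["t2"] != model.labels["t3"]

    def test_orthogonal_blocks_recovered(self):
        rows = np.vstack([np.tile([1.0, 0, 0], (4, 1)),
                          np.tile([0, 0, 1.0], (4, 1))])
        mat = pd.DataFrame(rows, index=[f"t{i}" for i in range(8)])
        model = tf.cluster_tfs(mat, k=2)
        labels = model.labels
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_below_two_errors(self):
        mat = pd.DataFrame([[1.0], [0.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            tf.cluster_tfs(mat, k=1)


class TestFamilyEnrichment:
    def test_concentrated_family_minimal_p(self):
        labels = pd.Series({f"t{i}": 1 if i < 4 else 2 for i in range(8)})
        fams = pd.Series({f"t{i}": "F" if i < 4 else "G" for i in range(8)})
        out = tf.family_enrichment(labels, fams)
        sub = out[out.family == "F"].set_index("cluster")
        assert sub.loc[1, "p_value"] == sub["p_value"].min()
        assert sub.loc[1, "p_value"] == pytest.approx(
            enumeration_pvalue(4, 4, 4, 8), abs=1e-12
        )

    def test_uniform_family_or_near_one(self):
        labels = pd.Series({f"t{i}": (i % 2) + 1 for i in range(12)})
        fams = pd.Series({f"t{i}": "F" if i < 6 else "G" for i in range(12)})
        out = tf.family_enrichment(labels, fams)
        ors = out[out.family == "F"]["odds_ratio"]
        assert np.allclose(ors, 1.0, atol=0.5)

    def test_p_matches_enumeration_on_toy_counts(self):
        labels = pd.Series({f"t{i}": 1 if i < 5 else 2 for i in range(9)})
        fams = pd.Series(
            {f"t{i}": "F" if i in (0, 1, 5) else "G" for i in range(9)}
        )
        out = tf.family_enrichment(labels, fams).set_index(["family", "cluster"])
        assert out.loc[("F", 1), "p_value"] == pytest.approx(
            enumeration_pvalue(2, 5, 3, 9), abs=1e-12
        )


class TestTssHistogram:
    def _genes(self):
        return GeneModelSet([
            GeneModel("g1", GenomicInterval("c", 5000, 6000, "+")),
            GeneModel("g2", GenomicInterval("c", 20_000, 21_000, "-")),
        ])

    def test_peaks_at_tss_spike_at_zero(self):
        ps = PeakSet("T", "chip", [GenomicInterval("c", 4950, 5050)])
        out = tf.tss_binding_histogram({1: [ps]}, self._genes(),
                                       window=1000, nbins=4)
        hot = out[out["count"] > 0]
        assert len(hot) == 1
        assert hot.iloc[0]["bin_left"] <= 0 <= hot.iloc[0]["bin_right"]

    def test_minus_strand_orientation(self):
        # 150 bp to the right of a minus gene's TSS base is upstream
        ps = PeakSet("T", "chip", [GenomicInterval("c", 21_099, 21_199)])
        out = tf.tss_binding_histogram({1: [ps]}, self._genes(),
                                       window=1000, nbins=10)
        hot = out[out["count"] > 0].iloc[0]
        assert hot["bin_right"] <= 0

    def test_planted_cluster_modes_on_opposite_sides(self, small_study):
        truth = small_study.truth.tf_table
        peaks_by = {1: [], 2: []}
        for ps in small_study.peaks:
            pref = truth.loc[ps.tf_id, "preferred_state"]
            if pref == "I1":
                peaks_by[1].append(ps)  # promoter/NFR binders: upstream
            elif pref == "E3":
                peaks_by[2].append(ps)  # deep gene-body binders: downstream
        pc = small_study.genes.subset("protein_coding")
        out = tf.tss_binding_histogram(peaks_by, pc, window=2000, nbins=20)

        def mode_center(cluster):
            sub = out[out.cluster == cluster]
            top = sub.loc[sub["count"].idxmax()]
            return (top["bin_left"] + top["bin_right"]) / 2

        assert mode_center(1) < 0 < mode_center(2)
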