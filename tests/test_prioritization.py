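"""Gene distinctiveness scores and the Jaccard pathway fingerprint."""

import math
import warnings

import pytest

from specfp import (
    GeneGraph,
    GraphSet,
    distinctiveness,
    fingerprint,
    fingerprint_difference,
    gene_degree_profile,
    gene_kl,
    gene_scores,
    pathway_jaccard,
    top_driving_genes,
)
from specfp.prioritization import (
    DrivingGeneSet,
    FingerprintRow,
    GeneAbsentError,
    GeneScore,
    fingerprint_frame,
)


def star_pathway(pid, center, leaves):
    """Pathway where ``center`` has degree len(leaves)."""
    return GeneGraph.from_edges(pid, [center, *leaves], [(center, l) for l in leaves])


def make_cluster(label, degrees, center="990001"):
    """Cluster whose pathways give ``center`` the listed degrees.

    Leaf gene IDs are disjoint between cluster labels so only the center is
    shared across clusters.
    """
    base = 900000 + 1000 * sum(ord(c) for c in label)
    graphs = []
    for i, deg in enumerate(degrees):
        leaves = [str(base + 100 * i + j) for j in range(deg)]
        graphs.append(star_pathway(f"{label}-{i}", center, leaves))
    return GraphSet(label, graphs)


class TestDegreeProfile:
    def test_point_mass_before_smoothing(self):
        cluster = make_cluster("A", [3, 3])
        prof = gene_degree_profile("990001", cluster, support=[3], alpha=0.0)
        assert prof.probabilities.tolist() == [1.0]
        assert prof.n_pathways == 2

    def test_two_distinct_degrees_give_half_half(self):
        cluster = make_cluster("A", [2, 4])
        prof = gene_degree_profile("990001", cluster, support=[2, 4], alpha=0.0)
        assert prof.probabilities.tolist() == [0.5, 0.5]

    def test_smoothing_keeps_all_probabilities_positive(self):
        cluster = make_cluster("A", [3, 3, 3, 3])
        prof = gene_degree_profile("990001", cluster, support=[1, 3, 10])
        assert (prof.probabilities > 0).all()
        assert prof.probabilities.sum() == pytest.approx(1.0)

    def test_absent_gene_signals_absence(self):
        cluster = make_cluster("A", [3, 3])
        with pytest.raises(GeneAbsentError):
            gene_degree_profile("123", cluster, support=[1])


class TestGeneKl:
    def test_identical_profiles_give_zero(self):
        a = make_cluster("A", [3, 3, 3, 3])
        b = make_cluster("B", [3, 3, 3, 3])
        assert gene_kl("990001", a, b) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_computation(self):
        # degree 1 in all 4 pathways of k, degree 10 in all 4 of l:
        # smoothed profiles on {1,10} are (0.9, 0.1) vs (0.1, 0.9);
        # KL = 0.9 ln 9 + 0.1 ln(1/9) = 0.8 ln 9
        a = make_cluster("A", [1, 1, 1, 1])
        b = make_cluster("B", [10, 10, 10, 10])
        assert gene_kl("990001", a, b) == pytest.approx(0.8 * math.log(9), abs=1e-12)

    def test_directional_asymmetry(self):
        a = make_cluster("A", [1, 2, 3])
        b = make_cluster("B", [2, 2, 2, 2])
        assert gene_kl("990001", a, b) != pytest.approx(gene_kl("990001", b, a))


class TestDistinctiveness:
    def test_min_over_other_clusters(self):
        # l1 overlaps k's degree support, l2 is disjoint: KL against l1 is smaller
        clusters = {
            "k": make_cluster("k", [2, 2, 2, 2]),
            "l1": make_cluster("l1", [2, 2, 3, 3]),
            "l2": make_cluster("l2", [12, 12, 12, 12]),
        }
        score = distinctiveness("990001", clusters, home="k")
        assert score.kl_values["l1"] < score.kl_values["l2"]
        assert score.distinctiveness == pytest.approx(min(score.kl_values.values()))
        assert score.distinctiveness == pytest.approx(score.kl_values["l1"])

    def test_two_cluster_case_equals_single_kl(self):
        a = make_cluster("A", [2, 2, 2, 2])
        b = make_cluster("B", [7, 7, 7, 7])
        score = distinctiveness("990001", {"A": a, "B": b}, home="A")
        assert score.distinctiveness == pytest.approx(gene_kl("990001", a, b))

    def test_score_invariant_enforced(self):
        with pytest.raises(ValueError, match="minimum|min"):
            GeneScore("g", "k", {"l": 0.5}, 0.1)

    def test_gene_absent_everywhere_else(self):
        a = make_cluster("A", [2, 2])
        b = make_cluster("B", [3, 3])
        leaf_of_a = sorted(a.genes() - {"990001"})[0]
        with pytest.raises(GeneAbsentError):
            distinctiveness(leaf_of_a, {"A": a, "B": b}, home="A")


class TestGeneScores:
    def test_exclude_policy_drops_unshared_genes(self):
        a = make_cluster("A", [2, 2, 2, 2])
        b = make_cluster("B", [5, 5, 5, 5])
        scores = gene_scores({"A": a, "B": b})
        assert {s.gene for s in scores} == {"990001"}  # only the center is shared

    def test_unique_policy_assigns_ceiling_and_flags(self):
        a = make_cluster("A", [2, 2, 2, 2])
        b = make_cluster("B", [5, 5, 5, 5])
        scores = gene_scores({"A": a, "B": b}, absent_policy="unique")
        uniques = [s for s in scores if s.unique_to_cluster]
        shared = [s for s in scores if not s.unique_to_cluster]
        assert uniques and shared
        ceiling = max(s.distinctiveness for s in shared)
        assert all(u.distinctiveness > ceiling for u in uniques)


class TestTopDrivingGenes:
    def _scores(self, values, cluster="k"):
        return [GeneScore(g, cluster, {"l": v}, v) for g, v in values.items()]

    def test_fewer_genes_than_n_returns_all_with_warning(self):
        scores = self._scores({"1": 0.3, "2": 0.2, "3": 0.1})
        with pytest.warns(UserWarning, match="only 3"):
            d = top_driving_genes(scores, "k", top_n=10)
        assert d.genes == {"1", "2", "3"}

    def test_tie_at_cutoff_includes_both(self):
        values = {str(i): 1.0 - 0.05 * i for i in range(1, 11)}
        values["11"] = values["10"]  # tie at rank 10
        d = top_driving_genes(self._scores(values), "k", top_n=10)
        assert len(d.genes) == 11
        assert "ties" in d.selection_rule

    def test_deterministic_across_runs(self):
        values = {str(i): (i * 7919 % 13) / 13 for i in range(1, 30)}
        d1 = top_driving_genes(self._scores(values), "k", top_n=10)
        d2 = top_driving_genes(self._scores(values), "k", top_n=10)
        assert d1.genes == d2.genes and d1.selection_rule == d2.selection_rule


class TestPathwayJaccard:
    def test_identical_sets_give_one(self):
        d = DrivingGeneSet("k", frozenset({"1", "2", "3"}), "top_n=3")
        g = GeneGraph.from_edges("p", ["1", "2", "3"], [("1", "2")])
        assert pathway_jaccard(d, g) == 1.0

    def test_disjoint_sets_give_zero(self):
        d = DrivingGeneSet("k", frozenset({"7"}), "top_n=1")
        g = GeneGraph.from_edges("p", ["1", "2"], [("1", "2")])
        assert pathway_jaccard(d, g) == 0.0

    def test_partial_overlap(self):
        d = DrivingGeneSet("k", frozenset({"1", "2", "3"}), "r")
        g = GeneGraph.from_edges("p", ["2", "3", "4"], [("2", "3")])
        assert pathway_jaccard(d, g) == pytest.approx(0.5)

    def test_both_empty_is_zero_with_warning(self):
        d = DrivingGeneSet("k", frozenset(), "r")
        g = GeneGraph.from_edges("p", [], [])
        with pytest.warns(UserWarning, match="empty"):
            assert pathway_jaccard(d, g) == 0.0


def _fingerprint_setup():
    clusters = {"A": make_cluster("A", [2, 2, 2]), "B": make_cluster("B", [9, 9, 9])}
    scores = gene_scores(clusters)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # only one shared gene -> top_n warning
        driving = {l: top_driving_genes(scores, l, top_n=5) for l in clusters}
    return clusters, driving


class TestFingerprint:
    def test_row_count_equals_total_pathways(self):
        clusters, driving = _fingerprint_setup()
        rows = fingerprint(clusters, driving)
        assert len(rows) == sum(len(c) for c in clusters.values())

    def test_identical_pathways_get_identical_jaccard(self):
        clusters, driving = _fingerprint_setup()
        rows = fingerprint(clusters, driving)
        for label in clusters:
            assert len({r.jaccard for r in rows if r.cluster == label}) == 1

    def test_missing_metadata_defaults_to_unknown(self):
        clusters, driving = _fingerprint_setup()
        rows = fingerprint(clusters, driving, metadata={})
        assert all(r.kegg_class == "unknown" for r in rows)

    def test_sorted_by_class_then_descending_jaccard(self):
        clusters, driving = _fingerprint_setup()
        meta = {
            pid: ("Metabolism" if pid.startswith("A") else "Human Diseases")
            for c in clusters.values()
            for pid in c.pathway_ids
        }
        rows = fingerprint(clusters, driving, metadata=meta)
        keys = [(r.kegg_class, -r.jaccard) for r in rows]
        assert keys == sorted(keys)

    def test_jaccard_bounds_enforced(self):
        with pytest.raises(ValueError):
            FingerprintRow("p", "k", "c", 1.5)


class TestFingerprintDifference:
    def _rows(self, values, cluster="k"):
        return [FingerprintRow(pid, cluster, kc, j) for pid, (kc, j) in values.items()]

    def test_identical_fingerprints_give_zero_differences(self):
        fp = self._rows({"p1": ("M", 0.4), "p2": ("M", 0.1)})
        by_pathway, by_class = fingerprint_difference(fp, fp)
        assert (by_pathway["difference"] == 0).all()
        assert (by_class["difference"] == 0).all()

    def test_single_shared_pathway_difference(self):
        a = self._rows({"p1": ("M", 0.4)})
        b = self._rows({"p1": ("M", 0.1)})
        by_pathway, _ = fingerprint_difference(a, b)
        assert by_pathway["difference"].item() == pytest.approx(0.3)

    def test_class_aggregate_is_mean_of_member_differences(self):
        a = self._rows({"p1": ("M", 0.5), "p2": ("M", 0.3), "p3": ("H", 0.2)})
        b = self._rows({"p1": ("M", 0.1), "p2": ("M", 0.3), "p3": ("H", 0.6)})
        by_pathway, by_class = fingerprint_difference(a, b)
        m = by_pathway[by_pathway["kegg_class"] == "M"]["difference"].mean()
        assert by_class.set_index("kegg_class").loc["M", "difference"] == pytest.approx(m)

    def test_no_shared_pathways_warns_and_returns_empty(self):
        a = self._rows({"p1": ("M", 0.5)})
        b = self._rows({"p9": ("M", 0.5)})
        with pytest.warns(UserWarning, match="share no pathways"):
            by_pathway, by_class = fingerprint_difference(a, b)
        assert by_pathway.empty and by_class.empty


def test_adding_pathway_without_driving_genes_never_raises_others_jaccard():
    clusters, driving = _fingerprint_setup()
    before = {r.pathway_id: r.jaccard for r in fingerprint(clusters, driving)}
    extra = GeneGraph.from_edges("A-extra", ["888880", "888881"], [("888880", "888881")])
    bigger = dict(clusters)
    bigger["A"] = GraphSet("A", list(clusters["A"].graphs) + [extra])
    after = {r.pathway_id: r.jaccard for r in fingerprint(bigger, driving)}
    for pid, j in before.items():
        assert after[pid] <= j + 1e-12


def test_fingerprint_frame_columns():
    rows = [FingerprintRow("p", "k", "M", 0.5, True)]
    df = fingerprint_frame(rows)
    assert list(df.columns) == ["pathway_id", "cluster", "kegg_class", "jaccard", "flagged"]
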