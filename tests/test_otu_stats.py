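import logging

import numpy as np
import pytest
from sklearn.base import clone

from barcodedelim import SimConfig, simulate_dataset
from barcodedelim.distances import (
    DistanceMatrix,
    DistanceModelConfig,
    NoComparableSitesError,
    distance_matrix,
)
from barcodedelim.otu_stats import (
    UNASSIGNED,
    AssignConfig,
    ClassicalMDS,
    Partition,
    ReferenceAssigner,
    ThresholdClustering,
    assign_to_reference,
    barcode_gap_table,
    mds_embed,
    otu_summaries,
    summaries_table,
    threshold_cluster,
)
from barcodedelim.seqio import Alignment, SequenceRecord

from .oracles import naive_components


def dm_from(labels, data):
    return DistanceMatrix(labels, np.asarray(data, float),
                          DistanceModelConfig(model="p"))


class TestPartition:
    def test_groups_and_structure(self):
        p = Partition({"a": "1", "b": "1", "c": "2"})
        assert p.n_groups == 2
        assert p.groups() == {"1": ["a", "b"], "2": ["c"]}
        q = Partition({"a": "x", "b": "x", "c": "y"})
        assert p.same_structure(q)

    def test_tsv_roundtrip(self, tmp_path):
        p = Partition({"a": "1", "b": "2"}, source="abgd")
        path = tmp_path / "p.tsv"
        p.to_tsv(path)
        assert Partition.from_tsv(path).assignment == p.assignment

    def test_empty_group_id_rejected(self):
        with pytest.raises(ValueError):
            Partition({"a": ""})


class TestThresholdCluster:
    def test_threshold_above_max_gives_one_group(self):
        dm = dm_from(list("abc"), [[0, 0.1, 0.2], [0.1, 0, 0.15], [0.2, 0.15, 0]])
        assert threshold_cluster(dm, 0.5).n_groups == 1

    def test_threshold_below_min_gives_singletons(self):
        dm = dm_from(list("abc"), [[0, 0.1, 0.2], [0.1, 0, 0.15], [0.2, 0.15, 0]])
        assert threshold_cluster(dm, 0.05).n_groups == 3

    def test_planted_lineages_recovered(self):
        sim = simulate_dataset(SimConfig(n_lineages=4, seqs_per_lineage=5, seed=8))
        dm = distance_matrix(sim.alignment, DistanceModelConfig(model="p"))
        part = threshold_cluster(dm, 0.0112)
        assert part.same_structure(sim.truth)

    def test_monotone_in_threshold(self):
        sim = simulate_dataset(SimConfig(n_lineages=4, seqs_per_lineage=5, seed=8))
        dm = distance_matrix(sim.alignment, DistanceModelConfig(model="p"))
        counts = [threshold_cluster(dm, t).n_groups
                  for t in (0.001, 0.005, 0.02, 0.05, 0.2)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_components(self, rng):
        n = 8
        labels = [f"s{i}" for i in range(n)]
        data = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0, 0.1, len(iu[0]))
        data[iu] = vals
        data += data.T
        dm = dm_from(labels, data)
        part = threshold_cluster(dm, 0.04)
        assert part.as_sets() == naive_components(labels, data, 0.04)

    def test_estimator_clone(self):
        est = ThresholdClustering(threshold=0.02)
        assert clone(est).get_params() == est.get_params()


def ref_alignment():
    return Alignment(
        [
            SequenceRecord(id="r1", seq="A" * 100, group="G1"),
            SequenceRecord(id="r2", seq="C" * 100, group="G2"),
        ]
    )


class TestAssignment:
    def test_identical_query_assigned_at_100(self):
        assert assign_to_reference("A" * 100, ref_alignment()) == "G1"

    def test_two_percent_divergence_unassigned(self):
        # p-distance 0.02 -> similarity 98.0 < 98.88
        query = "G" * 2 + "A" * 98
        assert assign_to_reference(query, ref_alignment()) == UNASSIGNED

    def test_one_percent_divergence_assigned(self):
        # p-distance 0.01 -> similarity 99.0 >= 98.88
        query = "G" * 1 + "A" * 99
        assert assign_to_reference(query, ref_alignment()) == "G1"

    def test_never_invents_groups(self):
        est = ReferenceAssigner().fit(["A" * 50, "C" * 50], ["G1", "G2"])
        preds = est.predict(["A" * 50, "C" * 50, "T" * 50])
        assert set(preds) <= {"G1", "G2", UNASSIGNED}

    def test_tie_broken_by_first_reference_with_warning(self, caplog):
        refs = Alignment(
            [
                SequenceRecord(id="r1", seq="A" * 99 + "C", group="G1"),
                SequenceRecord(id="r2", seq="A" * 99 + "G", group="G2"),
            ]
        )
        # query equidistant (p = 0.01, similarity 99) from both groups
        with caplog.at_level(logging.WARNING, logger="barcodedelim"):
            got = assign_to_reference("A" * 100, refs)
        assert got == "G1"
        assert any("tie" in rec.message for rec in caplog.records)

    def test_no_comparable_sites_errors(self):
        refs = Alignment([SequenceRecord(id="r1", seq="NNNN", group="G1")])
        with pytest.raises(NoComparableSitesError):
            assign_to_reference("ACGT", refs)

    def test_missing_group_label_rejected(self):
        refs = Alignment([SequenceRecord(id="r1", seq="ACGT")])
        with pytest.raises(ValueError, match="group"):
            assign_to_reference("ACGT", refs)


class TestOtuSummaries:
    def test_hand_enumerated_two_groups_of_two(self):
        labels = ["a1", "a2", "b1", "b2"]
        data = np.array(
            [
                [0.0, 0.01, 0.08, 0.10],
                [0.01, 0.0, 0.09, 0.11],
                [0.08, 0.09, 0.0, 0.02],
                [0.10, 0.11, 0.02, 0.0],
            ]
        )
        part = Partition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        by_group = {s.group: s for s in otu_summaries(dm_from(labels, data), part)}
        a, b = by_group["A"], by_group["B"]
        assert (a.n, b.n) == (2, 2)
        assert a.max_intra == pytest.approx(1.0)  # percent
        assert a.mean_intra == pytest.approx(1.0)
        assert b.max_intra == pytest.approx(2.0)
        assert a.nn_group == "B" and b.nn_group == "A"
        assert a.nn_distance == pytest.approx(8.0)  # min cross pair, percent
        assert b.nn_distance == pytest.approx(8.0)

    def test_min_cross_distance_is_symmetric(self):
        sim = simulate_dataset(SimConfig(n_lineages=3, seqs_per_lineage=4, seed=17))
        dm = distance_matrix(sim.alignment, DistanceModelConfig(model="p"))
        summaries = {s.group: s for s in otu_summaries(dm, sim.truth)}
        groups = sim.truth.groups()
        for g, s in summaries.items():
            ia = [dm.index(l) for l in groups[g]]
            ib = [dm.index(l) for l in groups[s.nn_group]]
            forward = dm.data[np.ix_(ia, ib)].min()
            backward = dm.data[np.ix_(ib, ia)].min()
            assert forward == pytest.approx(backward)

    def test_singleton_intra_stats_undefined(self):
        dm = dm_from(["a", "b", "c"], [[0, 0.05, 0.06], [0.05, 0, 0.04],
                                       [0.06, 0.04, 0]])
        part = Partition({"a": "X", "b": "Y", "c": "Y"})
        s = {x.group: x for x in otu_summaries(dm, part)}
        assert s["X"].max_intra is None and s["X"].mean_intra is None
        assert s["X"].nn_distance is not None

    def test_two_identical_members(self):
        dm = dm_from(["a", "b"], [[0, 0], [0, 0]])
        part = Partition({"a": "G", "b": "G"})
        with pytest.warns(UserWarning, match="fewer than 2 groups"):
            (s,) = otu_summaries(dm, part)
        assert s.max_intra == 0 and s.mean_intra == 0 and s.nn_group is None

    def test_unassigned_label_errors(self):
        dm = dm_from(["a", "b"], [[0, 0.1], [0.1, 0]])
        with pytest.raises(KeyError):
            otu_summaries(dm, Partition({"a": "G"}))

    def test_summaries_table_columns(self):
        dm = dm_from(["a", "b"], [[0, 0.1], [0.1, 0]])
        part = Partition({"a": "X", "b": "Y"})
        df = summaries_table(otu_summaries(dm, part))
        assert list(df.columns) == ["group", "N", "max_intra", "mean_intra", "NN",
                                    "dist_to_NN"]


class TestBarcodeGapTable:
    def _summary(self, group, max_intra, nn_distance):
        from barcodedelim.otu_stats import OtuSummary

        return OtuSummary(group, 5, max_intra, max_intra, "other", nn_distance)

    def test_resolved_otu_positive_gap(self):
        # max intra 3.54%, NN at 5.3% -> gap statistic 1.76, resolved
        (row,) = barcode_gap_table([self._summary("AAB1732", 3.54, 5.3)]).to_dict(
            "records"
        )
        assert row["y_gap"] == pytest.approx(1.76)
        assert row["resolved"]

    def test_unresolved_otu_negative_gap(self):
        # max intra 3.71% exceeds NN distance 1.44% -> -2.27, unresolved
        (row,) = barcode_gap_table([self._summary("ABZ3047", 3.71, 1.44)]).to_dict(
            "records"
        )
        assert row["y_gap"] == pytest.approx(-2.27)
        assert not row["resolved"]

    def test_boundary_zero_flagged_unresolved(self):
        (row,) = barcode_gap_table([self._summary("X", 2.0, 2.0)]).to_dict("records")
        assert row["y_gap"] == 0 and not row["resolved"]

    def test_singletons_excluded(self):
        from barcodedelim.otu_stats import OtuSummary

        df = barcode_gap_table([OtuSummary("S", 1, None, None, "other", 2.0)])
        assert df.empty


class TestClassicalMDS:
    def test_three_equidistant_points_form_equilateral_triangle(self):
        dm = dm_from(list("abc"), 1 - np.eye(3))
        coords = mds_embed(dm, k=2)
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
                assert d == pytest.approx(1.0, abs=1e-9)

    def test_planted_planar_configuration_recovered(self, rng):
        pts = rng.uniform(-2, 2, size=(7, 2))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        labels = [f"g{i}" for i in range(7)]
        coords = mds_embed(dm_from(labels, D), k=2).to_numpy()
        D2 = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.allclose(D, D2, atol=1e-9)

    def test_collinear_points_have_flat_second_axis(self, rng):
        x = np.sort(rng.uniform(0, 5, size=6))
        D = np.abs(x[:, None] - x[None, :])
        coords = mds_embed(dm_from([f"g{i}" for i in range(6)], D), k=2)
        # the degenerate axis carries sqrt(machine-epsilon) eigenvector noise
        assert np.allclose(coords["axis2"], 0, atol=1e-6)

    def test_matches_skbio_pcoa(self, rng):
        import skbio

        pts = rng.uniform(-1, 1, size=(6, 3))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        labels = [f"g{i}" for i in range(6)]
        ours = mds_embed(dm_from(labels, D), k=2).to_numpy()
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D, ids=labels), number_of_dimensions=2
        ).samples.to_numpy()
        # same up to per-axis sign
        for axis in range(2):
            col, ref = ours[:, axis], theirs[:, axis]
            assert np.allclose(col, ref, atol=1e-8) or np.allclose(col, -ref,
                                                                   atol=1e-8)

    def test_too_few_points_or_components_rejected(self):
        dm = dm_from(list("ab"), [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            ClassicalMDS(n_components=2).fit(dm)
        dm3 = dm_from(list("abc"), 1 - np.eye(3))
        with pytest.raises(ValueError):
            ClassicalMDS(n_components=3).fit(dm3)

    def test_isometry_up_to_rigid_motion(self, rng):
        # Euclidean-realizable input: embedding preserves all distances
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        emb = ClassicalMDS(n_components=2).fit_transform(D)
        D2 = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=-1)
        assert np.allclose(D, D2, atol=1e-9)
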