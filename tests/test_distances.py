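import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcodedelim import SimConfig, simulate_dataset
from barcodedelim.distances import (
    DegenerateFrequenciesError,
    DistanceMatrix,
    DistanceModelConfig,
    NoComparableSitesError,
    SitePatternCounts,
    distance_matrix,
    group_distance_summary,
    k2p_distance,
    p_distance,
    site_pattern_counts,
    tn93_distance,
)
from barcodedelim.otu_stats import Partition

from .oracles import naive_site_counts

UNIFORM100 = (50, 50, 50, 50)  # uniform base counts for n_sites=100


def counts(n, ag, ct, tv, bases=None):
    if bases is None:
        per = n // 2
        bases = (per, per, per, 2 * n - 3 * per)
    return SitePatternCounts(n, ag, ct, tv, bases)


seq_pairs = st.integers(5, 60).flatmap(
    lambda L: st.tuples(
        st.text(alphabet="ACGTN-", min_size=L, max_size=L),
        st.text(alphabet="ACGTN-", min_size=L, max_size=L),
    )
)


class TestSitePatternCounts:
    def test_identical_sequences(self):
        c = site_pattern_counts("ACGT", "ACGT")
        assert (c.n_sites, c.n_ts_AG, c.n_ts_CT, c.n_tv) == (4, 0, 0, 0)

    def test_ag_change_is_transition(self):
        c = site_pattern_counts("ACGT", "GCGT")
        assert (c.n_sites, c.n_ts_AG, c.n_tv) == (4, 1, 0)

    def test_pairwise_deletion_drops_gap_and_n_columns(self):
        c = site_pattern_counts("AC-T", "ACNT")
        expected = naive_site_counts("AC-T", "ACNT")
        assert c.n_sites == expected["n_sites"] == 3
        assert c.base_counts == expected["base_counts"]

    @given(seq_pairs)
    def test_matches_naive_enumeration(self, pair):
        a, b = pair
        expected = naive_site_counts(a, b)
        if expected["n_sites"] == 0:
            with pytest.raises(NoComparableSitesError):
                site_pattern_counts(a, b)
            return
        c = site_pattern_counts(a, b)
        assert c.n_sites == expected["n_sites"]
        assert c.n_ts_AG == expected["n_ts_AG"]
        assert c.n_ts_CT == expected["n_ts_CT"]
        assert c.n_tv == expected["n_tv"]
        assert c.base_counts == expected["base_counts"]

    def test_no_comparable_sites(self):
        with pytest.raises(NoComparableSitesError):
            site_pattern_counts("NNNN", "ACGT")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            site_pattern_counts("ACGT", "ACGTA")


class TestPDistance:
    def test_zero_and_simple_fraction(self):
        assert p_distance(counts(100, 0, 0, 0)) == 0.0
        assert p_distance(counts(100, 2, 2, 1)) == pytest.approx(0.05)

    @given(seq_pairs)
    def test_equals_naive_mismatch_fraction(self, pair):
        a, b = pair
        expected = naive_site_counts(a, b)
        if expected["n_sites"] == 0:
            return
        diffs = expected["n_ts_AG"] + expected["n_ts_CT"] + expected["n_tv"]
        assert p_distance(site_pattern_counts(a, b)) == pytest.approx(
            diffs / expected["n_sites"]
        )


class TestK2P:
    def test_zero(self):
        assert k2p_distance(counts(100, 0, 0, 0)) == 0.0

    def test_closed_form_pure_transition(self):
        # d = -1/2 ln(1 - 2*0.1) at P=0.1, Q=0
        d = k2p_distance(SitePatternCounts(100, 5, 5, 0, UNIFORM100))
        assert d == pytest.approx(0.11157, abs=5e-6)
        assert d == pytest.approx(-0.5 * math.log(0.8))

    def test_closed_form_pure_transversion(self):
        # d = -1/2 ln(0.9) - 1/4 ln(0.8) at P=0, Q=0.1
        d = k2p_distance(SitePatternCounts(100, 0, 0, 10, UNIFORM100))
        assert d == pytest.approx(-0.5 * math.log(0.9) - 0.25 * math.log(0.8))
        assert d == pytest.approx(0.108466, abs=5e-7)

    def test_saturation_signalled_as_inf(self):
        assert math.isinf(k2p_distance(counts(10, 5, 0, 0)))
        assert math.isinf(k2p_distance(counts(10, 0, 0, 5)))

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_k2p_at_least_p(self, ag, ct, tv):
        n = 100
        c = SitePatternCounts(n, ag, ct, tv, UNIFORM100)
        k2p, p = k2p_distance(c), p_distance(c)
        assert k2p >= p >= 0
        if p > 0:
            assert k2p > p
        else:
            assert k2p == 0


class TestTN93:
    def test_identical_zero_for_any_alpha(self):
        c = counts(100, 0, 0, 0, (50, 50, 50, 50))
        for alpha in (None, 0.5, 1.0, 10.0):
            assert tn93_distance(c, gamma_shape=alpha) == 0.0

    def test_reduces_to_k2p_under_uniform_pi(self):
        c = SitePatternCounts(200, 10, 10, 8, (100, 100, 100, 100))
        assert tn93_distance(c) == pytest.approx(k2p_distance(c), abs=1e-9)

    def test_gamma_one_closed_form(self):
        # independent direct evaluation: uniform pi, P1=P2=0.05, Q=0.02, alpha=1
        c = SitePatternCounts(100, 5, 5, 2, (50, 50, 50, 50))
        piA = piC = piG = piT = 0.25
        piR = piY = 0.5
        k1 = 2 * piA * piG / piR
        k2 = 2 * piT * piC / piY
        k3 = 2 * (piR * piY - piA * piG * piY / piR - piT * piC * piR / piY)
        P1 = P2 = 0.05
        Q = 0.02
        w1 = 1 - P1 / k1 - Q / (2 * piR)
        w2 = 1 - P2 / k2 - Q / (2 * piY)
        w3 = 1 - Q / (2 * piR * piY)
        expected = (
            k1 * (1 / w1 - 1) + k2 * (1 / w2 - 1) + k3 * (1 / w3 - 1)
        )
        assert tn93_distance(c, gamma_shape=1.0) == pytest.approx(expected, rel=1e-12)

    def test_large_alpha_converges_to_no_gamma(self):
        c = SitePatternCounts(200, 12, 9, 6, (120, 90, 80, 110))
        assert tn93_distance(c, gamma_shape=1e6) == pytest.approx(
            tn93_distance(c), abs=1e-6
        )

    def test_degenerate_frequencies_name_the_base(self):
        c = SitePatternCounts(10, 0, 0, 0, (10, 5, 0, 5))
        with pytest.raises(DegenerateFrequenciesError, match="G"):
            tn93_distance(c)

    def test_saturation_signalled_as_inf(self):
        c = SitePatternCounts(10, 4, 0, 4, (6, 4, 6, 4))
        assert math.isinf(tn93_distance(c))


class TestDistanceMatrix:
    def test_two_identical_sequences(self, tmp_path):
        from barcodedelim.seqio import Alignment, SequenceRecord

        aln = Alignment(
            [SequenceRecord(id="a", seq="ACGT"), SequenceRecord(id="b", seq="ACGT")]
        )
        dm = distance_matrix(aln, DistanceModelConfig(model="p"))
        assert np.array_equal(dm.data, np.zeros((2, 2)))

    def test_matrix_equals_pairwise_calls(self, three_lineage_sim):
        aln = three_lineage_sim.alignment.select(three_lineage_sim.alignment.ids[:5])
        cfg = DistanceModelConfig(model="k2p")
        dm = distance_matrix(aln, cfg)
        for i, a in enumerate(aln.records):
            for j, b in enumerate(aln.records):
                if i < j:
                    expected = k2p_distance(site_pattern_counts(a.seq, b.seq))
                    assert dm.data[i, j] == pytest.approx(expected)

    def test_symmetry_zero_diagonal_triangle(self, ten_lineage_sim):
        dm = distance_matrix(ten_lineage_sim.alignment, DistanceModelConfig())
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)
        # spot-check the triangle inequality on a few label triples; model-based
        # estimates can violate it by estimation noise, so allow a small slack
        rng = np.random.default_rng(0)
        n = len(dm.labels)
        for _ in range(50):
            i, j, k = rng.choice(n, size=3, replace=False)
            assert dm.data[i, j] <= dm.data[i, k] + dm.data[k, j] + 5e-3

    def test_saturated_pair_flagged(self):
        from barcodedelim.seqio import Alignment, SequenceRecord

        aln = Alignment(
            [
                SequenceRecord(id="a", seq="ACAC" * 10),
                SequenceRecord(id="b", seq="CACA" * 10),  # all transversions
                SequenceRecord(id="c", seq="ACAC" * 10),
            ]
        )
        dm = distance_matrix(aln, DistanceModelConfig(model="k2p"))
        assert ("a", "b") in dm.saturated_pairs
        assert math.isinf(dm[("a", "b")])
        assert dm[("a", "c")] == 0.0

    def test_no_comparable_sites_names_pair(self):
        from barcodedelim.seqio import Alignment, SequenceRecord

        aln = Alignment(
            [SequenceRecord(id="a", seq="AC--"), SequenceRecord(id="b", seq="--GT")]
        )
        with pytest.raises(NoComparableSitesError, match="'a' and 'b'"):
            distance_matrix(aln, DistanceModelConfig(model="p"))

    def test_tsv_roundtrip(self, tmp_path, three_lineage_sim):
        dm = distance_matrix(three_lineage_sim.alignment, DistanceModelConfig())
        path = tmp_path / "dm.tsv"
        dm.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == dm.labels
        assert np.allclose(back.data, dm.data)

    def test_phylip_export_shape(self, tmp_path, three_lineage_sim):
        dm = distance_matrix(three_lineage_sim.alignment, DistanceModelConfig())
        path = tmp_path / "dm.phy"
        dm.to_phylip(path)
        lines = path.read_text().splitlines()
        assert lines[0].strip() == str(len(dm.labels))
        assert len(lines) == len(dm.labels) + 1


class TestGroupDistanceSummary:
    def _dm(self, labels, data):
        return DistanceMatrix(labels, np.asarray(data, dtype=float),
                              DistanceModelConfig(model="p"))

    def test_two_singletons_between_equals_pairwise(self):
        dm = self._dm(["a", "b"], [[0, 0.3], [0.3, 0]])
        part = Partition({"a": "G1", "b": "G2"})
        df = group_distance_summary(dm, part)
        assert df.loc["G1", "G2"] == pytest.approx(0.3)
        assert np.isnan(df.loc["G1", "G1"])

    def test_within_mean_of_pair(self):
        dm = self._dm(["a", "b"], [[0, 0.02], [0.02, 0]])
        part = Partition({"a": "G", "b": "G"})
        within = group_distance_summary(dm, part, between=False)
        assert within["G"] == pytest.approx(0.02)

    def test_unassigned_label_errors(self):
        dm = self._dm(["a", "b"], [[0, 0.1], [0.1, 0]])
        with pytest.raises(KeyError, match="b"):
            group_distance_summary(dm, Partition({"a": "G"}))

    def test_planted_between_mean_near_target(self, ten_lineage_sim):
        sim = ten_lineage_sim
        dm = distance_matrix(sim.alignment, DistanceModelConfig(model="k2p"))
        df = grp = group_distance_summary(dm, sim.truth)
        off = df.to_numpy()[~np.eye(len(df), dtype=bool)]
        # K2P estimates of a 0.08-substitutions/site planted divergence
        assert abs(off.mean() - sim.config.inter_target) < 0.01
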