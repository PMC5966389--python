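import logging

import numpy as np
import pytest

from ncphmda import (
    AssociationNetwork,
    load_association_edgelist,
    load_symptom_counts,
    load_symptom_similarity,
    network_stats,
    write_association_edgelist,
    write_ranked_predictions,
)
from ncphmda.errors import AlignmentError, EdgeListFormatError, EmptyEdgeListError

from conftest import write_lines


class TestEdgeListLoading:
    def test_three_edges_build_expected_adjacency(self, tmp_path):
        p = write_lines(tmp_path / "e.tsv",
                        ["d1\tm1", "d1\tm2", "d2\tm1"])
        net = load_association_edgelist(p)
        assert net.diseases == ["d1", "d2"]
        assert net.microbes == ["m1", "m2"]
        np.testing.assert_array_equal(net.A, [[1, 1], [1, 0]])

    def test_duplicate_edges_collapse_with_warning(self, tmp_path, caplog):
        p = write_lines(tmp_path / "e.tsv",
                        ["d1\tm1", "d1\tm1", "d1\tm2", "d2\tm1"])
        with caplog.at_level(logging.WARNING):
            net = load_association_edgelist(p)
        np.testing.assert_array_equal(net.A, [[1, 1], [1, 0]])
        assert any("duplicate" in r.message for r in caplog.records)

    def test_header_and_comments_skipped(self, tmp_path):
        p = write_lines(tmp_path / "e.tsv",
                        ["# a comment", "disease\tmicrobe", "d1\tm1", "d2\tm2"])
        net = load_association_edgelist(p)
        assert net.n_associations == 2

    def test_labels_matched_case_insensitively(self, tmp_path):
        p = write_lines(tmp_path / "e.tsv",
                        ["Asthma\tm1", " asthma \tm2"])
        net = load_association_edgelist(p)
        assert net.diseases == ["Asthma"]
        assert net.n_associations == 2

    def test_lexicographic_order_option(self, tmp_path):
        p = write_lines(tmp_path / "e.tsv", ["zzz\tm2", "aaa\tm1"])
        net = load_association_edgelist(p, order="lex")
        assert net.diseases == ["aaa", "zzz"]

    def test_error_signals_are_distinct(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_association_edgelist(tmp_path / "nope.tsv")
        one_col = write_lines(tmp_path / "one.tsv", ["d1", "d2"])
        with pytest.raises(EdgeListFormatError):
            load_association_edgelist(one_col)
        empty = write_lines(tmp_path / "empty.tsv", ["#disease\tmicrobe"])
        with pytest.raises((EmptyEdgeListError, EdgeListFormatError)):
            load_association_edgelist(empty)

    def test_round_trip_preserves_adjacency(self, dense_net, tmp_path):
        p = tmp_path / "rt.tsv"
        write_association_edgelist(dense_net, p)
        back = load_association_edgelist(p)
        assert sorted(back.diseases) == sorted(dense_net.diseases)
        assert sorted(back.microbes) == sorted(dense_net.microbes)
        # adjacency identical once aligned by label
        ri = [back.diseases.index(d) for d in dense_net.diseases]
        rj = [back.microbes.index(m) for m in dense_net.microbes]
        np.testing.assert_array_equal(back.A[np.ix_(ri, rj)], dense_net.A)


class TestNetworkStats:
    def test_toy_counts_and_means(self, toy_net):
        s = network_stats(toy_net)
        assert s.n_associations == 3
        assert s.mean_microbe_degree == pytest.approx(1.5)
        assert s.mean_disease_degree == pytest.approx(1.5)
        assert s.microbe_degree_histogram == {1: 1, 2: 1}
        assert s.disease_degree_histogram == {1: 1, 2: 1}

    def test_means_times_counts_equal_edges(self, dense_net):
        s = network_stats(dense_net)
        assert s.mean_microbe_degree * s.n_microbes == pytest.approx(s.n_associations)
        assert s.mean_disease_degree * s.n_diseases == pytest.approx(s.n_associations)
        assert sum(s.microbe_degree_histogram.values()) == s.n_microbes
        assert sum(s.disease_degree_histogram.values()) == s.n_diseases

    def test_row_order_permutation_leaves_degree_stats_unchanged(self, tmp_path):
        lines = ["d1\tm1", "d1\tm2", "d2\tm1", "d3\tm3"]
        a = load_association_edgelist(write_lines(tmp_path / "a.tsv", lines))
        b = load_association_edgelist(write_lines(tmp_path / "b.tsv", lines[::-1]))
        sa, sb = network_stats(a), network_stats(b)
        assert sa.microbe_degree_histogram == sb.microbe_degree_histogram
        assert sa.disease_degree_histogram == sb.disease_degree_histogram
        assert sa.mean_disease_degree == sb.mean_disease_degree


class TestSymptomSimilarityLoading:
    def test_triples_fill_symmetrically_with_unit_diagonal(self, tmp_path):
        p = write_lines(tmp_path / "ss.tsv", ["d1\td2\t0.3"])
        ss = load_symptom_similarity(p)
        i, j = ss.labels.index("d1"), ss.labels.index("d2")
        assert ss.S[i, j] == ss.S[j, i] == 0.3
        assert ss.S[i, i] == ss.S[j, j] == 1.0
        assert ss.mask[i, j] and ss.mask[i, i]

    def test_unlisted_pairs_are_absent_not_zero(self, tmp_path):
        p = write_lines(tmp_path / "ss.tsv", ["d1\td2\t0.0", "d1\td3\t0.4"])
        ss = load_symptom_similarity(p)
        i, j, k = (ss.labels.index(x) for x in ("d1", "d2", "d3"))
        assert ss.mask[i, j]          # explicit zero counts as present
        assert not ss.mask[j, k]      # never listed

    def test_empty_file_gives_empty_matrix(self, tmp_path):
        p = write_lines(tmp_path / "ss.tsv", ["# nothing"])
        ss = load_symptom_similarity(p)
        assert ss.n == 0

    def test_score_outside_unit_interval_rejected(self, tmp_path):
        p = write_lines(tmp_path / "ss.tsv", ["d1\td2\t1.5"])
        with pytest.raises(ValueError):
            load_symptom_similarity(p)

    def test_self_pair_coerced_to_one_with_warning(self, tmp_path, caplog):
        p = write_lines(tmp_path / "ss.tsv", ["d1\td1\t0.7"])
        with caplog.at_level(logging.WARNING):
            ss = load_symptom_similarity(p)
        assert ss.S[0, 0] == 1.0
        with pytest.raises(ValueError):
            load_symptom_similarity(p, coerce=False)


class TestSymptomCountLoading:
    def test_long_format(self, tmp_path):
        p = write_lines(tmp_path / "w.tsv",
                        ["d1\ts1\t2", "d1\ts2\t1", "d2\ts1\t1"])
        prof = load_symptom_counts(p)
        np.testing.assert_array_equal(prof.W, [[2, 1], [1, 0]])

    def test_wide_format_equivalent_to_long(self, tmp_path):
        long = load_symptom_counts(write_lines(
            tmp_path / "l.tsv", ["d1\ts1\t2", "d1\ts2\t1", "d2\ts1\t1"]))
        wide = load_symptom_counts(write_lines(
            tmp_path / "w.tsv", ["disease\ts1\ts2", "d1\t2\t1", "d2\t1\t0"]))
        assert wide.diseases == long.diseases
        assert wide.symptoms == long.symptoms
        np.testing.assert_array_equal(wide.W, long.W)

    def test_negative_counts_rejected(self, tmp_path):
        p = write_lines(tmp_path / "n.tsv", ["d1\ts1\t-2"])
        with pytest.raises(ValueError):
            load_symptom_counts(p)

    def test_all_zero_disease_retained(self, tmp_path, caplog):
        p = write_lines(tmp_path / "z.tsv",
                        ["disease\ts1\ts2", "d1\t1\t0", "d2\t0\t0"])
        with caplog.at_level(logging.INFO):
            prof = load_symptom_counts(p)
        assert "d2" in prof.diseases
        assert any("all-zero" in r.message for r in caplog.records)


class TestRankedPredictions:
    def test_only_candidates_ranked_with_label_tiebreak(self, toy_net, tmp_path):
        scores = np.array([[0.9, 0.5], [0.4, 0.7]])
        out = tmp_path / "rank.tsv"
        write_ranked_predictions(scores, toy_net, out)
        rows = [l.split("\t") for l in out.read_text().splitlines()
                if l and not l.startswith(("#", "disease"))]
        d2 = [r for r in rows if r[0] == "d2"]
        assert [r[2] for r in d2 if r[4] == "0"] == ["m2"]
        assert [r[2] for r in d2 if r[4] == "1"] == ["m1"]
        d1 = [r for r in rows if r[0] == "d1" and r[4] == "0"]
        assert d1 == []  # both m1, m2 known for d1

    def test_ties_broken_by_microbe_label(self, tmp_path):
        net = AssociationNetwork(["d"], ["b", "a", "c"],
                                 np.zeros((1, 3)))
        out = tmp_path / "rank.tsv"
        write_ranked_predictions(np.array([[0.5, 0.5, 0.5]]), net, out)
        rows = [l.split("\t") for l in out.read_text().splitlines()[2:]]
        assert [r[2] for r in rows] == ["a", "b", "c"]

    def test_top_k_caps_candidate_rows(self, tmp_path):
        net = AssociationNetwork(["d"], [f"m{j}" for j in range(20)],
                                 np.zeros((1, 20)))
        out = tmp_path / "rank.tsv"
        rng = np.random.default_rng(0)
        write_ranked_predictions(rng.random((1, 20)), net, out, top_k=10)
        rows = [l for l in out.read_text().splitlines()[2:] if l]
        assert len(rows) == 10

    def test_shape_mismatch_rejected(self, toy_net, tmp_path):
        with pytest.raises(AlignmentError):
            write_ranked_predictions(np.zeros((3, 3)), toy_net,
                                     tmp_path / "x.tsv")
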