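"""Cosine distance, the five neighbor-selection cases, and batch prediction."""

import math

import numpy as np
import pytest

from _oracles import assert_selection_equivalent, oracle_select
from itsfunc.errors import (
    DegenerateVectorError,
    EmptyDatabaseError,
    FastaParseError,
    InvalidParameterError,
)
from itsfunc.kmers import KmerVector, count_kmers
from itsfunc.predict import (
    SelectionCase,
    cosine_distance,
    predict_batch,
    predict_profile,
    predict_records,
    predict_sequence,
    predictions_to_table,
    select_neighbors,
    write_prediction_table,
)

from conftest import make_db


def kv_from(freqs, k=1):
    freqs = np.asarray(freqs, dtype=float)
    return KmerVector(k=k, frequencies=freqs, valid_window_count=1)


class TestCosineDistance:
    def test_identical_is_zero(self):
        u = count_kmers("ACGTACGT", 3)
        assert cosine_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self):
        u = kv_from([1, 0, 0, 0])
        v = kv_from([0, 0, 1, 0])
        assert cosine_distance(u, v) == 1.0

    def test_hand_computed_value(self):
        # u=(1,0), v=(.5,.5): 1 - 0.5/(1 * sqrt(0.5)) = 1 - 1/sqrt(2)
        u = kv_from([1.0, 0.0, 0.0, 0.0])
        v = kv_from([0.5, 0.5, 0.0, 0.0])
        assert cosine_distance(u, v) == pytest.approx(1 - 1 / math.sqrt(2), abs=1e-12)

    def test_degenerate_vector_raises(self):
        u = kv_from([1, 0, 0, 0])
        z = KmerVector(k=1, frequencies=np.zeros(4), valid_window_count=0)
        with pytest.raises(DegenerateVectorError):
            cosine_distance(u, z)

    def test_k_mismatch_raises(self):
        with pytest.raises(InvalidParameterError):
            cosine_distance(kv_from(np.ones(4) / 4, k=1), kv_from(np.ones(16) / 16, k=2))


class TestSelectNeighbors:
    def test_exact_match_preempts_radius(self, tiny_db):
        # even with a wide radius, the exact gA match alone is used
        q = count_kmers("AAAAAA", 2)
        ns = select_neighbors(q, tiny_db, K=10, eps=0.999)
        assert ns.selection_case is SelectionCase.ZERO_DISTANCE_OVERRIDE
        assert [g for g, _ in ns.entries] == ["gA"]

    def test_case_rules_on_constructed_distances(self):
        # three RAVs at distances ~0.1, ~0.2, ~0.9 from the query
        db = make_db(
            entries=[("g1", "AAAAAAAAAC"), ("g2", "AAAAAAACAC"), ("g3", "CCCCCCCCCC")],
            profiles={g: [0.5, 0.5] for g in ("g1", "g2", "g3")},
            k=2,
        )
        q = count_kmers("AAAAAAAAAA", 2)
        ns = select_neighbors(q, db, K=10, eps=0.5)
        assert ns.selection_case is SelectionCase.FEWER_THAN_K
        assert [g for g, _ in ns.entries] == ["g1", "g2"]
        assert all(d <= 0.5 for _, d in ns.entries)

    def test_zero_distance_override_beats_eps_and_k(self, tiny_db):
        q = count_kmers("ACACAC", 2)  # identical to gM
        ns = select_neighbors(q, tiny_db, K=1, eps=0.01)
        assert ns.selection_case is SelectionCase.ZERO_DISTANCE_OVERRIDE
        assert [g for g, _ in ns.entries] == ["gM"]
        assert all(d <= 1e-12 for _, d in ns.entries)

    def test_override_keeps_all_zero_distance_ravs_even_above_k(self):
        db = make_db(
            entries=[("g1", "ACACAC"), ("g2", "ACACAC"), ("g3", "CCCCCC")],
            profiles={"g1": [1, 0], "g2": [0, 1], "g3": [0.5, 0.5]},
            k=2,
        )
        # g1 and g2 share the sequence -> both at distance 0
        q = count_kmers("ACACAC", 2)
        ns = select_neighbors(q, db, K=1, eps=0.5)
        assert ns.selection_case is SelectionCase.ZERO_DISTANCE_OVERRIDE
        assert [g for g, _ in ns.entries] == ["g1", "g2"]

    def test_empty_when_nothing_within_eps(self, tiny_db):
        q = count_kmers("GGGGGG", 2)
        ns = select_neighbors(q, tiny_db, K=10, eps=0.05)
        assert ns.selection_case is SelectionCase.EMPTY
        assert ns.k_chosen == 0

    def test_parameter_validation(self, tiny_db):
        q = count_kmers("AAAAAA", 2)
        with pytest.raises(InvalidParameterError):
            select_neighbors(q, tiny_db, K=0)
        with pytest.raises(InvalidParameterError):
            select_neighbors(q, tiny_db, eps=0.0)
        with pytest.raises(EmptyDatabaseError):
            tiny_db.subset([])


def random_instance(rng, n_ravs):
    """A random small database plus query over a 16-dim 2-mer space."""
    def seq(length):
        return "".join(rng.choice(list("ACGT"), size=length))
    entries, profiles = [], {}
    for i in range(n_ravs):
        gid = f"g{i:02d}"
        entries.append((gid, seq(rng.integers(6, 30))))
        profiles[gid] = np.array([0.3, 0.7])
    db = make_db(entries, profiles, k=2)
    query = count_kmers(seq(rng.integers(6, 30)), 2)
    K = int(rng.integers(1, 8))
    eps = float(rng.uniform(0.01, 1.0))
    return db, query, K, eps


def test_select_neighbors_matches_brute_force_oracle():
    """>=200 random small instances agree with the literal case-rule oracle."""
    rng = np.random.default_rng(2024)
    cases_seen = set()
    for _ in range(250):
        db, query, K, eps = random_instance(rng, int(rng.integers(1, 31)))
        ns = select_neighbors(query, db, K=K, eps=eps)
        rav_items = [(r.genome_id, r.kvector.frequencies) for r in db.ravs]
        expected_entries, expected_case = oracle_select(query.frequencies, rav_items, K, eps)
        assert ns.selection_case.value == expected_case
        assert_selection_equivalent(ns.entries, expected_entries)
        cases_seen.add(expected_case)
    assert {"EMPTY", "FEWER_THAN_K", "TRUNCATED_TO_K"} <= cases_seen


def test_permutation_invariance(sim_db):
    """Shuffling database record order never changes a prediction."""
    rng = np.random.default_rng(5)
    perm = rng.permutation(len(sim_db))
    shuffled = make_db(
        [(sim_db.ravs[i].genome_id, sim_db.ravs[i].sequence) for i in perm],
        {g: p for g, p in sim_db.profiles.items()},
        catalog=sim_db.catalog,
        k=sim_db.k,
    )
    query = "".join(rng.choice(list("ACGT"), size=300))
    p1 = predict_sequence(query, sim_db, K=5, eps=0.9)
    p2 = predict_sequence(query, shuffled, K=5, eps=0.9)
    assert p1.neighbor_set.entries == p2.neighbor_set.entries
    np.testing.assert_array_equal(p1.predicted, p2.predicted)


class TestPredictProfile:
    def test_single_neighbor_copies_profile(self, tiny_db):
        pred = predict_sequence("AAAAAA", tiny_db, K=10, eps=0.5)
        np.testing.assert_array_equal(pred.predicted, tiny_db.profiles["gA"])

    def test_mean_of_two_one_hot_profiles(self):
        db = make_db(
            entries=[("g1", "ACACAC"), ("g2", "ACACAC")],
            profiles={"g1": [1.0, 0.0], "g2": [0.0, 1.0]},
            k=2,
        )
        pred = predict_sequence("ACACAC", db)
        np.testing.assert_allclose(pred.predicted, [0.5, 0.5])

    def test_averaging_identical_profiles_is_idempotent(self):
        profile = [0.2, 0.3, 0.5]
        db = make_db(
            entries=[("g1", "AAAAAT"), ("g2", "AAAATA"), ("g3", "AAATAA")],
            profiles={g: profile for g in ("g1", "g2", "g3")},
            k=2,
        )
        pred = predict_sequence("AAAAAA", db, K=3, eps=0.9)
        assert pred.neighbor_set.k_chosen == 3
        np.testing.assert_allclose(pred.predicted, profile)

    def test_no_prediction_marker(self, tiny_db):
        q = count_kmers("GGGGGG", 2)
        ns = select_neighbors(q, tiny_db, eps=0.05)
        pred = predict_profile(ns, tiny_db)
        assert not pred.is_predicted
        assert pred.predicted is None


class TestPredictBatch:
    def test_exact_match_and_no_neighbor_together(self, tiny_db, tmp_path):
        fasta = tmp_path / "q.fasta"
        fasta.write_text(">hit\nACACAC\n>miss\nGGGGGG\n")
        predictions, table = predict_batch(fasta, tiny_db, K=10, eps=0.05)
        assert [p.query_id for p in predictions] == ["hit", "miss"]
        np.testing.assert_allclose(table["hit"].to_numpy(), tiny_db.profiles["gM"])
        assert table["miss"].isna().all()
        assert table.index.name == "function"
        assert list(table.index) == tiny_db.catalog

    def test_short_query_fails_alone(self, tiny_db):
        preds = predict_records([("tiny", "A"), ("ok", "ACACAC")], tiny_db)
        assert preds[0].error is not None and not preds[0].is_predicted
        assert preds[1].is_predicted

    def test_empty_query_file(self, tiny_db, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        predictions, table = predict_batch(fasta, tiny_db)
        assert predictions == [] and table.shape == (3, 0)

    def test_malformed_fasta_raises(self, tiny_db, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("this is not fasta\n")
        with pytest.raises(FastaParseError):
            predict_batch(bad, tiny_db)

    def test_table_tsv_format(self, tiny_db, tmp_path):
        preds = predict_records([("s1", "ACACAC"), ("s2", "GGGGGG")], tiny_db, eps=0.05)
        table = predictions_to_table(preds, tiny_db.catalog)
        out = tmp_path / "out.tsv"
        write_prediction_table(table, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["function", "s1", "s2"]
        assert lines[1].split("\t")[2] == "NA"


def test_epsilon_monotone_predicted_sets(sim_db):
    """Queries predicted at a small eps stay predicted at every larger eps."""
    rng = np.random.default_rng(11)
    records = [
        (f"q{i}", "".join(rng.choice(list("ACGT"), size=200))) for i in range(30)
    ]
    previous = set()
    for eps in (0.2, 0.4, 0.6, 0.8, 1.0):
        preds = predict_records(records, sim_db, K=10, eps=eps)
        predicted = {p.query_id for p in preds if p.is_predicted}
        assert previous <= predicted
        previous = predicted
    assert previous == {q for q, _ in records}  # eps=1 admits every RAV
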