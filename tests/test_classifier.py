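"""Read encoding, matrix scoring vs a brute-force oracle, weighting, and the
iterative classification loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import markovbin as mb
from markovbin.classify import _score_all, assignment_proportions
from conftest import random_toy_model


def brute_force_score(seq: str, model: mb.TransitionModel) -> float:
    """Independent per-read oracle: walk the read and sum -ln p step by step."""
    k = model.k
    M = model.as_matrix()
    total = 0.0
    for i in range(len(seq) - k):
        window = seq[i : i + k + 1]
        if not set(window) <= set("ACGT"):
            continue
        prefix = sum("ACGT".index(c) * 4 ** (k - 1 - j) for j, c in enumerate(window[:-1]))
        total += M[prefix, "ACGT".index(window[-1])]
    return total


class TestEncodeRead:
    def test_direct_enumeration(self):
        v = mb.encode_read(("r", "ACGTT"), k=1)
        idx = lambda w: "ACGT".index(w[0]) * 4 + "ACGT".index(w[1])
        assert v.n_valid == 4  # l - k
        for w in ("AC", "CG", "GT", "TT"):
            assert v.counts[idx(w)] == 1

    def test_minimal_length_read_single_step(self):
        v = mb.encode_read(("r", "ACGTTA"), k=5)
        assert v.n_valid == 1 and v.counts.sum() == 1

    def test_ambiguous_windows_skipped(self):
        v = mb.encode_read(("r", "ACNGT"), k=1)
        assert v.n_valid == 2  # AC and GT survive; windows with N drop

    def test_too_short_read_yields_zero_valid_not_error(self):
        v = mb.encode_read(("r", "ACG"), k=5)
        assert v.n_valid == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=3, max_size=120),
           k=st.integers(min_value=1, max_value=2))
    def test_n_valid_is_length_minus_k_for_clean_reads(self, seq, k):
        if len(seq) >= k + 1:
            assert mb.encode_read(("r", seq), k).n_valid == len(seq) - k


class TestRawScores:
    def test_read_from_homopolymer_model_scores_zero(self):
        model = mb.build_transition_model("A" * 50, 1, pseudocount=0.0, genome_id="h")
        db = mb.ReferenceDatabase(k=1, models=[model], lineages={"h": mb.TaxLineage()})
        S = mb.raw_scores([mb.encode_read(("r", "AAAAAA"), 1)], db)
        assert S.values[0, 0] == 0.0

    def test_uniform_model_gives_analytic_v_ln4(self, rng):
        # every transition at P = 1/4: score must be n_valid * ln 4
        seq = "".join(rng.choice(list("ACGT"), size=200))
        model = mb.build_transition_model(seq, 1, pseudocount=1e12, genome_id="u")
        db = mb.ReferenceDatabase(k=1, models=[model], lineages={"u": mb.TaxLineage()})
        read = "".join(rng.choice(list("ACGT"), size=80))
        v = mb.encode_read(("r", read), 1)
        S = mb.raw_scores([v], db)
        assert S.values[0, 0] == pytest.approx(v.n_valid * math.log(4), rel=1e-9)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matrix_product_matches_brute_force_oracle(self, k, rng):
        models = [random_toy_model(rng, k, f"m{i}") for i in range(5)]
        db = mb.ReferenceDatabase(
            k=k, models=models, lineages={m.genome_id: mb.TaxLineage() for m in models}
        )
        reads = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(50)]
        S = mb.raw_scores([mb.encode_read((f"r{i}", s), k) for i, s in enumerate(reads)], db)
        for i, seq in enumerate(reads):
            for j, model in enumerate(models):
                expected = brute_force_score(seq, model)
                assert S.values[i, j] == pytest.approx(expected, rel=1e-9)

    def test_k_mismatch_rejected(self, divergent_pair_db):
        with pytest.raises(ValueError, match="k="):
            mb.raw_scores([mb.encode_read(("r", "ACGTACGT"), 3)], divergent_pair_db)

    def test_column_shift_identity(self, rng):
        # adding a constant c to one genome's neglogp row shifts the weighted
        # score by exactly n_valid * c * (1 + omega_i)
        k, c = 2, 0.37
        model = random_toy_model(rng, k, "m0")
        shifted = mb.TransitionModel("m0", k, model.neglogp + c)
        db = mb.ReferenceDatabase(k=k, models=[model], lineages={"m0": mb.TaxLineage()})
        db2 = mb.ReferenceDatabase(k=k, models=[shifted], lineages={"m0": mb.TaxLineage()})
        v = mb.encode_read(("r", "".join(rng.choice(list("ACGT"), size=60))), k)
        w = mb.WeightVector(omega=np.array([-0.3]))
        s1 = mb.apply_weights(mb.raw_scores([v], db), w).values[0, 0]
        s2 = mb.apply_weights(mb.raw_scores([v], db2), w).values[0, 0]
        assert s2 - s1 == pytest.approx(v.n_valid * c * 0.7, rel=1e-9)


class TestWeighting:
    def _scores(self, values, n_valid=None):
        values = np.asarray(values, dtype=float)
        return mb.ScoreMatrix(
            read_ids=[f"r{i}" for i in range(values.shape[0])],
            genome_ids=[f"g{j}" for j in range(values.shape[1])],
            values=values,
            n_valid=np.asarray(n_valid if n_valid is not None else [1] * values.shape[0]),
        )

    def test_zero_weights_are_identity(self):
        S = self._scores([[1.0, 2.0], [3.0, 4.0]])
        out = mb.apply_weights(S, mb.WeightVector(omega=np.zeros(2)))
        assert np.array_equal(out.values, S.values)

    def test_columnwise_arithmetic(self):
        S = self._scores([[10.0, 10.0]])
        out = mb.apply_weights(S, mb.WeightVector(omega=np.array([-0.5, 0.0])))
        assert np.array_equal(out.values, [[5.0, 10.0]])

    def test_nonpositive_multiplier_rejected(self):
        S = self._scores([[1.0, 1.0]])
        with pytest.raises(ValueError, match="strictly positive"):
            mb.apply_weights(S, mb.WeightVector(omega=np.array([-1.0, 0.0])))

    def test_equal_raw_scores_resolve_to_more_abundant_genome(self):
        # abundance-weighted ties must break toward the larger proportion
        S = self._scores([[7.0, 7.0]])
        w = mb.update_weights(
            [mb.Assignment("a", "g0", 1.0, mb.TaxLineage())] * 9
            + [mb.Assignment("b", "g1", 1.0, mb.TaxLineage())],
            ["g0", "g1"],
            alpha=0.5,
        )
        weighted = mb.apply_weights(S, w)
        assert np.argmin(weighted.values[0]) == 0

    def test_update_weights_formula(self):
        mk = lambda g: mb.Assignment("r", g, 1.0, mb.TaxLineage())
        w = mb.update_weights([mk("g0")] * 9 + [mk("g1")], ["g0", "g1"], alpha=0.5)
        assert np.allclose(w.omega, [-0.45, -0.05])
        assert np.allclose(w.multipliers(), [0.55, 0.95])
        w_uni = mb.update_weights([mk(f"g{i}") for i in range(4)],
                                  [f"g{i}" for i in range(4)], alpha=0.5)
        assert np.allclose(w_uni.omega, [-0.125] * 4)

    def test_zero_classified_reads_error(self):
        un = mb.Assignment("r", mb.UNCLASSIFIED, float("nan"), mb.TaxLineage())
        with pytest.raises(ValueError, match="no classified reads"):
            mb.update_weights([un], ["g0"], alpha=0.5)


class TestBrayCurtis:
    def test_identity_disjoint_and_half(self):
        assert mb.bray_curtis([0.3, 0.7], [0.3, 0.7]) == 0.0
        assert mb.bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0
        assert mb.bray_curtis([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mb.bray_curtis([0.0, 0.0], [0.0, 0.0])


class TestAssign:
    def _db(self, ids):
        models = [mb.build_transition_model("ACGTACGTA", 1, 1.0, genome_id=g) for g in ids]
        return mb.ReferenceDatabase(k=1, models=models,
                                    lineages={g: mb.TaxLineage(species=g) for g in ids})

    def test_argmin_and_tie_rule(self):
        db = self._db(["g1", "g2", "g3"])
        S = mb.ScoreMatrix(["r1", "r2"], db.genome_ids,
                           np.array([[3.2, 1.1, 7.0], [1.0, 1.0, 2.0]]),
                           n_valid=np.array([5, 5]))
        out = mb.assign(S, db)
        assert out[0].genome_id == "g2"
        assert out[1].genome_id == "g1"  # exact tie -> first in canonical order

    def test_no_valid_window_is_unclassified(self):
        db = self._db(["g1"])
        S = mb.ScoreMatrix(["r"], db.genome_ids, np.array([[0.0]]), n_valid=np.array([0]))
        a = mb.assign(S, db)[0]
        assert a.genome_id == mb.UNCLASSIFIED and not a.classified


class TestClassifyLoop:
    def _community(self, genomes, props, n_reads, rate, seed):
        members = tuple(zip([g.genome_id for g in genomes], props))
        spec = mb.CommunitySpec(members=members, read_length=100, n_reads=n_reads,
                                substitution_rate=rate, seed=seed)
        return mb.simulate_reads(genomes, spec)

    def test_recovers_sources_between_divergent_genomes(self, divergent_pair,
                                                        divergent_pair_db):
        _, genomes = divergent_pair
        reads, truth = self._community(genomes, (0.5, 0.5), 1000, 0.0, seed=5)
        res = mb.classify(reads, divergent_pair_db)
        tmap = dict(zip(truth.read_id, truth.genome_id))
        frac = np.mean([a.genome_id == tmap[a.read_id] for a in res.assignments])
        assert frac >= 0.95

    def test_single_genome_database_trivially_converges(self, divergent_pair):
        lineages, genomes = divergent_pair
        db = mb.build_database(genomes[:1], lineages, k=5)
        reads, _ = self._community(genomes[:1], (1.0,), 50, 0.0, seed=8)
        res = mb.classify(reads, db)
        assert all(a.genome_id == genomes[0].genome_id for a in res.assignments)
        assert res.log["converged"] and res.log["iterations"] <= 2
        assert res.log["bc_trajectory"][-1] == 0.0

    def test_alpha_zero_equals_single_unweighted_pass(self, divergent_pair,
                                                      divergent_pair_db):
        _, genomes = divergent_pair
        reads, _ = self._community(genomes, (0.5, 0.5), 300, 0.0, seed=21)
        res = mb.classify(reads, divergent_pair_db,
                          mb.ClassifyConfig(alpha=0.0))
        # manual single unweighted pass
        vectors = [mb.encode_read(r, 5) for r in reads]
        from markovbin._kmers import reverse_complement
        rc = [mb.encode_read((rid, reverse_complement(s)), 5) for rid, s in reads]
        S = _score_all(vectors, rc, divergent_pair_db, 1000)
        manual = mb.assign(S, divergent_pair_db)
        assert [a.genome_id for a in res.assignments] == [a.genome_id for a in manual]
        assert [a.score for a in res.assignments] == [a.score for a in manual]

    def test_batch_size_invariance_bitwise(self, divergent_pair, divergent_pair_db):
        _, genomes = divergent_pair
        reads, _ = self._community(genomes, (0.7, 0.3), 200, 0.01, seed=2)
        results = [
            mb.classify(reads, divergent_pair_db, mb.ClassifyConfig(batch_size=b))
            for b in (1, 7, 1000)
        ]
        ref = results[0]
        for other in results[1:]:
            assert [a.genome_id for a in ref.assignments] == \
                   [a.genome_id for a in other.assignments]
            assert [a.score for a in ref.assignments] == \
                   [a.score for a in other.assignments]
            assert ref.log["bc_trajectory"] == other.log["bc_trajectory"]

    def test_skewed_community_estimate_tracks_truth(self, divergent_pair,
                                                    divergent_pair_db):
        _, genomes = divergent_pair
        reads, truth = self._community(genomes, (0.9, 0.1), 2000, 0.0, seed=17)
        res = mb.classify(reads, divergent_pair_db)
        q = assignment_proportions(res.assignments, divergent_pair_db.genome_ids)
        assert res.log["converged"] and res.log["iterations"] <= 20
        assert abs(q[0] - 0.9) <= 0.05 and abs(q[1] - 0.1) <= 0.05

    def test_empty_read_stream_rejected(self, divergent_pair_db):
        with pytest.raises(ValueError, match="empty read stream"):
            mb.classify([], divergent_pair_db)

    def test_both_strand_mode_recovers_reverse_reads(self, divergent_pair,
                                                     divergent_pair_db):
        # all-reverse-strand community: both-strand scoring must still recover
        _, genomes = divergent_pair
        spec = mb.CommunitySpec(
            members=(("p1.g1.s1", 1.0),), read_length=100, n_reads=200, seed=3
        )
        reads, truth = mb.simulate_reads(genomes, spec)
        res = mb.classify(reads, divergent_pair_db)
        frac = np.mean([a.genome_id == "p1.g1.s1" for a in res.assignments])
        assert frac >= 0.95
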