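"""Profile-HMM construction and local Viterbi search.

The central check is oracle equivalence: the vectorized local Viterbi
must equal an independent top-down enumeration of all alignment paths
(memoized recursion over the model definition), which is itself
validated against a fully explicit path generator on tiny models.
"""

from functools import lru_cache

import numpy as np
import pytest

from pepclust import msa as M
from pepclust import phmm as P
from pepclust.greedy import SequencePool
from pepclust.substitution import AMINO_ACIDS, blosum62_background
from tests.conftest import make_msa, make_unique, random_peptide

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_viterbi_score(hmm, seq):
    """Best local-path log-odds by top-down recursion over the model."""
    n, L = hmm.n_match, len(seq)
    x = [AMINO_ACIDS.index(c) for c in seq]
    mlo = hmm.match_log_odds
    lt = hmm._log_t()

    @lru_cache(maxsize=None)
    def f(state, k, pos):
        """Best suffix score entering `state` at slot k, `pos` consumed."""
        if state == "M":
            if pos >= L or k >= n:
                return -np.inf
            e = mlo[k, x[pos]]
            opts = [0.0]  # free exit from any match state
            if k < n - 1:
                opts.append(lt["mm"][k] + f("M", k + 1, pos + 1))
                opts.append(lt["mi"][k] + f("I", k, pos + 1))
                opts.append(lt["md"][k] + f("D", k + 1, pos + 1))
            return e + max(opts)
        if state == "I":
            if pos >= L or k >= n - 1:
                return -np.inf
            return max(lt["ii"][k] + f("I", k, pos + 1),
                       lt["im"][k] + f("M", k + 1, pos + 1))
        # D consumes nothing
        if k >= n:
            return -np.inf
        opts = [lt["dm"][k] + f("M", k + 1, pos)] if k < n - 1 else []
        if k < n - 1:
            opts.append(lt["dd"][k] + f("D", k + 1, pos))
        return max(opts) if opts else -np.inf

    return hmm.entry_log + max(f("M", k0, p0)
                               for k0 in range(n) for p0 in range(L))


def exhaustive_paths_score(hmm, seq):
    """Explicitly generate every complete local path (tiny models only)."""
    n, L = hmm.n_match, len(seq)
    x = [AMINO_ACIDS.index(c) for c in seq]
    mlo = hmm.match_log_odds
    lt = hmm._log_t()
    best = [-np.inf]

    def extend(state, k, pos, score):
        if state == "M":
            if pos >= L or k >= n:
                return
            score = score + mlo[k, x[pos]]
            best[0] = max(best[0], score)  # exit here
            if k < n - 1:
                extend("M", k + 1, pos + 1, score + lt["mm"][k])
                extend("I", k, pos + 1, score + lt["mi"][k])
                extend("D", k + 1, pos + 1, score + lt["md"][k])
        elif state == "I":
            if pos >= L or k >= n - 1:
                return
            extend("I", k, pos + 1, score + lt["ii"][k])
            extend("M", k + 1, pos + 1, score + lt["im"][k])
        else:
            if k >= n - 1:
                return
            extend("M", k + 1, pos, score + lt["dm"][k])
            extend("D", k + 1, pos, score + lt["dd"][k])

    for k0 in range(n):
        for p0 in range(L):
            extend("M", k0, p0, hmm.entry_log)
    return best[0]


def random_phmm(rng, n):
    """A random but valid model (Dirichlet emissions, random transitions)."""
    bg = blosum62_background()
    em = rng.dirichlet(np.full(20, 0.5), size=n)
    nt = max(n - 1, 1)

    def rdist(parts):
        d = rng.dirichlet(np.ones(parts), size=nt)
        return [d[:, i].copy() for i in range(parts)]

    t_mm, t_mi, t_md = rdist(3)
    t_im, t_ii = rdist(2)
    t_dm, t_dd = rdist(2)
    return P.ProfileHMM(n_match=n, match_emissions=em, insert_emissions=bg,
                        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im,
                        t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
                        match_column_map=list(range(n)), background=bg)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class TestBuildPhmm:
    def test_no_pseudocounts_gives_pure_frequencies(self):
        msa = make_msa("AAAA", "AAAA", "AAAA")
        hmm = P.build_phmm(msa, [0, 1, 2, 3], pseudocount_weight=0.0,
                           min_match=4)
        assert hmm.match_emissions[0, 0] == pytest.approx(1.0)
        assert hmm.match_emissions[0, 1:].sum() == pytest.approx(0.0)

    def test_uniform_pseudocount_formula(self, uniform_bg):
        n = 7
        msa = make_msa(*["AAAA"] * n)
        hmm = P.build_phmm(msa, [0, 1, 2, 3], pseudocount_weight=20.0,
                           background=uniform_bg, min_match=4)
        # P(A) = (n + 1) / (n + 20) with one pseudo-observation per residue
        assert hmm.match_emissions[0, 0] == pytest.approx((n + 1) / (n + 20))

    def test_distributions_normalized(self, rng):
        seqs = [random_peptide(rng, 6) for _ in range(8)]
        msa = make_msa(*set(seqs))
        hmm = P.build_phmm(msa, list(range(6)), min_match=4)
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(hmm.t_mm + hmm.t_mi + hmm.t_md, 1.0, atol=1e-9)
        assert np.allclose(hmm.t_im + hmm.t_ii, 1.0, atol=1e-9)
        assert np.allclose(hmm.t_dm + hmm.t_dd, 1.0, atol=1e-9)

    def test_too_few_match_columns_rejected(self):
        msa = make_msa("AAAA", "AAAA")
        with pytest.raises(ValueError, match="match columns"):
            P.build_phmm(msa, [0, 1, 2], min_match=4)

    def test_transitions_reflect_row_paths(self):
        # one row has an interior deletion at column 1
        msa = M.MSA([("ACD", "ACD"), ("AD", "A-D"), ("ACD", "ACD")])
        hmm = P.build_phmm(msa, [0, 1, 2], min_match=1)
        # M0->M1 twice, M0->D1 once, +1 pseudocount each over 3 types
        assert hmm.t_mm[0] == pytest.approx(3 / 6)
        assert hmm.t_md[0] == pytest.approx(2 / 6)
        assert hmm.t_mi[0] == pytest.approx(1 / 6)


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

class TestViterbiOracle:
    def test_exhaustive_validates_recursive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 4))
            hmm = random_phmm(rng, n)
            seq = random_peptide(rng, int(rng.integers(1, 5)))
            assert oracle_viterbi_score(hmm, seq) == pytest.approx(
                exhaustive_paths_score(hmm, seq), abs=1e-9)

    def test_viterbi_equals_path_enumeration(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 7))
            hmm = random_phmm(rng, n)
            seq = random_peptide(rng, int(rng.integers(1, 9)))
            hit = P.viterbi_local(hmm, seq)
            assert hit.bit_score == pytest.approx(
                oracle_viterbi_score(hmm, seq), abs=1e-9)

    def test_batch_scores_match_single(self, rng):
        hmm = random_phmm(rng, 5)
        seqs = [random_peptide(rng, int(rng.integers(3, 10)))
                for _ in range(30)]
        batch = P.score_sequences(hmm, seqs)
        for s, b in zip(seqs, batch):
            assert P.viterbi_local(hmm, s).bit_score == pytest.approx(b, abs=1e-9)

    def test_path_is_consistent_with_span_and_score(self, rng):
        for _ in range(40):
            hmm = random_phmm(rng, int(rng.integers(2, 7)))
            seq = random_peptide(rng, int(rng.integers(2, 9)))
            hit = P.viterbi_local(hmm, seq)
            consumed = [i for op, _, i in hit.path if i is not None]
            assert consumed == list(range(hit.span[0], hit.span[1]))
            assert hit.path[0][0] == "M" and hit.path[-1][0] == "M"
            # recompute the path's score from its ops
            lt = hmm._log_t()
            x = [AMINO_ACIDS.index(c) for c in seq]
            score = hmm.entry_log
            prev = None
            for op, k, i in hit.path:
                if prev is not None:
                    pop, pk = prev
                    score += lt[(pop + op).lower()][pk]
                if op == "M":
                    score += hmm.match_log_odds[k, x[i]]
                prev = (op, k)
            assert score == pytest.approx(hit.bit_score, abs=1e-9)


class TestViterbiClosedForms:
    def test_single_residue_closed_form(self, rng):
        hmm = random_phmm(rng, 5)
        for aa in "AWP":
            hit = P.viterbi_local(hmm, aa)
            expected = hmm.entry_log + max(
                hmm.match_log_odds[k, AMINO_ACIDS.index(aa)]
                for k in range(hmm.n_match))
            assert hit.bit_score == pytest.approx(expected)

    def test_identical_training_sequence_scores_all_match(self):
        msa = make_msa(*["ACDEF"] * 10)
        hmm = P.build_phmm(msa, list(range(5)), min_match=4)
        hit = P.viterbi_local(hmm, "ACDEF")
        assert [op for op, _, _ in hit.path] == ["M"] * 5
        assert hit.bit_score == pytest.approx(oracle_viterbi_score(hmm, "ACDEF"))

    def test_consensus_dominates_point_mutants(self, uniform_bg):
        msa = make_msa(*["ACDEF"] * 10)
        hmm = P.build_phmm(msa, list(range(5)), background=uniform_bg,
                           min_match=4)
        base = P.viterbi_local(hmm, "ACDEF").bit_score
        for pos, sub in [(0, "W"), (2, "G"), (4, "Y")]:
            mutant = "ACDEF"[:pos] + sub + "ACDEF"[pos + 1:]
            assert P.viterbi_local(hmm, mutant).bit_score <= base


class TestSearchPool:
    def _pool(self, seqs):
        pool = SequencePool()
        for s in seqs:
            pool.add(make_unique(s))
        return pool

    def test_empty_pool(self, rng):
        hmm = random_phmm(rng, 4)
        assert P.search_pool(hmm, self._pool([]), 0.0) == []

    def test_consensus_tops_the_hit_list(self):
        msa = make_msa(*["ACDEF"] * 10)
        hmm = P.build_phmm(msa, list(range(5)), min_match=4)
        pool = self._pool(["ACDEF", "ACDEW", "WYWYW"])
        hits = P.search_pool(hmm, pool, threshold=0.0)
        assert hits[0].sequence == "ACDEF"
        assert all(hits[i].bit_score >= hits[i + 1].bit_score
                   for i in range(len(hits) - 1))

    def test_planted_pool_separates_at_threshold(self):
        """A profile trained on fixed-offset motif carriers retrieves
        exactly the motif-bearing half of a mixed pool at a threshold
        placed in the score gap between the two populations."""
        from pepclust.synthetic import CLASS_I, generate_dataset
        train_occ, _ = generate_dataset([CLASS_I], [200], n_noise=0,
                                        length=10, seed=3, fixed_offset=1)
        msa = M.MSA([(o.sequence, o.sequence) for o in train_occ])
        cols = M.match_columns(msa)  # the planted anchor positions
        assert cols == [1, 4, 7]
        hmm = P.build_phmm(msa, cols, min_match=3)

        probe_occ, truth = generate_dataset([CLASS_I], [50], n_noise=50,
                                            length=10, seed=11)
        pool = self._pool([o.sequence for o in probe_occ])
        seqs = sorted(s.sequence for s in pool)
        scores = dict(zip(seqs, P.score_sequences(hmm, seqs)))
        motif_scores = [scores[s] for s in seqs if truth[s] == "class_I"]
        noise_scores = [scores[s] for s in seqs if truth[s] == "noise"]
        threshold = (max(noise_scores) + min(motif_scores)) / 2
        assert max(noise_scores) < min(motif_scores)  # a margin exists
        hits = {h.sequence
                for h in P.search_pool(hmm, pool, threshold, with_paths=False)}
        assert hits == {s for s in seqs if truth[s] == "class_I"}

    def test_distant_hits_superset_and_monotone(self, rng):
        hmm = random_phmm(rng, 4)
        seqs = [random_peptide(rng, 8) for _ in range(40)]
        pool = self._pool(seqs)
        hits = {h.sequence for h in P.search_pool(hmm, pool, 2.0,
                                                  with_paths=False)}
        distant = P.distant_hits(hmm, pool, 0.0)
        assert hits <= distant
        assert distant <= P.distant_hits(hmm, pool, -5.0)
        assert P.distant_hits(hmm, pool, -np.inf) == set(seqs)
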