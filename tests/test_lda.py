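"""Collapsed Gibbs sampler: conditionals, sweeps, estimates, matching."""

import itertools
import math

import numpy as np
import pytest

from aqsurveil.errors import EmptyInputError, InvalidConfigError
from aqsurveil.lda import (
    GibbsLDA,
    conditional_distribution,
    estimate_theta_phi,
    fit,
    gibbs_sweep,
    init_state,
    theta_threshold_match,
    top_words,
    topic_match,
)


def collapsed_log_joint(docs, z_by_doc, K, V, alpha, beta):
    """Independent oracle: log P(z, w) of the collapsed LDA joint.

    Product over documents of Dirichlet-multinomial terms in topic counts,
    times product over topics of Dirichlet-multinomial terms in word counts.
    Computed directly from gamma functions, recounting from scratch.
    """
    lg = math.lgamma
    total = 0.0
    n_kw = np.zeros((K, V), dtype=int)
    for doc, zs in zip(docs, z_by_doc):
        n_dk = np.zeros(K, dtype=int)
        for w, k in zip(doc, zs):
            n_dk[k] += 1
            n_kw[k, w] += 1
        total += lg(K * alpha) - lg(K * alpha + len(doc))
        for k in range(K):
            total += lg(alpha + n_dk[k]) - lg(alpha)
    for k in range(K):
        n_k = n_kw[k].sum()
        total += lg(V * beta) - lg(V * beta + n_k)
        for w in range(V):
            total += lg(beta + n_kw[k, w]) - lg(beta)
    return total


def oracle_conditional(docs, z_by_doc, K, V, alpha, beta, doc, pos):
    """Normalized ratio of collapsed joints over the K choices at (doc, pos)."""
    logs = []
    for k in range(K):
        z_mod = [list(zs) for zs in z_by_doc]
        z_mod[doc][pos] = k
        logs.append(collapsed_log_joint(docs, z_mod, K, V, alpha, beta))
    logs = np.array(logs)
    p = np.exp(logs - logs.max())
    return p / p.sum()


def state_from_assignment(docs, z_by_doc, K, V, alpha, beta):
    state = init_state(docs, K=K, alpha=alpha, beta=beta, seed=0, V=V)
    state.z = np.array(
        [k for zs in z_by_doc for k in zs], dtype=np.int32
    )
    state.n_dk, state.n_kw, state.n_k = state.recount()
    return state


class TestConditional:
    def test_single_topic_forced(self):
        state = init_state([[0, 1], [1]], K=1, alpha=1.0, beta=0.1, seed=0)
        assert conditional_distribution(state, 0, 1) == pytest.approx([1.0])

    def test_symmetric_two_topic_state(self):
        # five single-token docs of one word; the first four split 0,1,0,1.
        # Excluding the fifth token leaves identical counts for both topics.
        docs = [[0]] * 5
        z = [[0], [1], [0], [1], [0]]
        state = state_from_assignment(docs, z, 2, 2, 0.5, 0.5)
        np.testing.assert_allclose(
            conditional_distribution(state, 4, 0), [0.5, 0.5], atol=1e-14
        )

    def test_sums_to_one(self, rng):
        docs = [list(rng.integers(0, 5, size=6)) for _ in range(4)]
        state = init_state(docs, K=3, alpha=0.7, beta=0.05, seed=1)
        for d in range(4):
            for pos in range(6):
                assert conditional_distribution(state, d, pos).sum() == (
                    pytest.approx(1.0, abs=1e-12)
                )

    def test_matches_collapsed_joint_ratio_small_instance(self):
        """2-document, 6-token instance: every position's conditional equals
        the brute-force collapsed-joint ratio."""
        docs = [[0, 2, 1], [2, 2, 0]]
        K, V, alpha, beta = 2, 3, 0.8, 0.3
        for z_flat in itertools.product(range(K), repeat=6):
            z_by_doc = [list(z_flat[:3]), list(z_flat[3:])]
            state = state_from_assignment(docs, z_by_doc, K, V, alpha, beta)
            for d, doc in enumerate(docs):
                for pos in range(len(doc)):
                    expected = oracle_conditional(
                        docs, z_by_doc, K, V, alpha, beta, d, pos
                    )
                    got = conditional_distribution(state, d, pos)
                    np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_index_errors(self):
        state = init_state([[0, 1]], K=2, alpha=1.0, beta=0.1, seed=0)
        with pytest.raises(IndexError):
            conditional_distribution(state, 1, 0)
        with pytest.raises(IndexError):
            conditional_distribution(state, 0, 2)


class TestInitAndSweep:
    def test_single_topic_init(self):
        state = init_state([[0, 1, 2], [1]], K=1, alpha=1.0, beta=0.1, seed=0)
        assert (state.z == 0).all()
        assert state.n_k[0] == 4

    def test_same_seed_identical_state(self, rng):
        docs = [list(rng.integers(0, 8, size=5)) for _ in range(10)]
        a = init_state(docs, K=4, seed=7)
        b = init_state(docs, K=4, seed=7)
        np.testing.assert_array_equal(a.z, b.z)

    def test_init_counts_equal_recount(self, rng):
        docs = [list(rng.integers(0, 10, size=int(rng.integers(1, 8)))) for _ in range(10)]
        state = init_state(docs, K=3, seed=2)
        state.check_invariants()

    def test_sweep_preserves_invariants(self, rng):
        docs = [list(rng.integers(0, 6, size=5)) for _ in range(10)]
        state = init_state(docs, K=3, seed=3)
        for _ in range(5):
            gibbs_sweep(state)
            state.check_invariants()
        assert state.iteration == 5

    def test_single_topic_sweep_no_op(self):
        state = init_state([[0, 1], [2]], K=1, alpha=1.0, beta=0.1, seed=0)
        z_before = state.z.copy()
        gibbs_sweep(state)
        np.testing.assert_array_equal(state.z, z_before)
        assert state.iteration == 1

    def test_identical_seed_identical_trajectories(self, rng):
        docs = [list(rng.integers(0, 12, size=6)) for _ in range(20)]
        a = init_state(docs, K=3, seed=11)
        b = init_state(docs, K=3, seed=11)
        for _ in range(10):
            gibbs_sweep(a)
            gibbs_sweep(b)
            np.testing.assert_array_equal(a.z, b.z)

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            init_state([[0]], K=0, seed=0)
        with pytest.raises(InvalidConfigError):
            init_state([[0]], K=2, alpha=-1.0, seed=0)
        with pytest.raises(EmptyInputError):
            init_state([], K=2, seed=0)


class TestEstimates:
    def test_single_topic_theta_all_ones(self):
        state = init_state([[0, 1], [1, 1]], K=1, alpha=0.5, beta=0.1, seed=0)
        theta, phi = estimate_theta_phi(state)
        np.testing.assert_allclose(theta, 1.0)
        assert phi.shape == (1, 2)

    def test_empty_document_prior_only(self):
        state = init_state([[0, 1], []], K=4, alpha=0.5, beta=0.1, seed=0)
        theta, _ = estimate_theta_phi(state)
        np.testing.assert_allclose(theta[1], 0.25)

    def test_rows_sum_to_one_and_match_hand_formula(self, rng):
        docs = [list(rng.integers(0, 7, size=int(rng.integers(1, 9)))) for _ in range(8)]
        state = init_state(docs, K=3, alpha=0.4, beta=0.07, seed=5)
        gibbs_sweep(state)
        theta, phi = estimate_theta_phi(state)
        np.testing.assert_allclose(theta.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(phi.sum(axis=1), 1.0, atol=1e-9)
        for d, doc in enumerate(docs):
            for k in range(3):
                expected = (state.n_dk[d, k] + 0.4) / (len(doc) + 3 * 0.4)
                assert theta[d, k] == pytest.approx(expected, abs=1e-12)
        for k in range(3):
            for w in range(state.V):
                expected = (state.n_kw[k, w] + 0.07) / (state.n_k[k] + state.V * 0.07)
                assert phi[k, w] == pytest.approx(expected, abs=1e-12)


class TestMatching:
    def test_empty_document_never_matches(self):
        state = init_state([[0], []], K=2, seed=0)
        assert topic_match(state, 0, 1) is False
        assert topic_match(state, 1, 1) is False

    def test_single_topic_nonempty_matches(self):
        state = init_state([[0, 1]], K=1, alpha=1.0, beta=0.1, seed=0)
        assert topic_match(state, 0, 0) is True

    def test_token_criterion_equals_bruteforce_scan(self, rng):
        docs = [list(rng.integers(0, 9, size=int(rng.integers(1, 7)))) for _ in range(15)]
        state = init_state(docs, K=4, seed=9)
        gibbs_sweep(state)
        for d in range(len(docs)):
            span = state.z[state.docptr[d] : state.docptr[d + 1]]
            for k in range(4):
                assert topic_match(state, k, d) == bool((span == k).any())

    def test_theta_threshold_smoothing_floor_and_uniform(self):
        state = init_state([[0, 1, 2]], K=100, alpha=0.5, beta=0.1, seed=0)
        # tau=0: smoothing keeps every theta entry positive
        assert all(
            theta_threshold_match(state, k, 0, tau=0.0) for k in range(100)
        )
        # near-uniform row at K=100: every entry ~0.01 < 0.1
        assert not any(
            theta_threshold_match(state, k, 0, tau=0.1) for k in range(100)
        )

    def test_theta_threshold_strict_inequality_semantics(self, rng):
        docs = [list(rng.integers(0, 5, size=6)) for _ in range(6)]
        state = init_state(docs, K=3, alpha=0.3, beta=0.1, seed=4)
        gibbs_sweep(state)
        theta, _ = estimate_theta_phi(state)
        for d in range(6):
            for k in range(3):
                tau = float(theta[d, k])  # boundary: strict > must fail
                assert theta_threshold_match(state, k, d, tau=tau) is False
                assert theta_threshold_match(state, k, d, tau=tau - 1e-9)


class TestTopWords:
    def test_full_vocabulary_is_permutation(self, rng):
        docs = [list(rng.integers(0, 6, size=8)) for _ in range(5)]
        state = init_state(docs, K=2, seed=1)
        summary = top_words(state, 0, n=state.V)
        assert sorted(w for w, _ in summary.top_words) == sorted(
            state.vocab_symbols
        )

    def test_dominant_word_first(self):
        state = init_state([[2] * 20 + [0, 1]], K=1, alpha=1.0, beta=0.01, seed=0)
        assert top_words(state, 0, n=3).top_words[0][0] == "2"

    def test_equals_full_sort_oracle_with_tie_rule(self, rng):
        docs = [list(rng.integers(0, 10, size=7)) for _ in range(10)]
        state = init_state(docs, K=3, seed=6)
        gibbs_sweep(state)
        _, phi = estimate_theta_phi(state)
        for k in range(3):
            ranked = sorted(range(state.V), key=lambda w: (-phi[k, w], w))
            got = [w for w, _ in top_words(state, k, n=5).top_words]
            assert got == [state.vocab_symbols[w] for w in ranked[:5]]
        probs = [p for _, p in top_words(state, 0, n=state.V).top_words]
        assert all(a >= b for a, b in zip(probs, probs[1:]))


class TestFitAndSerialization:
    def test_zero_iters_returns_initial_state(self, rng):
        docs = [list(rng.integers(0, 5, size=4)) for _ in range(6)]
        fitted = fit(docs, K=2, iters=0, seed=3)
        initial = init_state(docs, K=2, seed=3)
        np.testing.assert_array_equal(fitted.z, initial.z)

    def test_save_load_identical_filter_decisions(self, tmp_path, rng):
        docs = [list(rng.integers(0, 8, size=6)) for _ in range(12)]
        state = fit(docs, K=3, iters=5, seed=2)
        path = tmp_path / "model.npz"
        state.save(path)
        loaded = type(state).load(path)
        np.testing.assert_array_equal(state.z, loaded.z)
        for d in range(12):
            for k in range(3):
                assert topic_match(state, k, d) == topic_match(loaded, k, d)
                assert theta_threshold_match(state, k, d) == (
                    theta_threshold_match(loaded, k, d)
                )
        assert state.fingerprint() == loaded.fingerprint()

    def test_document_permutation_permutes_outputs(self, rng):
        """Permuting document order (same seed) permutes per-document
        matching via id lookup: ids keep their decisions."""
        from aqsurveil.synthetic import generate_topic_corpus

        corpus, _ = generate_topic_corpus(40, 2, 30, seed=1)
        model = GibbsLDA(n_topics=2, n_iter=10, random_state=5).fit(corpus)
        decisions = {
            mid: topic_match(model.state_, 0, model.state_.doc_index(mid))
            for mid in model.state_.doc_ids
        }
        assert set(decisions) == set(corpus.ids)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        est = GibbsLDA(n_topics=7, n_iter=3, beta=0.2, random_state=1)
        params = est.get_params()
        clone = GibbsLDA(**params)
        assert clone.get_params() == params

    def test_fit_transform_shape(self, rng):
        docs = [list(rng.integers(0, 10, size=5)) for _ in range(9)]
        theta = GibbsLDA(n_topics=3, n_iter=4, random_state=0).fit_transform(docs)
        assert theta.shape == (9, 3)
        np.testing.assert_allclose(theta.sum(axis=1), 1.0, atol=1e-9)
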