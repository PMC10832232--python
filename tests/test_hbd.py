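"""Multi-class HBD hidden Markov model: emissions, transitions, decoding, EM."""

import itertools

import numpy as np
import pandas as pd
import pytest

from idstrat.data_io import MISSING, AlleleFrequencySet, GenotypeMatrix
from idstrat.hbd import (
    DEFAULT_RATES,
    HD_RATES,
    HBDDecoding,
    HBDModelSpec,
    em_fit,
    emission_probs,
    forward_backward,
    summarize_f_hbd,
    transition_matrix,
)


def _gm(dosages, morgan, chrom=None):
    dosages = np.atleast_2d(np.asarray(dosages))
    n, L = dosages.shape
    return GenotypeMatrix(
        dosages,
        [f"i{k}" for k in range(n)],
        pd.DataFrame(
            {
                "chrom": chrom if chrom is not None else ["1"] * L,
                "snp_id": [f"s{i}" for i in range(L)],
                "morgan": morgan,
                "bp": np.arange(1, L + 1),
                "a1": "A",
                "a2": "B",
            }
        ),
    )


def brute_force_loglik(dosages, morgan, p, spec, mixing):
    """Exhaustive sum over all state paths; the independent oracle."""
    S = spec.n_states
    state_col = [0] * spec.n_classes + [1]
    emis = np.array(
        [emission_probs(int(g), float(pp), spec.epsilon) for g, pp in zip(dosages, p)]
    )
    total = 0.0
    for path in itertools.product(range(S), repeat=len(dosages)):
        pr = mixing[path[0]] * emis[0, state_col[path[0]]]
        for t in range(1, len(dosages)):
            T = transition_matrix(morgan[t] - morgan[t - 1], spec, mixing)
            pr *= T[path[t - 1], path[t]] * emis[t, state_col[path[t]]]
        total += pr
    return np.log(total)


class TestEmissions:
    def test_heterozygote_impossible_in_hbd_without_error(self):
        for p in (0.1, 0.5, 0.9):
            assert emission_probs(1, p, 0.0)[0] == 0.0

    def test_missing_is_uninformative(self):
        np.testing.assert_allclose(emission_probs(MISSING, 0.3, 0.01), [1.0, 1.0])

    def test_stated_formulas_at_p_half(self):
        hbd, nonhbd = emission_probs(2, 0.5, 0.01)
        assert hbd == pytest.approx(0.99 * 0.5 + 0.01 * 0.25)
        assert nonhbd == pytest.approx(0.25)

    def test_frequency_bounds_enforced(self):
        with pytest.raises(ValueError):
            emission_probs(2, 0.0, 0.01)


class TestTransitions:
    def setup_method(self):
        self.spec = HBDModelSpec(rates=(2.0, 512.0), epsilon=0.0)
        self.M = np.array([0.3, 0.2, 0.5])

    def test_zero_distance_is_identity(self):
        np.testing.assert_allclose(
            transition_matrix(0.0, self.spec, self.M), np.eye(3)
        )

    def test_large_distance_forgets_state(self):
        T = transition_matrix(100.0, self.spec, self.M)
        for row in T:
            np.testing.assert_allclose(row, self.M, atol=1e-12)

    def test_hand_evaluated_stay_probability(self):
        spec = HBDModelSpec(rates=(2.0,), epsilon=0.0)
        T = transition_matrix(0.5, spec, np.array([0.5, 0.5]))
        expect = np.exp(-1.0) + (1 - np.exp(-1.0)) * 0.5
        assert T[0, 0] == pytest.approx(expect)

    def test_rows_are_stochastic(self):
        for d in (0.0, 0.01, 0.3, 5.0):
            T = transition_matrix(d, self.spec, self.M)
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(T >= 0)


class TestForwardBackward:
    def test_single_marker_heterozygote_has_zero_hbd_posterior(self):
        spec = HBDModelSpec(rates=(2.0,), epsilon=0.0, mixing=np.array([0.7, 0.3]))
        g = _gm([1], [0.0])
        dec = forward_backward(
            g, AlleleFrequencySet([0.5], "sample"), spec, store_posteriors=True
        )
        assert dec.posteriors[0, 0, 0] == 0.0

    def test_single_marker_bayes_by_hand(self):
        spec = HBDModelSpec(rates=(2.0,), epsilon=0.0, mixing=np.array([0.5, 0.5]))
        g = _gm([2], [0.0])
        dec = forward_backward(
            g, AlleleFrequencySet([0.5], "sample"), spec, store_posteriors=True
        )
        assert dec.posteriors[0, 0, 0] == pytest.approx(2.0 / 3.0)

    def test_loglik_matches_exhaustive_enumeration(self):
        """Scaled forward-backward equals the brute-force path sum to 1e-10
        on every fixture with <= 6 markers and <= 3 states."""
        rng = np.random.default_rng(12)
        cases = []
        for K in (1, 2):
            for L in (2, 4, 6):
                cases.append((K, L))
        for K, L in cases:
            rates = (4.0,) if K == 1 else (4.0, 64.0)
            mix = rng.dirichlet(np.ones(K + 1))
            spec = HBDModelSpec(rates=rates, epsilon=0.01, mixing=mix)
            dos = rng.integers(0, 3, size=L)
            dos[rng.uniform(size=L) < 0.2] = MISSING
            p = rng.uniform(0.2, 0.8, size=L)
            morgan = np.sort(rng.uniform(0, 0.5, size=L))
            g = _gm(dos, morgan)
            dec = forward_backward(g, AlleleFrequencySet(p, "sample"), spec)
            oracle = brute_force_loglik(dos, morgan, p, spec, mix)
            assert abs(dec.loglik[0] - oracle) < 1e-10

    def test_numba_and_numpy_paths_agree(self):
        rng = np.random.default_rng(13)
        L = 40
        dos = rng.integers(0, 3, size=(5, L))
        p = rng.uniform(0.1, 0.9, size=L)
        morgan = np.sort(rng.uniform(0, 1, size=L))
        g = _gm(dos, morgan)
        af = AlleleFrequencySet(p, "sample")
        spec = HBDModelSpec()
        d1 = forward_backward(g, af, spec, store_posteriors=True, use_numba=True)
        d2 = forward_backward(g, af, spec, store_posteriors=True, use_numba=False)
        np.testing.assert_allclose(d1.loglik, d2.loglik, atol=1e-12)
        np.testing.assert_allclose(d1.posteriors, d2.posteriors, atol=1e-12)

    def test_posteriors_sum_to_one(self, small_analysis):
        g = small_analysis["genotypes"].subset_markers(np.arange(200))
        af = AlleleFrequencySet(
            small_analysis["founder_af"].frequencies[:200], "founder_estimated"
        )
        dec = forward_backward(g, af, HBDModelSpec(), store_posteriors=True)
        np.testing.assert_allclose(dec.posteriors.sum(axis=2), 1.0, atol=1e-9)

    def test_chromosome_order_invariance(self):
        rng = np.random.default_rng(14)
        L = 60
        chrom = ["1"] * 30 + ["2"] * 30
        dos = rng.integers(0, 3, size=(4, L))
        p = rng.uniform(0.1, 0.9, size=L)
        morgan = np.concatenate(
            [np.sort(rng.uniform(0, 1, 30)), np.sort(rng.uniform(0, 1, 30))]
        )
        g = _gm(dos, morgan, chrom=chrom)
        af = AlleleFrequencySet(p, "sample")
        spec = HBDModelSpec()
        dec = forward_backward(g, af, spec)
        # swap the two chromosome blocks
        order = np.concatenate([np.arange(30, 60), np.arange(30)])
        g_sw = _gm(dos[:, order], morgan[order], chrom=["2"] * 30 + ["1"] * 30)
        dec_sw = forward_backward(g_sw, AlleleFrequencySet(p[order], "sample"), spec)
        np.testing.assert_allclose(dec.loglik, dec_sw.loglik, atol=1e-10)
        np.testing.assert_allclose(dec.f_hbd, dec_sw.f_hbd, atol=1e-12)

    def test_unsorted_map_rejected_at_container(self):
        with pytest.raises(ValueError, match="Morgan"):
            _gm([0, 1, 2], [0.3, 0.1, 0.2])


class TestEM:
    def test_all_heterozygous_drives_hbd_mixing_to_zero(self):
        L = 30
        g = _gm(np.ones((1, L), dtype=int), np.linspace(0, 1, L))
        af = AlleleFrequencySet(np.full(L, 0.5), "sample")
        spec = HBDModelSpec(rates=(4.0, 64.0), epsilon=0.0)
        fitted, dec = em_fit(g, af, spec, tol=1e-9, max_iter=500)
        assert fitted.mixing[0, :2].sum() < 1e-6
        assert dec.f_hbd[0] < 1e-6

    def test_loglik_never_decreases(self, small_analysis):
        g = small_analysis["genotypes"].subset_markers(np.arange(400))
        af = AlleleFrequencySet(
            small_analysis["sample_af"].frequencies[:400], "sample"
        )
        _, dec, hist = em_fit(
            g, af, HBDModelSpec(), tol=1e-6, max_iter=60, return_history=True
        )
        assert np.all(np.diff(hist, axis=1) > -1e-9)

    def test_mixing_recovery_from_model_simulated_data(self):
        """Data generated from the HMM itself (K = 2, known M) give back the
        mixing proportions within Monte-Carlo error over 200 individuals."""
        rng = np.random.default_rng(15)
        K = 2
        rates = (2.0, 16.0)  # ~10+ markers per segment even in the fast class
        M_true = np.array([0.25, 0.15, 0.60])
        spec = HBDModelSpec(rates=rates, epsilon=0.002)
        L = 1000
        morgan = np.linspace(0, 5.0, L)
        p = rng.uniform(0.2, 0.8, size=L)
        state_rates = spec.state_rates
        n = 200
        dosages = np.empty((n, L), dtype=np.int8)
        for i in range(n):
            s = rng.choice(3, p=M_true)
            for t in range(L):
                if t > 0:
                    d = morgan[t] - morgan[t - 1]
                    if rng.uniform() > np.exp(-state_rates[s] * d):
                        s = rng.choice(3, p=M_true)
                pt = p[t]
                if s < K:  # HBD: draw one allele, duplicate, then error
                    geno = 2 * (rng.uniform() < pt)
                else:
                    geno = (rng.uniform() < pt) + (rng.uniform() < pt)
                if rng.uniform() < spec.epsilon:
                    geno = (rng.uniform() < pt) + (rng.uniform() < pt)
                dosages[i, t] = geno
        g = _gm(dosages, morgan)
        af = AlleleFrequencySet(p, "sample")
        fitted, dec = em_fit(g, af, spec, tol=1e-6, max_iter=500)
        m_hat = fitted.mixing.mean(axis=0)
        se = fitted.mixing.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(m_hat - M_true) < 3 * se + 0.02)

    def test_max_iter_flagged_not_fatal(self):
        rng = np.random.default_rng(16)
        L = 50
        g = _gm(rng.integers(0, 3, size=(2, L)), np.linspace(0, 1, L))
        af = AlleleFrequencySet(rng.uniform(0.3, 0.7, L), "sample")
        _, dec = em_fit(g, af, HBDModelSpec(), tol=1e-12, max_iter=3)
        assert dec.n_em_iterations == 3
        assert not dec.converged


class TestSummaries:
    def test_degenerate_posterior_cases(self):
        spec = HBDModelSpec()  # 9 classes + non-HBD, cut-off 256
        K = spec.n_classes
        per_class = np.zeros((1, K))
        per_class[0, 0] = 1.0
        dec = HBDDecoding(
            f_hbd_per_class=per_class, f_hbd=np.zeros(1), loglik=np.zeros(1)
        )
        agg, pc = summarize_f_hbd(dec, spec)
        assert agg[0] == pytest.approx(1.0)

    def test_uniform_posterior_arithmetic(self):
        """Uniform posteriors over the 10 states: each class holds 0.1 of the
        genome and the R_c <= 256 aggregate spans 8 of the 9 HBD classes."""
        spec = HBDModelSpec()
        per_class = np.full((1, spec.n_classes), 0.1)
        dec = HBDDecoding(
            f_hbd_per_class=per_class, f_hbd=np.zeros(1), loglik=np.zeros(1)
        )
        agg, _ = summarize_f_hbd(dec, spec)
        assert agg[0] == pytest.approx(0.8)

    def test_default_and_hd_rate_ladders(self):
        assert DEFAULT_RATES == tuple(2.0 ** k for k in range(1, 10))
        assert HD_RATES == tuple(2.0 ** k for k in range(1, 12))
        assert len(DEFAULT_RATES) == 9 and len(HD_RATES) == 11

    def test_per_class_truth_correlation_recent_classes(self, small_analysis):
        """Posterior class fractions track the gene-drop truth for the recent
        classes (R_c <= 16), where segments are long and well covered."""
        pop = small_analysis["pop"]
        spec = small_analysis["spec"]
        dec = small_analysis["dec_founder"]
        truth = pop.truth_class_fractions(np.asarray(spec.rates))
        truth = truth.loc[small_analysis["genotypes"].sample_ids]
        # pool classes 2..16 (individually sparse at this scale)
        rates = np.asarray(spec.rates)
        recent = rates <= 16
        est = dec.f_hbd_per_class[:, recent].sum(axis=1)
        tru = truth.to_numpy()[:, recent].sum(axis=1)
        assert np.corrcoef(est, tru)[0, 1] > 0.8
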