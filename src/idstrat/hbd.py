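"""Multi-class homozygous-by-descent (HBD) hidden Markov model.

The genome of an individual is modelled as a mosaic of HBD and non-HBD
segments.  K HBD classes are defined; in class c segment lengths are
exponential with rate R_c per Morgan (expected length 1/R_c), so classes
correspond to groups of ancestors roughly 0.5 * R_c generations in the past.
One non-HBD class completes the state space; it shares the rate of the last
(fastest) HBD class.  Upon leaving a segment the chain enters class c' with
the individual's mixing probability M_c', which is also the initial
distribution at chromosome starts; the M vector is estimated per individual
by Baum-Welch EM with the rates held fixed.

Emissions compare the observed genotype with what an HBD segment allows:
inside HBD only homozygotes are possible up to a genotyping-error rate
epsilon, outside HBD genotypes follow Hardy-Weinberg at the marker's allele
frequency.  Missing genotypes emit likelihood 1 in both states.

The per-class genome fractions F_HBD-c are the unweighted means over markers
of the class posteriors; the aggregate F_HBD sums the classes with
R_c <= aggregate_max_rate (the last class behaves more like a single-site
estimator, so it is excluded by default).

This is the single-level multi-class mixture formulation (one Markov chain
over K+1 states with exit-to-mixing transitions), not a nested-layer
recursion over successive ancestor generations; the two parameterisations
summarise into the same per-class genome fractions.

Numerics: underflow is controlled by per-marker scaling, the log-likelihood
recovered exactly from the scale accumulators.  The forward-backward runs in
a compiled kernel (numba) over all individuals of a chromosome at once; a
pure-numpy reference implementation is kept and compared in the tests.
Because each individual's EM problem is independent, individuals whose
log-likelihood gain has dropped below tolerance are frozen and removed from
subsequent iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_io import MISSING, AlleleFrequencySet, GenotypeMatrix

DEFAULT_RATES = tuple(float(2 ** k) for k in range(1, 10))   # 2 .. 512, 9 classes
HD_RATES = tuple(float(2 ** k) for k in range(1, 12))        # 2 .. 2048, 11 classes
DEFAULT_AGGREGATE_MAX_RATE = 256.0
DEFAULT_EPSILON = 0.0025

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@dataclass
class HBDModelSpec:
    """Rates, mixing proportions and error rate of the multi-class HBD model.

    ``rates`` lists the K HBD class rates (strictly increasing); the non-HBD
    state implicitly carries the last rate.  ``mixing`` is a simplex over the
    K+1 states, either one shared vector or one row per individual.
    """

    rates: tuple[float, ...] = DEFAULT_RATES
    epsilon: float = DEFAULT_EPSILON
    aggregate_max_rate: float = DEFAULT_AGGREGATE_MAX_RATE
    mixing: np.ndarray | None = None  # (K+1,) or (n, K+1); None = uniform

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if len(r) < 1 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("rates must be positive and strictly increasing")
        if not 0 <= self.epsilon <= 0.1:
            raise ValueError("epsilon must lie in [0, 0.1]")
        if self.mixing is not None:
            m = np.atleast_2d(np.asarray(self.mixing, dtype=float))
            if m.shape[-1] != self.n_states:
                raise ValueError("mixing must have K+1 entries per row")
            if np.any(m < 0) or not np.allclose(m.sum(axis=-1), 1.0):
                raise ValueError("mixing rows must be simplexes")

    @property
    def n_classes(self) -> int:
        return len(self.rates)

    @property
    def n_states(self) -> int:
        return len(self.rates) + 1

    @property
    def state_rates(self) -> np.ndarray:
        """Exit rate per state; the non-HBD state shares the last HBD rate."""
        r = np.asarray(self.rates, dtype=float)
        return np.append(r, r[-1])

    def mixing_for(self, n: int) -> np.ndarray:
        """Per-individual mixing matrix (n, K+1), broadcasting the default."""
        if self.mixing is None:
            return np.full((n, self.n_states), 1.0 / self.n_states)
        m = np.atleast_2d(np.asarray(self.mixing, dtype=float))
        if m.shape[0] == 1:
            return np.repeat(m, n, axis=0)
        if m.shape[0] != n:
            raise ValueError("mixing rows do not match number of individuals")
        return m.copy()


@dataclass
class HBDDecoding:
    """Posterior summaries of one decoding run.

    ``f_hbd_per_class`` is an (n, K) matrix of genome fractions; ``f_hbd``
    the aggregate over classes with R_c <= aggregate_max_rate; ``loglik``
    per individual (chromosomes add).  ``posteriors`` (n, L, K+1) is only
    filled when requested — it is large.
    """

    f_hbd_per_class: np.ndarray
    f_hbd: np.ndarray
    loglik: np.ndarray
    n_em_iterations: int = 0
    converged: bool = True
    posteriors: np.ndarray | None = None


def emission_probs(genotype: int, p: float, epsilon: float) -> np.ndarray:
    """Emission likelihood (HBD, non-HBD) of one genotype at A1 frequency p.

    HBD:      P(2) = (1-e) p + e p^2,  P(1) = e 2p(1-p),  P(0) = (1-e)(1-p) + e (1-p)^2
    non-HBD:  Hardy-Weinberg p^2, 2p(1-p), (1-p)^2
    Missing genotypes return (1, 1): no information about the state.
    """
    if not 0 < p < 1:
        raise ValueError("allele frequency must lie strictly inside (0,1)")
    if genotype == MISSING:
        return np.array([1.0, 1.0])
    q = 1.0 - p
    e = epsilon
    hbd = {2: (1 - e) * p + e * p * p, 1: e * 2 * p * q, 0: (1 - e) * q + e * q * q}
    nonhbd = {2: p * p, 1: 2 * p * q, 0: q * q}
    return np.array([hbd[genotype], nonhbd[genotype]])


def _emission_table(dosages: np.ndarray, p: np.ndarray, epsilon: float) -> np.ndarray:
    """(n, L, 2) emission likelihoods (HBD, non-HBD) for a dosage matrix."""
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly inside (0,1)")
    q = 1.0 - p
    e = epsilon
    hbd_by_geno = np.stack(
        [(1 - e) * q + e * q * q, e * 2 * p * q, (1 - e) * p + e * p * p]
    )  # genotype 0,1,2
    nonhbd_by_geno = np.stack([q * q, 2 * p * q, p * p])
    n, L = dosages.shape
    out = np.ones((n, L, 2))
    for geno in (0, 1, 2):
        mask = dosages == geno
        out[..., 0] = np.where(mask, hbd_by_geno[geno][None, :], out[..., 0])
        out[..., 1] = np.where(mask, nonhbd_by_geno[geno][None, :], out[..., 1])
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite emission likelihoods")
    return out


def transition_matrix(d: float, spec: HBDModelSpec, mixing: np.ndarray) -> np.ndarray:
    """(K+1)x(K+1) transition matrix over a map distance of d Morgan.

    T[c, c'] = exp(-R_c d) [c == c'] + (1 - exp(-R_c d)) M_c'.
    """
    if d < 0:
        raise ValueError("map distance must be >= 0")
    mixing = np.asarray(mixing, dtype=float)
    stay = np.exp(-spec.state_rates * d)
    return np.diag(stay) + (1.0 - stay)[:, None] * mixing[None, :]


def _chromosome_blocks(markers: pd.DataFrame) -> list[np.ndarray]:
    """Column index blocks, one per chromosome, in file order."""
    blocks = []
    chrom = markers["chrom"].to_numpy()
    start = 0
    for j in range(1, len(chrom) + 1):
        if j == len(chrom) or chrom[j] != chrom[start]:
            blocks.append(np.arange(start, j))
            start = j
    return blocks


def _block_state_emissions(
    dosages_block: np.ndarray, p_block: np.ndarray, spec: HBDModelSpec
) -> np.ndarray:
    """(Lc, n, S) per-state emission likelihoods for one chromosome block."""
    emis = _emission_table(dosages_block, p_block, spec.epsilon)  # (n, Lc, 2)
    state_col = np.array([0] * spec.n_classes + [1])
    return np.ascontiguousarray(emis[:, :, state_col].transpose(1, 0, 2))


@njit(cache=False)
def _fb_kernel(e_state, dists, rates, M, collect, store):  # pragma: no cover
    """Scaled forward-backward for one chromosome over a batch of individuals.

    e_state: (Lc, n, S); dists: (Lc-1,) Morgan gaps; rates: (S,) exit rates;
    M: (n, S) mixing.  Returns per-individual loglik, summed posteriors,
    expected class-entry counts (chromosome start + after exits) and, when
    ``store``, the full posterior block (n, Lc, S).
    """
    Lc, n, S = e_state.shape
    alpha = np.empty((Lc, n, S))
    scale = np.empty((Lc, n))
    loglik = np.zeros(n)
    for i in range(n):
        s = 0.0
        for k in range(S):
            a = M[i, k] * e_state[0, i, k]
            alpha[0, i, k] = a
            s += a
        if s <= 0.0:
            raise ValueError("zero likelihood at chromosome start")
        scale[0, i] = s
        for k in range(S):
            alpha[0, i, k] /= s
    stay = np.empty((Lc - 1, S))
    for t in range(Lc - 1):
        for k in range(S):
            stay[t, k] = np.exp(-rates[k] * dists[t])
    for t in range(1, Lc):
        for i in range(n):
            ex = 0.0
            for k in range(S):
                ex += alpha[t - 1, i, k] * (1.0 - stay[t - 1, k])
            s = 0.0
            for k in range(S):
                a = (alpha[t - 1, i, k] * stay[t - 1, k] + ex * M[i, k]) * e_state[t, i, k]
                alpha[t, i, k] = a
                s += a
            if s <= 0.0:
                raise ValueError("zero likelihood during forward pass")
            scale[t, i] = s
            for k in range(S):
                alpha[t, i, k] /= s
    for t in range(Lc):
        for i in range(n):
            loglik[i] += np.log(scale[t, i])
    post_sum = np.zeros((n, S))
    entry = np.zeros((n, S))
    if store:
        posts = np.empty((n, Lc, S))
    else:
        posts = np.empty((1, 1, 1))
    beta = np.ones((n, S))
    for i in range(n):
        for k in range(S):
            g = alpha[Lc - 1, i, k]
            post_sum[i, k] += g
            if store:
                posts[i, Lc - 1, k] = g
    bb = np.empty(S)
    for t in range(Lc - 2, -1, -1):
        for i in range(n):
            reentry = 0.0
            sexit = 0.0
            for k in range(S):
                bbk = e_state[t + 1, i, k] * beta[i, k] / scale[t + 1, i]
                bb[k] = bbk
                reentry += M[i, k] * bbk
                sexit += alpha[t, i, k] * (1.0 - stay[t, k])
            for k in range(S):
                if collect:
                    entry[i, k] += sexit * M[i, k] * bb[k]
                beta[i, k] = stay[t, k] * bb[k] + (1.0 - stay[t, k]) * reentry
                g = alpha[t, i, k] * beta[i, k]
                post_sum[i, k] += g
                if store:
                    posts[i, t, k] = g
    if collect:
        for i in range(n):
            for k in range(S):
                entry[i, k] += alpha[0, i, k] * beta[i, k]
    return loglik, post_sum, entry, posts


def _fb_numpy(e_state, dists, rates, M, collect, store):
    """Pure-numpy reference for :func:`_fb_kernel`, same contract."""
    Lc, n, S = e_state.shape
    alpha = np.empty((Lc, n, S))
    scale = np.empty((Lc, n))
    a = M * e_state[0]
    c0 = a.sum(axis=1)
    if np.any(c0 <= 0):
        raise ValueError("zero likelihood at chromosome start")
    alpha[0] = a / c0[:, None]
    scale[0] = c0
    stay = np.exp(-rates[None, :] * dists[:, None])  # (Lc-1, S)
    for t in range(1, Lc):
        st = stay[t - 1]
        prev = alpha[t - 1]
        exit_mass = prev @ (1.0 - st)
        pred = prev * st[None, :] + exit_mass[:, None] * M
        a = pred * e_state[t]
        ct = a.sum(axis=1)
        if np.any(ct <= 0):
            raise ValueError("zero likelihood during forward pass")
        alpha[t] = a / ct[:, None]
        scale[t] = ct
    loglik = np.log(scale).sum(axis=0)

    beta = np.ones((n, S))
    post_sum = np.zeros((n, S))
    entry = np.zeros((n, S))
    posts = np.empty((n, Lc, S)) if store else None
    gamma = alpha[Lc - 1] * beta
    post_sum += gamma
    if store:
        posts[:, Lc - 1, :] = gamma
    for t in range(Lc - 2, -1, -1):
        st = stay[t]
        bb = e_state[t + 1] * beta / scale[t + 1][:, None]
        if collect:
            s_exit = alpha[t] @ (1.0 - st)
            entry += s_exit[:, None] * M * bb
        reentry = (M * bb).sum(axis=1)
        beta = st[None, :] * bb + (1.0 - st)[None, :] * reentry[:, None]
        gamma = alpha[t] * beta
        post_sum += gamma
        if store:
            posts[:, t, :] = gamma
    if collect:
        entry += alpha[0] * beta
    return loglik, post_sum, entry, posts


def _fb_dispatch(e_state, dists, rates, M, collect, store, use_numba=True):
    if use_numba and _HAVE_NUMBA:
        ll, ps, en, pb = _fb_kernel(
            e_state, dists, rates, np.ascontiguousarray(M), collect, store
        )
        return ll, ps, en, (pb if store else None)
    return _fb_numpy(e_state, dists, rates, M, collect, store)


def forward_backward(
    g: GenotypeMatrix,
    af: AlleleFrequencySet,
    spec: HBDModelSpec,
    store_posteriors: bool = False,
    use_numba: bool = True,
) -> HBDDecoding:
    """Posterior decode all individuals under fixed mixing proportions."""
    M = spec.mixing_for(g.n_samples)
    blocks = _chromosome_blocks(g.markers)
    morgan = g.markers["morgan"].to_numpy(float)
    n, L, S = g.n_samples, g.n_markers, spec.n_states
    loglik = np.zeros(n)
    post_sum = np.zeros((n, S))
    posts = np.empty((n, L, S)) if store_posteriors else None
    rates = spec.state_rates
    for cols in blocks:
        d = np.diff(morgan[cols])
        if np.any(d < 0):
            raise ValueError("markers not sorted by Morgan position within chromosome")
        e_state = _block_state_emissions(
            g.dosages[:, cols], af.frequencies[cols], spec
        )
        ll, ps, _, pb = _fb_dispatch(e_state, d, rates, M, False, store_posteriors,
                                     use_numba)
        loglik += ll
        post_sum += ps
        if store_posteriors:
            posts[:, cols, :] = pb
    per_class = post_sum[:, : spec.n_classes] / L
    agg = per_class[:, np.asarray(spec.rates) <= spec.aggregate_max_rate].sum(axis=1)
    return HBDDecoding(
        f_hbd_per_class=per_class, f_hbd=agg, loglik=loglik, posteriors=posts
    )


def em_fit(
    g: GenotypeMatrix,
    af: AlleleFrequencySet,
    spec: HBDModelSpec,
    tol: float = 1e-6,
    max_iter: int = 1000,
    store_posteriors: bool = False,
    return_history: bool = False,
    use_numba: bool = True,
):
    """Baum-Welch estimation of the per-individual mixing proportions.

    Rates stay fixed; only M is updated, from the expected state occupancies
    at chromosome starts plus the expected class entries after segment exits.
    An individual is frozen once its log-likelihood gain drops below ``tol``
    (its EM is independent of everyone else's); the fit stops when all are
    frozen or at ``max_iter`` (flagged, results still returned).

    Returns (fitted spec, decoding) and optionally the per-iteration
    log-likelihood history (n, n_iter), padded with the final value for
    individuals that converged early.
    """
    M = spec.mixing_for(g.n_samples)
    blocks = _chromosome_blocks(g.markers)
    morgan = g.markers["morgan"].to_numpy(float)
    n, S = g.n_samples, spec.n_states
    rates = spec.state_rates

    e_blocks = []
    dist_blocks = []
    for cols in blocks:
        d = np.diff(morgan[cols])
        if np.any(d < 0):
            raise ValueError("markers not sorted by Morgan position within chromosome")
        e_blocks.append(
            _block_state_emissions(g.dosages[:, cols], af.frequencies[cols], spec)
        )
        dist_blocks.append(d)

    history: list[np.ndarray] = []
    prev_ll = np.full(n, -np.inf)
    active = np.arange(n)
    it = 0
    while it < max_iter and len(active):
        it += 1
        loglik_a = np.zeros(len(active))
        entries = np.zeros((len(active), S))
        Ma = M[active]
        for e_state, d in zip(e_blocks, dist_blocks):
            ll, _, en, _ = _fb_dispatch(
                np.ascontiguousarray(e_state[:, active, :]), d, rates, Ma,
                True, False, use_numba,
            )
            loglik_a += ll
            entries += en
        if not np.all(np.isfinite(loglik_a)):
            raise ValueError("non-finite log-likelihood in EM")
        ll_full = prev_ll.copy()
        ll_full[active] = loglik_a
        history.append(ll_full)
        gain = loglik_a - prev_ll[active]
        prev_ll[active] = loglik_a
        total = entries.sum(axis=1, keepdims=True)
        M[active] = np.where(total > 0, entries / total, Ma)
        active = active[gain >= tol]
    converged = len(active) == 0

    fitted = replace(spec, mixing=M)
    dec = forward_backward(g, af, fitted, store_posteriors=store_posteriors,
                           use_numba=use_numba)
    dec.n_em_iterations = it
    dec.converged = converged
    if return_history:
        # frozen individuals repeat their final log-likelihood, keeping rows monotone
        hist = np.array(history).T if history else np.zeros((n, 0))
        return fitted, dec, hist
    return fitted, dec


def summarize_f_hbd(dec: HBDDecoding, spec: HBDModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """(aggregate F_HBD, per-class F_HBD-c) from a decoding.

    The aggregate sums the classes with R_c <= aggregate_max_rate; with the
    default nine classes and a 256 cut-off that is eight of the nine.
    """
    rates = np.asarray(spec.rates)
    agg = dec.f_hbd_per_class[:, rates <= spec.aggregate_max_rate].sum(axis=1)
    return agg, dec.f_hbd_per_class


def decode_table(
    g: GenotypeMatrix,
    af: AlleleFrequencySet,
    spec: HBDModelSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[pd.DataFrame, HBDModelSpec]:
    """Fit and decode every individual; tabulate F_HBD and the class fractions."""
    spec = spec or HBDModelSpec()
    fitted, dec = em_fit(g, af, spec, tol=tol, max_iter=max_iter)
    cols = {f"f_hbd_R{int(r)}": dec.f_hbd_per_class[:, k]
            for k, r in enumerate(spec.rates)}
    df = pd.DataFrame(
        {"id": g.sample_ids, "f_hbd": dec.f_hbd, **cols,
         "loglik": dec.loglik, "n_iter": dec.n_em_iterations}
    )
    return df, fitted
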