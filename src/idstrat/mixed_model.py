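"""REML linear mixed models for inbreeding depression.

The single-coefficient model regresses a trait deviation on one inbreeding
coefficient, y_i = mu + u_i + b F_i + e_i with polygenic effects
u ~ N(0, G sigma_g^2), and the stratified model fits the genome fractions of
all age-related HBD classes simultaneously, y_i = mu + u_i + sum_c b_c
F_HBD-c,i + e_i.  The relationship matrix G is chosen to match the fitted
estimator (pedigree A, VanRaden 1 or 2, or the allele-frequency-0.5
similarity matrix).

Variance components are estimated by restricted maximum likelihood profiled
down to one dimension: after an eigendecomposition of G the covariance is
diagonal in the rotated basis, V = sigma_p^2 (h2 L + (1-h2) I), and the REML
log-likelihood is maximised over h2 by bounded scalar search.  This is exact
for a single relationship matrix and needs no iterative solver.  Fixed
effects come from GLS at the optimum; Wald p-values use the normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .estimators import GRM_FLAVOR_FOR_ESTIMATOR

_H2_EPS = 1e-6


@dataclass
class REMLWorkspace:
    """Eigendecomposition of G plus rotated responses, reusable across fits
    that share the same relationship matrix (e.g. simulation replicates)."""

    eigvals: np.ndarray
    rot: np.ndarray  # U', applied to y and X

    @classmethod
    def from_grm(cls, G: np.ndarray, ridge: float = 1e-6) -> "REMLWorkspace":
        G = np.asarray(G, dtype=float)
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        w, U = np.linalg.eigh(G)
        if w.min() < -1e-8:
            w = w + (ridge - w.min())
        w = np.maximum(w, 0.0)
        return cls(eigvals=w, rot=U.T)


@dataclass
class IDFit:
    """Result of one mixed-model fit.

    ``b`` holds the fixed-effect estimates (intercept first), with matching
    standard errors, two-sided Wald p-values and 95% confidence bounds;
    ``term_names`` labels them.  Variance components are on the phenotypic
    scale.
    """

    b: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    term_names: list[str]
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    n_used: int
    converged: bool
    dropped_terms: list[str] = field(default_factory=list)

    def effect(self, name: str) -> tuple[float, float, float]:
        k = self.term_names.index(name)
        return self.b[k], self.se[k], self.p_values[k]


def _reml_negloglik(h2: float, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    """Profiled REML -loglik at heritability h2; returns (nll, beta, XtVX_inv, s2)."""
    n, p = Xr.shape
    w = h2 * lam + (1.0 - h2)
    wi = 1.0 / w
    XtWX = Xr.T @ (Xr * wi[:, None])
    XtWy = Xr.T @ (yr * wi)
    try:
        XtWX_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    beta = XtWX_inv @ XtWy
    resid = yr - Xr @ beta
    rss = float(resid @ (resid * wi))
    if rss <= 0:
        return np.inf, beta, XtWX_inv, 0.0
    s2 = rss / (n - p)
    _, logdet_xx = np.linalg.slogdet(XtWX)
    nll = 0.5 * ((n - p) * np.log(s2) + np.log(w).sum() + logdet_xx + (n - p))
    return nll, beta, XtWX_inv, s2


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray | None = None,
    workspace: REMLWorkspace | None = None,
    term_names: list[str] | None = None,
) -> IDFit:
    """REML fit of y = X beta + u + e with u ~ N(0, G sigma_g^2).

    Either a relationship matrix or a precomputed :class:`REMLWorkspace` must
    be given.  Raises on rank-deficient X, naming the aliased columns; a
    constant y returns a degenerate zero fit rather than an error.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    if n < p + 2:
        raise ValueError("not enough observations for the model")
    term_names = term_names or [f"x{k}" for k in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify aliased columns by greedy QR-style elimination
        keep: list[int] = []
        for j in range(p):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
        aliased = [term_names[j] for j in range(p) if j not in keep]
        raise ValueError(f"design matrix rank-deficient; aliased columns: {aliased}")

    if workspace is None:
        if G is None:
            raise ValueError("either G or a workspace is required")
        workspace = REMLWorkspace.from_grm(G)
    lam = workspace.eigvals
    yr = workspace.rot @ y
    Xr = workspace.rot @ X

    if np.var(y) == 0:
        zeros = np.zeros(p)
        b = zeros.copy()
        b[0] = y[0]
        return IDFit(
            b=b, se=zeros, p_values=np.ones(p), ci_low=b, ci_high=b,
            term_names=term_names, sigma_g2=0.0, sigma_e2=0.0, h2=0.0,
            loglik=0.0, n_used=n, converged=True,
        )

    res = optimize.minimize_scalar(
        lambda h: _reml_negloglik(h, lam, yr, Xr)[0],
        bounds=(0.0, 1.0 - _H2_EPS),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    nll, beta, XtWX_inv, s2 = _reml_negloglik(h2, lam, yr, Xr)
    converged = bool(res.success) and np.isfinite(nll)
    se = np.sqrt(np.maximum(np.diag(XtWX_inv) * s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return IDFit(
        b=beta,
        se=se,
        p_values=pvals,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        term_names=term_names,
        sigma_g2=h2 * s2,
        sigma_e2=(1.0 - h2) * s2,
        h2=h2,
        loglik=-nll,
        n_used=n,
        converged=converged,
    )


def fit_id_single(
    y: np.ndarray,
    f: np.ndarray,
    G: np.ndarray | None = None,
    estimator: str | None = None,
    grm_flavor: str | None = None,
    workspace: REMLWorkspace | None = None,
) -> IDFit:
    """Single-coefficient inbreeding-depression fit: X = [1, F].

    When ``estimator`` and ``grm_flavor`` are both given, the pairing is
    checked against the convention used throughout the pipeline (pedigree A
    with f_ped; VanRaden 1 with f_uni/f_grm1; VanRaden 2 with f_grm2; the
    AF=0.5 similarity matrix with f_het/f_hbd).
    """
    if estimator is not None and grm_flavor is not None:
        expected = GRM_FLAVOR_FOR_ESTIMATOR.get(estimator)
        if expected is None:
            raise ValueError(f"unknown estimator {estimator!r}")
        if grm_flavor != expected:
            raise ValueError(
                f"{estimator} must be fitted with {expected}, got {grm_flavor}"
            )
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite inbreeding coefficients")
    if np.var(f) == 0:
        raise ValueError("design matrix rank-deficient; aliased columns: ['f']")
    X = np.column_stack([np.ones_like(f), f])
    return reml_fit(y, X, G=G, workspace=workspace, term_names=["intercept", "f"])


def fit_id_stratified(
    y: np.ndarray,
    f_classes: np.ndarray,
    G: np.ndarray | None = None,
    class_names: list[str] | None = None,
    workspace: REMLWorkspace | None = None,
    var_floor: float = 1e-12,
) -> IDFit:
    """Stratified fit: X = [1, F_HBD-1 .. F_HBD-C], one coefficient per class.

    Class columns with variance below ``var_floor`` (or collinear with the
    columns already kept) are dropped and reported in ``dropped_terms``.
    """
    F = np.asarray(f_classes, dtype=float)
    n, C = F.shape
    class_names = class_names or [f"class{k + 1}" for k in range(C)]
    keep = [k for k in range(C) if np.var(F[:, k]) > var_floor]
    X = np.column_stack([np.ones(n)] + [F[:, k] for k in keep])
    # drop columns that are collinear with earlier ones
    cols = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, cols + [j]]) > len(cols):
            cols.append(j)
    kept = [keep[j - 1] for j in cols[1:]]
    dropped = [class_names[k] for k in range(C) if k not in kept]
    X = np.column_stack([np.ones(n)] + [F[:, k] for k in kept])
    names = ["intercept"] + [class_names[k] for k in kept]
    fit = reml_fit(y, X, G=G, workspace=workspace, term_names=names)
    fit.dropped_terms = dropped
    return fit


def significance_threshold(n_tests: int, fwer: float = 0.05) -> tuple[float, float]:
    """Bonferroni threshold: exact value and the value at two significant figures."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    exact = fwer / n_tests
    if exact == 0:
        return 0.0, 0.0
    from math import floor, log10
    digits = -int(floor(log10(abs(exact)))) + 1
    return exact, round(exact, digits)
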