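"""Pedigree and marker-based inbreeding coefficients and relationship matrices.

Six estimators are used downstream: F_PED (pedigree, Meuwissen-Luo), F_HET
(excess homozygosity), F_UNI (correlation of uniting gametes), F_GRM-1 and
F_GRM-2 (VanRaden diagonal rules), and F_HBD (HMM, computed in
:mod:`idstrat.hbd`).  The genomic estimators depend on the allele-frequency
source (sample vs base population), which is why every function takes an
explicit :class:`AlleleFrequencySet`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import MISSING, AlleleFrequencySet, GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pedigree inbreeding: Meuwissen & Luo recursion
# ---------------------------------------------------------------------------

def f_ped(ped: Pedigree) -> np.ndarray:
    """Pedigree inbreeding coefficients by the Meuwissen-Luo algorithm.

    Founders have F = 0; F of a non-founder is the kinship of its parents,
    computed through the L (Cholesky-of-A) decomposition without ever forming
    the full relationship matrix.  O(n * ancestors^2) but exact.
    """
    sire, dam = ped.parent_indices()
    n = ped.n
    f = np.zeros(n)
    D = np.empty(n)  # Mendelian sampling variance, d_ii of A = T D T'
    for i in range(n):
        s, d = sire[i], dam[i]
        D[i] = 0.5 - 0.25 * (
            (f[s] if s >= 0 else -1.0) + (f[d] if d >= 0 else -1.0)
        )
        if s < 0 or d < 0:
            f[i] = 0.0  # an individual with an unknown parent cannot be inbred
            continue
        # a_ii = sum_j L_ij^2 D_j over the ancestors of i; F_i = a_ii - 1
        L: dict[int, float] = {i: 1.0}
        a_ii = 0.0
        for j in range(i, -1, -1):
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            a_ii += lj * lj * D[j]
            if sire[j] >= 0:
                L[sire[j]] = L.get(sire[j], 0.0) + 0.5 * lj
            if dam[j] >= 0:
                L[dam[j]] = L.get(dam[j], 0.0) + 0.5 * lj
        f[i] = a_ii - 1.0
    return f


def _fped_slow(ped: Pedigree) -> np.ndarray:
    """Reference pedigree F via the tabular relationship matrix (O(n^2) memory)."""
    A = relationship_matrix_pedigree(ped)
    return np.diag(A) - 1.0


# ---------------------------------------------------------------------------
# Marker-based estimators
# ---------------------------------------------------------------------------

def _checked(g: GenotypeMatrix, af: AlleleFrequencySet) -> tuple[np.ndarray, np.ndarray]:
    if len(af) != g.n_markers:
        raise ValueError("AF length does not match marker count")
    return g.dosages, af.frequencies


def f_het(g: GenotypeMatrix, af: AlleleFrequencySet) -> np.ndarray:
    """Excess-homozygosity inbreeding: F = (O_hom - E_hom) / (L_used - E_hom).

    E_hom sums 1 - 2 p (1 - p) over the individual's non-missing markers; this
    is the method-of-moments estimator behind PLINK's --het output.
    """
    d, p = _checked(g, af)
    obs = d != MISSING
    hom = obs & (d != 1)
    e_marker = 1.0 - 2.0 * p * (1.0 - p)
    e_hom = obs @ e_marker
    l_used = obs.sum(axis=1).astype(float)
    denom = l_used - e_hom
    if np.any(np.abs(denom) < 1e-12):
        bad = [g.sample_ids[i] for i in np.flatnonzero(np.abs(denom) < 1e-12)]
        raise ValueError(f"degenerate excess-homozygosity denominator for {bad[:5]}")
    return (hom.sum(axis=1) - e_hom) / denom


def f_uni(g: GenotypeMatrix, af: AlleleFrequencySet) -> np.ndarray:
    """Correlation-of-uniting-gametes inbreeding (GCTA's third estimator):

    F = mean over non-missing markers of
        [x^2 - (1 + 2p) x + 2 p^2] / (2 p (1 - p)).
    """
    d, p = _checked(g, af)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic marker reached f_uni; filter by MAF first")
    obs = d != MISSING
    x = np.where(obs, d, 0).astype(float)
    num = x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p
    term = np.where(obs, num / (2.0 * p * (1.0 - p)), 0.0)
    l_used = obs.sum(axis=1)
    if np.any(l_used == 0):
        raise ValueError("individual with no genotypes")
    return term.sum(axis=1) / l_used


def f_grm(g: GenotypeMatrix, af: AlleleFrequencySet, rule: int) -> np.ndarray:
    """VanRaden diagonal inbreeding.

    rule 1: F = sum (x - 2p)^2 / sum 2p(1-p) - 1   (ratio of sums)
    rule 2: F = mean (x - 2p)^2 / (2p(1-p)) - 1    (mean of ratios)

    Both sums run over the individual's non-missing markers.
    """
    if rule not in (1, 2):
        raise ValueError("rule must be 1 or 2")
    d, p = _checked(g, af)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic marker reached f_grm; filter by MAF first")
    obs = d != MISSING
    x = np.where(obs, d, 0).astype(float)
    sq = np.where(obs, (x - 2.0 * p) ** 2, 0.0)
    het = 2.0 * p * (1.0 - p)
    if rule == 1:
        denom = obs @ het
        return sq.sum(axis=1) / denom - 1.0
    ratio = np.where(obs, sq / het, 0.0)
    return ratio.sum(axis=1) / obs.sum(axis=1) - 1.0


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

def relationship_matrix_pedigree(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method."""
    sire, dam = ped.parent_indices()
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def build_relationship_matrix(
    flavor: str,
    g: GenotypeMatrix | None = None,
    af: AlleleFrequencySet | None = None,
    ped: Pedigree | None = None,
    sample_ids: list[str] | None = None,
) -> np.ndarray:
    """Relationship matrix for the mixed model, one of four flavors.

    vanraden1:            G = Z Z' / sum 2p(1-p), Z = X - 2p
    vanraden2:            G_ij = mean_l z_il z_jl / (2 p_l (1 - p_l))
    half_freq_similarity: vanraden1 evaluated at p = 0.5, G = (X-1)(X-1)'/(L/2)
    pedigree_A:           tabular numerator relationship matrix, optionally
                          subset to ``sample_ids``

    Missing dosages are mean-imputed at 2p for matrix construction only.
    """
    if flavor == "pedigree_A":
        if ped is None:
            raise ValueError("pedigree_A needs a pedigree")
        A = relationship_matrix_pedigree(ped)
        if sample_ids is not None:
            pos = {iid: k for k, iid in enumerate(ped.ids)}
            idx = np.array([pos[i] for i in sample_ids])
            A = A[np.ix_(idx, idx)]
        return A

    if g is None:
        raise ValueError(f"{flavor} needs genotypes")
    d = g.dosages
    L = g.n_markers
    if flavor == "half_freq_similarity":
        p = np.full(L, 0.5)
    else:
        if af is None:
            raise ValueError(f"{flavor} needs allele frequencies")
        p = af.frequencies
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("monomorphic marker in GRM construction")
    missing = d == MISSING
    if missing.any():
        logger.info("mean-imputing %d missing dosages at 2p for GRM", missing.sum())
    x = np.where(missing, 2.0 * p, d).astype(float)
    z = x - 2.0 * p
    het = 2.0 * p * (1.0 - p)
    if flavor in ("vanraden1", "half_freq_similarity"):
        return (z @ z.T) / het.sum()
    if flavor == "vanraden2":
        zw = z / het
        return (zw @ z.T) / L
    raise ValueError(f"unknown relationship-matrix flavor {flavor!r}")


# estimator -> relationship-matrix flavor used in the ID mixed model
GRM_FLAVOR_FOR_ESTIMATOR = {
    "f_ped": "pedigree_A",
    "f_uni": "vanraden1",
    "f_grm1": "vanraden1",
    "f_grm2": "vanraden2",
    "f_het": "half_freq_similarity",
    "f_hbd": "half_freq_similarity",
}


# ---------------------------------------------------------------------------
# Tables and trends
# ---------------------------------------------------------------------------

def inbreeding_table(
    g: GenotypeMatrix,
    af: AlleleFrequencySet,
    ped: Pedigree | None = None,
    f_hbd: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-individual table of the estimators computable from the inputs."""
    out = pd.DataFrame(index=pd.Index(g.sample_ids, name="id"))
    if ped is not None:
        fp = pd.Series(f_ped(ped), index=ped.ids)
        out["f_ped"] = fp.reindex(g.sample_ids).to_numpy()
    out["f_het"] = f_het(g, af)
    out["f_uni"] = f_uni(g, af)
    out["f_grm1"] = f_grm(g, af, rule=1)
    out["f_grm2"] = f_grm(g, af, rule=2)
    if f_hbd is not None:
        out["f_hbd"] = np.asarray(f_hbd, float)
    out["af_source"] = af.source
    return out


def annual_trend(table: pd.DataFrame, ped: Pedigree) -> pd.DataFrame:
    """Slope of yearly mean inbreeding on birth year, per estimator column.

    Ordinary least squares on the yearly means; reported in F per year and
    as a percentage.  Raises if fewer than two distinct birth years.
    """
    years = ped.records.set_index("id")["birth_year"].reindex(table.index)
    f_cols = [c for c in table.columns if c.startswith("f_")]
    merged = table[f_cols].assign(birth_year=years.to_numpy())
    yearly = merged.groupby("birth_year").mean()
    if len(yearly) < 2:
        raise ValueError("annual trend needs at least two distinct birth years")
    rows = []
    for col in f_cols:
        res = sps.linregress(yearly.index.to_numpy(float), yearly[col].to_numpy())
        rows.append((col, res.slope, 100.0 * res.slope))
    return pd.DataFrame(rows, columns=["estimator", "slope_per_year", "slope_percent"])
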