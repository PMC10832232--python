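"""Shared fixtures: one small and one full-scale simulated analysis.

Both are session-scoped because the gene-drop simulation and the HBD decode
dominate the suite's runtime; every test that needs a realistic population
shares them.  All seeds are fixed, so the suite is deterministic.
"""

import numpy as np
import pytest

from idstrat.data_io import AlleleFrequencySet, compute_sample_af, filter_by_maf
from idstrat.estimators import build_relationship_matrix
from idstrat.founder_af import estimate_founder_af
from idstrat.hbd import HBDModelSpec, em_fit
from idstrat.simulate import SimulationConfig, simulate_population

SMALL_SEED = 11
FULL_SEED = 7


@pytest.fixture(scope="session")
def small_population():
    """Desk-scale drift scenario: 400-strong cohort, 3,000 markers."""
    cfg = SimulationConfig(
        seed=SMALL_SEED, cohort_size=400, n_markers=3000, n_chromosomes=3
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_population):
    """Filtered genotypes, AF sets and HBD decodes for the small scenario."""
    pop = small_population
    saf = compute_sample_af(pop.genotypes)
    g, saf = filter_by_maf(pop.genotypes, saf, 0.01)
    faf = estimate_founder_af(g, pop.pedigree)
    keep = faf.flags
    g = g.subset_markers(np.flatnonzero(keep))
    faf = AlleleFrequencySet(faf.frequencies[keep], "founder_estimated")
    saf = AlleleFrequencySet(saf.frequencies[keep], "sample")
    spec = HBDModelSpec()
    spec_f, dec_f = em_fit(g, faf, spec, tol=1e-4, max_iter=200)
    spec_s, dec_s = em_fit(g, saf, spec, tol=1e-4, max_iter=200)
    G_half = build_relationship_matrix("half_freq_similarity", g=g)
    return {
        "pop": pop,
        "genotypes": g,
        "founder_af": faf,
        "sample_af": saf,
        "spec": spec_f,
        "dec_founder": dec_f,
        "dec_sample": dec_s,
        "G_half": G_half,
    }


@pytest.fixture(scope="session")
def full_analysis():
    """The default study scenario: ~1,000 genotyped individuals, 6,000 markers,
    20 generations with the breeding population shrinking to 30."""
    cfg = SimulationConfig(seed=FULL_SEED)
    pop = simulate_population(cfg)
    saf = compute_sample_af(pop.genotypes)
    g, saf = filter_by_maf(pop.genotypes, saf, 0.01)
    faf = estimate_founder_af(g, pop.pedigree)
    keep = faf.flags
    g = g.subset_markers(np.flatnonzero(keep))
    faf = AlleleFrequencySet(faf.frequencies[keep], "founder_estimated")
    saf = AlleleFrequencySet(saf.frequencies[keep], "sample")
    spec = HBDModelSpec()
    spec_f, dec_f = em_fit(g, faf, spec, tol=1e-4, max_iter=200)
    spec_s, dec_s = em_fit(g, saf, spec, tol=1e-4, max_iter=200)
    G_half = build_relationship_matrix("half_freq_similarity", g=g)
    rates = np.asarray(spec.rates)
    f_classes = dec_f.f_hbd_per_class[:, rates <= spec.aggregate_max_rate]
    return {
        "pop": pop,
        "genotypes": g,
        "founder_af": faf,
        "sample_af": saf,
        "spec": spec_f,
        "dec_founder": dec_f,
        "dec_sample": dec_s,
        "G_half": G_half,
        "f_classes": f_classes,
    }
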