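"""Replicated validation experiments and the end-to-end pipeline.

The constant-effect study follows the validation design for stratified
inbreeding depression: phenotypes are simulated on the real (or simulated)
genotypes with a polygenic term, a residual, and an inbreeding term equal to
the aggregate F_HBD times one constant coefficient (default -21, a strongly
depressive effect on a conformation-trait scale).  The stratified mixed model
is then refitted on each replicate, giving per-class effect distributions and
detection rates — a direct measure of how much the variation in each HBD
class limits power, independent of any biological difference between classes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import compute_sample_af, filter_by_maf
from .estimators import build_relationship_matrix, inbreeding_table, annual_trend
from .founder_af import estimate_founder_af, founder_af_table
from .hbd import HBDModelSpec, decode_table
from .mixed_model import (
    REMLWorkspace,
    fit_id_single,
    fit_id_stratified,
    significance_threshold,
)
from .simulate import (
    PhenotypeArchitecture,
    SimulatedPopulation,
    SimulationConfig,
    simulate_phenotypes,
    simulate_population,
    write_population,
)


def replicate_seed(master_seed: int, counter: int) -> int:
    """Counter-based per-replicate seed: independent, individually reproducible,
    and stable under splitting replicates across processes."""
    h = hashlib.sha256(f"{master_seed}:{counter}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class PowerStudyConfig:
    id_effect: float = -21.0
    h2: float = 0.35
    var_phenotypic: float = 16.0
    n_replicates: int = 100
    alpha: float = 0.05
    seed: int = 0


@dataclass
class PowerStudyResult:
    """Per-class summaries over replicates of the constant-effect study."""

    class_names: list[str]
    mean_effect: np.ndarray
    sd_effect: np.ndarray
    detection_rate: np.ndarray
    f_class_sd: np.ndarray
    n_replicates: int
    seed: int
    effects: np.ndarray = field(repr=False)  # (replicates, classes)
    p_values: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_names,
                "mean_effect": self.mean_effect,
                "sd_effect": self.sd_effect,
                "detection_rate": self.detection_rate,
                "f_class_sd": self.f_class_sd,
            }
        )

    def count_more_negative_than(self, reference: float) -> np.ndarray:
        """Per class, number of replicates whose estimated effect is more
        negative (more deleterious) than a reference value."""
        return np.nansum(self.effects < reference, axis=0)


def run_constant_id_study(
    genotypes,
    f_hbd: np.ndarray,
    f_classes: np.ndarray,
    G: np.ndarray,
    config: PowerStudyConfig,
    class_names: list[str] | None = None,
) -> PowerStudyResult:
    """Simulate phenotypes with a constant inbreeding effect through total
    F_HBD and refit the stratified model, ``n_replicates`` times.

    The relationship matrix is eigendecomposed once and reused, so each
    replicate costs one phenotype draw plus a 1-D REML search.
    """
    F = np.asarray(f_classes, float)
    n, C = F.shape
    if (np.var(F, axis=0) > 1e-12).sum() < 2:
        raise ValueError("need at least two HBD classes with variation")
    class_names = class_names or [f"class{k + 1}" for k in range(C)]
    ws = REMLWorkspace.from_grm(G)
    effects = np.full((config.n_replicates, C), np.nan)
    pvals = np.full((config.n_replicates, C), np.nan)
    for rep in range(config.n_replicates):
        arch = PhenotypeArchitecture(
            h2=config.h2,
            var_phenotypic=config.var_phenotypic,
            id_effect_total=config.id_effect,
            seed=replicate_seed(config.seed, rep),
        )
        pheno = simulate_phenotypes(genotypes, f_hbd, arch)
        fit = fit_id_stratified(
            pheno.values, F, workspace=ws, class_names=class_names
        )
        for k, name in enumerate(class_names):
            if name in fit.term_names:
                b, se, p = fit.effect(name)
                effects[rep, k] = b
                pvals[rep, k] = p
    detection = np.nanmean(pvals < config.alpha, axis=0)
    return PowerStudyResult(
        class_names=class_names,
        mean_effect=np.nanmean(effects, axis=0),
        sd_effect=np.nanstd(effects, axis=0, ddof=1),
        detection_rate=detection,
        f_class_sd=F.std(axis=0, ddof=1),
        n_replicates=config.n_replicates,
        seed=config.seed,
        effects=effects,
        p_values=pvals,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Simulation-scenario pipeline configuration (single source of truth
    for the numbered analysis drivers)."""

    simulation: SimulationConfig = None
    hbd_epsilon: float = 0.0025
    hbd_max_iter: int = 200
    maf_threshold: float = 0.01
    gene_content_h2: float = 0.99
    power: PowerStudyConfig = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.power is None:
            self.power = PowerStudyConfig(seed=self.seed)


def run_full_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Simulate, estimate founder AF, compute all six estimators under both
    AF sources, decode HBD, fit single-F and stratified ID models, and run
    the constant-effect power study.  Writes every table as TSV plus a run
    manifest; returns the in-memory results keyed by stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "simulate"
    try:
        pop = simulate_population(config.simulation)
        write_population(pop, outdir / "simulated")
        results["population"] = pop

        stage = "marker_filter"
        g = pop.genotypes
        sample_af = compute_sample_af(g)
        g, sample_af = filter_by_maf(g, sample_af, config.maf_threshold)

        stage = "founder_af"
        founder_af = estimate_founder_af(g, pop.pedigree, h2=config.gene_content_h2)
        founder_af_table(g, founder_af, sample_af).to_csv(
            outdir / "founder_af.tsv", sep="\t", index=False
        )
        keep = founder_af.flags
        g = g.subset_markers(np.flatnonzero(keep))
        from .data_io import AlleleFrequencySet

        founder_af = AlleleFrequencySet(
            founder_af.frequencies[keep], "founder_estimated"
        )
        sample_af = AlleleFrequencySet(sample_af.frequencies[keep], "sample")
        results["genotypes"] = g
        results["founder_af"] = founder_af
        results["sample_af"] = sample_af

        stage = "hbd_decode"
        spec = HBDModelSpec(epsilon=config.hbd_epsilon)
        hbd_founder, spec_founder = decode_table(
            g, founder_af, spec, max_iter=config.hbd_max_iter
        )
        hbd_sample, _ = decode_table(g, sample_af, spec, max_iter=config.hbd_max_iter)
        hbd_founder.to_csv(outdir / "hbd_founder_af.tsv", sep="\t", index=False)
        hbd_sample.to_csv(outdir / "hbd_sample_af.tsv", sep="\t", index=False)
        results["hbd_founder"] = hbd_founder
        results["hbd_sample"] = hbd_sample
        results["hbd_spec"] = spec_founder

        stage = "estimators"
        tables = {}
        for af, tag in ((founder_af, "founder"), (sample_af, "sample")):
            hbd_tab = hbd_founder if tag == "founder" else hbd_sample
            tab = inbreeding_table(
                g, af, ped=pop.pedigree, f_hbd=hbd_tab["f_hbd"].to_numpy()
            )
            tab.to_csv(outdir / f"inbreeding_{tag}_af.tsv", sep="\t")
            tables[tag] = tab
        results["inbreeding"] = tables

        stage = "trend"
        trend = annual_trend(tables["founder"], pop.pedigree)
        trend.to_csv(outdir / "annual_trend.tsv", sep="\t", index=False)
        results["trend"] = trend

        stage = "id_single"
        arch = PhenotypeArchitecture(
            h2=config.power.h2,
            var_phenotypic=config.power.var_phenotypic,
            id_effect_total=config.power.id_effect,
            seed=replicate_seed(config.seed, 10**6),
        )
        f_hbd = tables["founder"]["f_hbd"].to_numpy()
        pheno = simulate_phenotypes(g, f_hbd, arch)
        rows = []
        fits = {}
        from .estimators import GRM_FLAVOR_FOR_ESTIMATOR

        for est, flavor in GRM_FLAVOR_FOR_ESTIMATOR.items():
            G = build_relationship_matrix(
                flavor, g=g, af=founder_af, ped=pop.pedigree, sample_ids=g.sample_ids
            )
            fit = fit_id_single(
                pheno.values, tables["founder"][est].to_numpy(), G=G,
                estimator=est, grm_flavor=flavor,
            )
            b, se, p = fit.effect("f")
            rows.append((est, b, se, p, fit.sigma_g2, fit.sigma_e2, fit.n_used,
                         fit.converged))
            fits[est] = fit
        exact, rounded = significance_threshold(66)
        single = pd.DataFrame(
            rows, columns=["estimator", "effect", "se", "p", "sigma_g2",
                           "sigma_e2", "n_used", "converged"],
        )
        single["significant"] = single["p"] < rounded
        single.to_csv(outdir / "id_single.tsv", sep="\t", index=False)
        results["id_single"] = single
        results["id_fits"] = fits

        stage = "id_stratified"
        rates = np.asarray(results["hbd_spec"].rates)
        keep_classes = rates <= results["hbd_spec"].aggregate_max_rate
        class_cols = [f"f_hbd_R{int(r)}" for r in rates[keep_classes]]
        F_classes = hbd_founder[class_cols].to_numpy()
        G_half = build_relationship_matrix("half_freq_similarity", g=g)
        strat = fit_id_stratified(
            pheno.values, F_classes, G=G_half, class_names=class_cols
        )
        strat_rows = [
            (nm, strat.b[k], strat.se[k], strat.p_values[k], strat.ci_low[k],
             strat.ci_high[k])
            for k, nm in enumerate(strat.term_names)
        ]
        pd.DataFrame(
            strat_rows, columns=["term", "effect", "se", "p", "ci_low", "ci_high"]
        ).to_csv(outdir / "id_stratified.tsv", sep="\t", index=False)
        results["id_stratified"] = strat
        results["f_classes"] = F_classes
        results["class_names"] = class_cols
        results["G_half"] = G_half
        results["phenotypes"] = pheno

        stage = "power_study"
        power = run_constant_id_study(
            g, f_hbd, F_classes, G_half, config.power, class_names=class_cols
        )
        power.to_frame().to_csv(outdir / "power_study.tsv", sep="\t", index=False)
        results["power"] = power

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "simulation": asdict(config.simulation),
            "power": asdict(config.power),
            "config_hash": hashlib.sha256(
                json.dumps(
                    {"sim": asdict(config.simulation), "pw": asdict(config.power)},
                    sort_keys=True, default=str,
                ).encode()
            ).hexdigest(),
            "stages": ["simulate", "marker_filter", "founder_af", "hbd_decode",
                        "estimators", "trend", "id_single", "id_stratified",
                        "power_study"],
            "assumed_trait_architecture": {
                "h2": config.power.h2, "var_phenotypic": config.power.var_phenotypic,
                "note": "trait h2 and variance are configurable assumptions",
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as err:  # annotate failures with the stage that broke
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return results
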