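"""Gene-drop simulation of a pedigreed population with truth-labelled HBD tracts.

Founder haplotypes are drawn site-wise from a founder allele-frequency
distribution; descendants are produced by dropping gametes down the pedigree
with crossovers from a Poisson process at rate 1 per Morgan (Haldane, no
interference).  Every haplotype records the mosaic of immediate-parent
haplotype copies it was spliced from, so the age of each
homozygous-by-descent (HBD) tract — the number of generations g back to the
most recent common ancestor haplotype of the two lineages — can be recovered
exactly by lifting both lineages one generation at a time and noting where
they first pass through the same ancestral haplotype copy.  Tracts of meeting
generation g have approximately exponential lengths with mean 1/(2g) Morgan,
the age-length relation the HBD-class HMM exploits (class rate R_c ~ 2g).

The default scenario emulates an intensively selected livestock population:
a moderate founder base followed by generations of random mating with the
breeding population shrinking towards the present, so that recent and ancient
HBD coexist in the final genotyped cohort and sample allele frequencies have
drifted away from the founder values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    MISSING,
    AlleleFrequencySet,
    GenotypeMatrix,
    Pedigree,
    build_pedigree,
    write_pedigree,
    write_plink,
)

# ---------------------------------------------------------------------------
# Mosaic primitives: a haplotype along one chromosome is piecewise constant,
# stored as (starts, labels) with starts[0] == 0; segment k covers
# [starts[k], starts[k+1]) and the last segment runs to chromosome end.
# ---------------------------------------------------------------------------


def _splice(mosaic_a, mosaic_b, xs: np.ndarray, first: int):
    """Recombine two parental mosaics at crossover positions xs (sorted).

    ``first`` selects the mosaic transmitted before the first crossover.
    Returns a new (starts, labels) pair.
    """
    sources = (mosaic_a, mosaic_b)
    bounds = np.concatenate(([0.0], xs, [np.inf]))
    starts: list[float] = []
    labels: list[int] = []
    which = first
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        s_starts, s_labels = sources[which]
        i0 = np.searchsorted(s_starts, lo, side="right") - 1
        i1 = np.searchsorted(s_starts, hi, side="left")
        for i in range(i0, i1):
            seg_start = max(lo, s_starts[i])
            lab = s_labels[i]
            if labels and labels[-1] == lab:
                continue  # merge adjacent equal labels
            starts.append(seg_start)
            labels.append(lab)
        which = 1 - which
    return np.asarray(starts), np.asarray(labels, dtype=np.int64)


def _evaluate(mosaic, positions: np.ndarray) -> np.ndarray:
    """Label of the mosaic at each query position."""
    starts, labels = mosaic
    idx = np.searchsorted(starts, positions, side="right") - 1
    return labels[idx]


def _first_meetings(mosaic_a, mosaic_b, length: float):
    """Intervals where the two mosaics carry the same label.

    Returns a list of (start, end, label) over [0, length).
    """
    sa, la = mosaic_a
    sb, lb = mosaic_b
    cuts = np.unique(np.concatenate([sa, sb, [0.0, length]]))
    cuts = cuts[cuts < length]
    out = []
    for k in range(len(cuts)):
        lo = cuts[k]
        hi = cuts[k + 1] if k + 1 < len(cuts) else length
        a = la[np.searchsorted(sa, lo, side="right") - 1]
        b = lb[np.searchsorted(sb, lo, side="right") - 1]
        if a == b:
            out.append((lo, hi, int(a)))
    return out


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------


class GeneDrop:
    """Drops recombining gametes down an explicitly built pedigree.

    Individuals are created in order (founders first); each carries two
    haplotypes per chromosome.  Haplotype copies get global integer ids;
    founder haplotype ids are < 2 * n_founders_so_far at creation time,
    handled via an explicit founder set.
    """

    def __init__(self, chromosome_lengths: list[float], rng: np.random.Generator):
        self.lengths = list(chromosome_lengths)
        self.rng = rng
        self.n_individuals = 0
        self.generation: list[int] = []
        # per chromosome: hap_id -> (starts, labels) in immediate-parent hap ids
        self.parent_mosaics: list[dict[int, tuple]] = [{} for _ in self.lengths]
        # per chromosome: hap_id -> (starts, labels) in founder hap ids
        self.founder_mosaics: list[dict[int, tuple]] = [{} for _ in self.lengths]
        self.founder_haps: set[int] = set()

    def _hap_ids(self, ind: int) -> tuple[int, int]:
        return 2 * ind, 2 * ind + 1

    def add_founder(self) -> int:
        ind = self.n_individuals
        self.n_individuals += 1
        self.generation.append(0)
        for h in self._hap_ids(ind):
            self.founder_haps.add(h)
            for c, _ in enumerate(self.lengths):
                trivial = (np.array([0.0]), np.array([h], dtype=np.int64))
                self.parent_mosaics[c][h] = trivial
                self.founder_mosaics[c][h] = trivial
        return ind

    def _gamete(self, parent: int, chrom: int, hap_id: int) -> None:
        length = self.lengths[chrom]
        n_x = self.rng.poisson(length)
        xs = np.sort(self.rng.uniform(0, length, size=n_x))
        first = int(self.rng.integers(2))
        p0, p1 = self._hap_ids(parent)
        # parent-level mosaic: alternating parent hap ids at the crossover points
        par_m = _splice(
            (np.array([0.0]), np.array([p0], dtype=np.int64)),
            (np.array([0.0]), np.array([p1], dtype=np.int64)),
            xs, first,
        )
        fm = self.founder_mosaics[chrom]
        fdr_m = _splice(fm[p0], fm[p1], xs, first)
        self.parent_mosaics[chrom][hap_id] = par_m
        self.founder_mosaics[chrom][hap_id] = fdr_m

    def add_offspring(self, sire: int, dam: int) -> int:
        ind = self.n_individuals
        self.n_individuals += 1
        self.generation.append(max(self.generation[sire], self.generation[dam]) + 1)
        h_pat, h_mat = self._hap_ids(ind)
        for c in range(len(self.lengths)):
            self._gamete(sire, c, h_pat)
            self._gamete(dam, c, h_mat)
        return ind

    def truth_tracts(self, ind: int) -> list[tuple[int, float, float, int]]:
        """HBD tracts of an individual as (chromosome, start, end, meeting generation g).

        g counts generations back to the most recent common ancestor haplotype
        copy of the two lineages over that interval; adjacent intervals with
        equal g are merged.  Founders and offspring of unrelated founders
        return an empty list.
        """
        tracts: list[tuple[int, float, float, int]] = []
        h_a, h_b = self._hap_ids(ind)
        for c, length in enumerate(self.lengths):
            mos_a = (np.array([0.0]), np.array([h_a], dtype=np.int64))
            mos_b = (np.array([0.0]), np.array([h_b], dtype=np.int64))
            resolved: list[tuple[float, float]] = []
            found: list[tuple[float, float, int]] = []
            depth = 0
            max_depth = self.generation[ind]
            while depth < max_depth:
                depth += 1
                mos_a = self._lift_one(mos_a, c)
                mos_b = self._lift_one(mos_b, c)
                for lo, hi, _ in _first_meetings(mos_a, mos_b, length):
                    lo2, hi2 = lo, hi
                    for seg in _subtract((lo2, hi2), resolved):
                        found.append((seg[0], seg[1], depth))
                        resolved.append(seg)
                resolved = _merge_intervals(resolved)
            for lo, hi, g in sorted(found):
                if tracts and tracts[-1][0] == c and tracts[-1][3] == g and \
                        abs(tracts[-1][2] - lo) < 1e-12:
                    tracts[-1] = (c, tracts[-1][1], hi, g)
                else:
                    tracts.append((c, lo, hi, g))
        return tracts

    def _lift_one(self, mosaic, chrom: int):
        starts, labels = mosaic
        out_s: list[float] = []
        out_l: list[int] = []
        ends = np.append(starts[1:], np.inf)
        pm = self.parent_mosaics[chrom]
        for s, e, h in zip(starts, ends, labels):
            if h in self.founder_haps:
                pieces = [(s, int(h))]
            else:
                p_starts, p_labels = pm[h]
                i0 = np.searchsorted(p_starts, s, side="right") - 1
                i1 = np.searchsorted(p_starts, e, side="left")
                pieces = [(max(s, float(p_starts[i])), int(p_labels[i])) for i in range(i0, i1)]
            for ps, pl in pieces:
                if out_l and out_l[-1] == pl:
                    continue
                out_s.append(ps)
                out_l.append(pl)
        return np.asarray(out_s), np.asarray(out_l, dtype=np.int64)

    def founder_hap_at(self, ind: int, chrom: int, positions: np.ndarray):
        """Founder-haplotype labels of the individual's two haplotypes at positions."""
        h_a, h_b = self._hap_ids(ind)
        fm = self.founder_mosaics[chrom]
        return _evaluate(fm[h_a], positions), _evaluate(fm[h_b], positions)


def _subtract(interval, covered):
    """Parts of ``interval`` not overlapped by any interval in ``covered``."""
    lo, hi = interval
    pieces = [(lo, hi)]
    for clo, chi in covered:
        nxt = []
        for plo, phi in pieces:
            if chi <= plo or clo >= phi:
                nxt.append((plo, phi))
                continue
            if plo < clo:
                nxt.append((plo, clo))
            if chi < phi:
                nxt.append((chi, phi))
        pieces = nxt
    return [(a, b) for a, b in pieces if b - a > 1e-12]


def _merge_intervals(intervals):
    if not intervals:
        return []
    ints = sorted(intervals)
    out = [list(ints[0])]
    for lo, hi in ints[1:]:
        if lo <= out[-1][1] + 1e-12:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [tuple(x) for x in out]


# ---------------------------------------------------------------------------
# Population scenario
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Scenario parameters for the default pedigreed population.

    The breeding population holds ``n_founders`` individuals for the first
    half of the pedigree, then shrinks linearly to ``shrink_to`` over the last
    ``shrink_over`` generations; the final generation is an expanded genotyped
    cohort of ``cohort_size``.  Marker positions are evenly spaced; founder
    allele frequencies are uniform on ``founder_af_range``.
    """

    n_founders: int = 100
    generations: int = 20
    shrink_to: int = 30
    shrink_over: int = 10
    cohort_size: int = 1000
    cohort_generations: int = 4
    n_chromosomes: int = 5
    chromosome_length_morgan: float = 1.0
    n_markers: int = 6000
    founder_af_range: tuple[float, float] = (0.05, 0.95)
    mating: str = "random"  # or "full_sib_enriched"
    full_sib_fraction: float = 0.2
    epsilon_sim: float = 0.001
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.n_markers % self.n_chromosomes != 0:
            raise ValueError("n_markers must divide evenly over chromosomes")
        for name in ("n_founders", "generations", "cohort_size", "n_chromosomes",
                     "n_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chromosome_length_morgan <= 0:
            raise ValueError("chromosome length must be positive")


@dataclass
class SimulatedPopulation:
    """Genotypes, pedigree, founder truth and HBD-tract truth from one gene drop."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    founder_af: AlleleFrequencySet
    truth_tracts: dict[str, list[tuple[int, float, float, int]]]
    drop: GeneDrop = field(repr=False)
    cohort_ids: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    def truth_hbd_fraction(self, ind_id: str) -> float:
        """Genome fraction of an individual lying in truth HBD tracts."""
        total = sum(self.drop.lengths)
        return sum(hi - lo for _, lo, hi, _ in self.truth_tracts[ind_id]) / total

    def truth_class_fractions(self, rates: np.ndarray) -> pd.DataFrame:
        """Per-individual genome fraction per HBD class, classifying each tract
        by the class whose 0.5*R_c is nearest its meeting generation g."""
        rates = np.asarray(rates, dtype=float)
        total = sum(self.drop.lengths)
        rows = {}
        for iid, tracts in self.truth_tracts.items():
            frac = np.zeros(len(rates))
            for _, lo, hi, g in tracts:
                c = int(np.argmin(np.abs(0.5 * rates - g)))
                frac[c] += (hi - lo) / total
            rows[iid] = frac
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"R{int(r)}" for r in rates]
        )


def _population_sizes(cfg: SimulationConfig) -> tuple[list[int], list[int]]:
    """(breeding size, surplus genotyped offspring) per generation 1..generations.

    The breeding population shrinks linearly to ``shrink_to`` over the last
    ``shrink_over`` generations; the last ``cohort_generations`` generations
    additionally produce surplus (non-breeding) offspring so that the
    genotyped cohort reaches ``cohort_size`` spread over several birth years.
    """
    breeding = []
    n_shrink = min(cfg.shrink_over, cfg.generations)
    n_stable = cfg.generations - n_shrink
    breeding.extend([cfg.n_founders] * n_stable)
    for k in range(1, n_shrink + 1):
        frac = k / n_shrink
        breeding.append(
            int(round(cfg.n_founders + frac * (cfg.shrink_to - cfg.n_founders)))
        )
    surplus = [0] * cfg.generations
    n_cg = min(cfg.cohort_generations, cfg.generations)
    base = sum(breeding[-n_cg:])
    extra = max(0, cfg.cohort_size - base)
    for k in range(cfg.generations - n_cg, cfg.generations):
        surplus[k] = int(np.ceil(extra / n_cg))
    return breeding, surplus


def simulate_population(cfg: SimulationConfig) -> SimulatedPopulation:
    """Run the full gene-drop scenario and genotype the final cohort."""
    rng = np.random.default_rng(cfg.seed)
    lengths = [cfg.chromosome_length_morgan] * cfg.n_chromosomes
    drop = GeneDrop(lengths, rng)

    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    years: list[int] = []
    index_of: dict[str, int] = {}

    def register(label, sire_label, dam_label, year, idx):
        ids.append(label)
        sires.append(sire_label)
        dams.append(dam_label)
        years.append(year)
        index_of[label] = idx

    prev: list[str] = []
    for k in range(cfg.n_founders):
        label = f"F{k:04d}"
        idx = drop.add_founder()
        register(label, "0", "0", 2000, idx)
        prev.append(label)

    breeding_sizes, surplus_sizes = _population_sizes(cfg)
    cohort_ids: list[str] = []
    n_cg = min(cfg.cohort_generations, cfg.generations)
    for gen in range(1, cfg.generations + 1):
        n_breed = breeding_sizes[gen - 1]
        n_total = n_breed + surplus_sizes[gen - 1]
        cur: list[str] = []
        for k in range(n_total):
            if cfg.mating == "full_sib_enriched" and rng.uniform() < cfg.full_sib_fraction:
                sire_l, dam_l = _pick_full_sibs(prev, sires, dams, index_of, rng)
            else:
                a, b = rng.choice(len(prev), size=2, replace=False)
                sire_l, dam_l = prev[a], prev[b]
            label = f"G{gen:02d}I{k:04d}"
            idx = drop.add_offspring(index_of[sire_l], index_of[dam_l])
            register(label, sire_l, dam_l, 2000 + gen, idx)
            cur.append(label)
        if gen > cfg.generations - n_cg:
            cohort_ids.extend(cur)
        prev = cur[:n_breed]  # only the breeding subset parents the next generation

    pedigree = build_pedigree(ids, sires, dams, years)

    # markers: evenly spaced within each chromosome
    per_chrom = cfg.n_markers // cfg.n_chromosomes
    positions = (np.arange(per_chrom) + 0.5) / per_chrom * cfg.chromosome_length_morgan
    founder_p = rng.uniform(*cfg.founder_af_range, size=cfg.n_markers)
    founder_alleles = (
        rng.uniform(size=(2 * cfg.n_founders, cfg.n_markers)) < founder_p
    ).astype(np.int8)

    dosages = np.empty((len(cohort_ids), cfg.n_markers), dtype=np.int8)
    for row, iid in enumerate(cohort_ids):
        ind = index_of[iid]
        geno = np.empty(cfg.n_markers, dtype=np.int8)
        for c in range(cfg.n_chromosomes):
            sl = slice(c * per_chrom, (c + 1) * per_chrom)
            ha, hb = drop.founder_hap_at(ind, c, positions)
            geno[sl] = (
                founder_alleles[ha, np.arange(*sl.indices(cfg.n_markers))]
                + founder_alleles[hb, np.arange(*sl.indices(cfg.n_markers))]
            )
        dosages[row] = geno

    # genotyping error: replace the call with a Hardy-Weinberg draw at rate epsilon
    if cfg.epsilon_sim > 0:
        err = rng.uniform(size=dosages.shape) < cfg.epsilon_sim
        hw = _hw_draw(founder_p, dosages.shape, rng)
        dosages = np.where(err, hw, dosages)

    markers = pd.DataFrame(
        {
            "chrom": np.repeat([str(c + 1) for c in range(cfg.n_chromosomes)], per_chrom),
            "snp_id": [f"snp{j}" for j in range(cfg.n_markers)],
            "morgan": np.tile(positions, cfg.n_chromosomes),
            "bp": np.tile((positions * 1e8).astype(np.int64) + 1, cfg.n_chromosomes),
            "a1": "A",
            "a2": "B",
        }
    )
    genotypes = GenotypeMatrix(dosages=dosages, sample_ids=cohort_ids, markers=markers)

    truth = {iid: drop.truth_tracts(index_of[iid]) for iid in cohort_ids}

    return SimulatedPopulation(
        genotypes=genotypes,
        pedigree=pedigree,
        founder_af=AlleleFrequencySet(founder_p, source="founder_true"),
        truth_tracts=truth,
        drop=drop,
        cohort_ids=cohort_ids,
        config=cfg,
    )


def _pick_full_sibs(prev, sires, dams, index_of, rng):
    """Pick a full-sib pair from the previous generation if one exists."""
    by_parents: dict[tuple[str, str], list[str]] = {}
    for iid in prev:
        i = index_of[iid]
        by_parents.setdefault((sires[i], dams[i]), []).append(iid)
    sib_groups = [v for v in by_parents.values() if len(v) >= 2]
    if not sib_groups:
        a, b = rng.choice(len(prev), size=2, replace=False)
        return prev[a], prev[b]
    group = sib_groups[int(rng.integers(len(sib_groups)))]
    a, b = rng.choice(len(group), size=2, replace=False)
    return group[a], group[b]


def _hw_draw(p: np.ndarray, shape, rng) -> np.ndarray:
    """Hardy-Weinberg genotype draw at per-marker frequency p, broadcast over rows."""
    u1 = rng.uniform(size=shape) < p[None, :]
    u2 = rng.uniform(size=shape) < p[None, :]
    return (u1.astype(np.int8) + u2.astype(np.int8))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeArchitecture:
    """Trait architecture: narrow-sense h2, phenotypic variance, and the
    inbreeding-depression effect expressed per unit of inbreeding.

    ``id_effect_total`` applies one coefficient to total F; per-class mode
    multiplies a coefficient vector with a per-class inbreeding matrix.
    Defaults emulate a moderately heritable conformation trait.
    """

    h2: float = 0.35
    var_phenotypic: float = 16.0
    id_effect_total: float | None = -21.0
    id_effects_per_class: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0,1)")
        if self.var_phenotypic < 0:
            raise ValueError("var_phenotypic must be >= 0")


@dataclass
class PhenotypeSet:
    values: np.ndarray
    polygenic: np.ndarray
    residual: np.ndarray
    id_component: np.ndarray


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    f: np.ndarray,
    arch: PhenotypeArchitecture,
    f_classes: np.ndarray | None = None,
) -> PhenotypeSet:
    """Phenotype = rescaled polygenic + rescaled residual + inbreeding effect.

    Per-marker allelic effects are standard-normal; the polygenic score is the
    dosage-weighted sum, centred and rescaled to variance h2 * var_phenotypic;
    the residual is rescaled to (1 - h2) * var_phenotypic; the inbreeding term
    is id_effect_total * f (or the per-class product when class coefficients
    are supplied).
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite inbreeding coefficients")
    n = genotypes.n_samples
    if len(f) != n:
        raise ValueError("f length does not match genotypes")
    rng = np.random.default_rng(arch.seed)

    effects = rng.standard_normal(genotypes.n_markers)
    dos = np.where(genotypes.dosages == MISSING, 0, genotypes.dosages).astype(float)
    poly = dos @ effects
    poly = poly - poly.mean()
    target_g = arch.h2 * arch.var_phenotypic
    sd = poly.std()
    if sd > 0 and target_g > 0:
        poly *= np.sqrt(target_g) / sd
    else:
        poly[:] = 0.0

    resid = rng.standard_normal(n)
    resid = resid - resid.mean()
    target_e = (1 - arch.h2) * arch.var_phenotypic
    sd = resid.std()
    if sd > 0 and target_e > 0:
        resid *= np.sqrt(target_e) / sd
    else:
        resid[:] = 0.0

    if arch.id_effects_per_class is not None:
        if f_classes is None:
            raise ValueError("per-class effects require a per-class F matrix")
        id_comp = np.asarray(f_classes, float) @ np.asarray(
            arch.id_effects_per_class, float
        )
    else:
        id_comp = (arch.id_effect_total or 0.0) * f

    return PhenotypeSet(
        values=poly + resid + id_comp,
        polygenic=poly,
        residual=resid,
        id_component=id_comp,
    )


# ---------------------------------------------------------------------------
# Single-locus gene drop: the Monte-Carlo oracle for pedigree inbreeding
# ---------------------------------------------------------------------------


def gene_drop_ibd_probability(
    ped: Pedigree, n_drops: int, seed: int
) -> np.ndarray:
    """Per-individual probability that the two alleles at a neutral locus are
    identical by descent, estimated by dropping unique founder alleles down
    the pedigree ``n_drops`` times (vectorised over drops)."""
    rng = np.random.default_rng(seed)
    sire, dam = ped.parent_indices()
    n = ped.n
    pat = np.empty((n, n_drops), dtype=np.int32)
    mat = np.empty((n, n_drops), dtype=np.int32)
    for i in range(n):
        if sire[i] < 0:
            pat[i] = 2 * i
        else:
            pick = rng.integers(2, size=n_drops, dtype=np.int8)
            pat[i] = np.where(pick == 0, pat[sire[i]], mat[sire[i]])
        if dam[i] < 0:
            mat[i] = 2 * i + 1
        else:
            pick = rng.integers(2, size=n_drops, dtype=np.int8)
            mat[i] = np.where(pick == 0, pat[dam[i]], mat[dam[i]])
    return (pat == mat).mean(axis=1)


# ---------------------------------------------------------------------------
# On-disk outputs
# ---------------------------------------------------------------------------


def write_population(pop: SimulatedPopulation, outdir: str | Path) -> None:
    """Write PLINK triplet, pedigree CSV, truth-tract TSV and founder AF TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(pop.genotypes, outdir / "cohort")
    write_pedigree(pop.pedigree, outdir / "pedigree.csv")
    rows = [
        (iid, c, lo, hi, g)
        for iid, tracts in pop.truth_tracts.items()
        for c, lo, hi, g in tracts
    ]
    pd.DataFrame(rows, columns=["id", "chrom", "start_M", "end_M", "g"]).to_csv(
        outdir / "truth_tracts.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "snp_id": pop.genotypes.markers["snp_id"],
            "founder_af": pop.founder_af.frequencies,
        }
    ).to_csv(outdir / "founder_af.tsv", sep="\t", index=False)
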