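"""Genotype, pedigree and allele-frequency containers plus the file formats they travel in.

The pipeline consumes PLINK 1 binary triplets (.bed/.bim/.fam, SNP-major),
a pedigree CSV (id, sire, dam, birth_year; 0 or empty = unknown parent) and
plain TSV tables.  Dosages count the .bim A1 allele, so 0/1/2 is the number
of A1 copies; -1 codes a missing call throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (SNP-major, v1.0): 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Dosage counts A1 copies.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Raised for malformed input files."""


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, missing parents)."""


@dataclass
class GenotypeMatrix:
    """n individuals x L markers of A1-allele dosages with marker metadata.

    ``dosages`` holds values in {0, 1, 2, MISSING}.  ``markers`` is a DataFrame
    with columns chrom, snp_id, morgan, bp, a1, a2; Morgan positions must be
    non-decreasing within a chromosome (the HMM works in Morgan only).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        n, L = self.dosages.shape
        if n == 0 or L == 0:
            raise ValueError("empty genotype matrix")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.markers) != L:
            raise ValueError("marker table length does not match dosage columns")
        for _, sub in self.markers.groupby("chrom", sort=False):
            m = sub["morgan"].to_numpy(float)
            if np.any(np.diff(m) < 0):
                raise ValueError("Morgan positions decrease within a chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[keep].reset_index(drop=True),
        )


@dataclass
class Pedigree:
    """Acyclic parent map with birth years, stored parents-before-offspring.

    ``records`` is a DataFrame with columns id, sire, dam, birth_year where
    sire/dam are the string "0" for unknown (founder side).  Rows are in a
    valid topological order, so downstream recursions (tabular A, inbreeding,
    gene drop) can run in row order.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.records["id"].tolist()
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise PedigreeError(f"duplicated individual id: {dup}")
        seen: set[str] = set()
        for row in self.records.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent != "0" and parent not in seen:
                    raise PedigreeError(
                        f"records not topologically ordered or parent missing: {parent}"
                    )
            seen.add(row.id)

    @property
    def ids(self) -> list[str]:
        return self.records["id"].tolist()

    @property
    def n(self) -> int:
        return len(self.records)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire and dam for every individual; -1 = unknown."""
        pos = {iid: k for k, iid in enumerate(self.records["id"])}
        sire = np.array([pos.get(s, -1) for s in self.records["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) for d in self.records["dam"]], dtype=np.int64)
        return sire, dam

    def founders(self) -> list[str]:
        mask = (self.records["sire"] == "0") & (self.records["dam"] == "0")
        return self.records.loc[mask, "id"].tolist()


@dataclass
class AlleleFrequencySet:
    """Per-marker A1 allele frequencies with a provenance tag.

    ``source`` records where the frequencies came from: the genotyped sample
    itself, the gene-content pedigree-BLUP estimate of the base population, or
    the simulation truth.
    """

    frequencies: np.ndarray
    source: str
    flags: np.ndarray | None = None  # optional keep/remove mask (MAF refilter)

    _SOURCES = ("sample", "founder_estimated", "founder_true", "fixed_half")

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.source not in self._SOURCES:
            raise ValueError(f"unknown AF source {self.source!r}")
        if np.any((self.frequencies < 0) | (self.frequencies > 1)):
            raise ValueError("allele frequencies outside [0,1]")

    def __len__(self) -> int:
        return len(self.frequencies)


# ---------------------------------------------------------------------------
# PLINK 1 binary triplet
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet (SNP-major v1.0) into a GenotypeMatrix.

    The .bim A1 allele is the counted allele; the .bim cM column divided by 100
    gives Morgan positions.  If the cM column is all zeros, positions are
    derived from bp at 1 cM/Mb (logged loudly) so that the HMM always has a map.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    if len(fam) == 0:
        raise FormatError(f"{prefix}.fam has no rows")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    n, L = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1 .bed)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * L
    if len(raw) != expected:
        raise FormatError(
            f"{prefix}.bed: size mismatch (got {len(raw)} bytes, expected {expected})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(L, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(L, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()  # n x L

    morgan = bim["cm"].to_numpy(float) / 100.0
    if np.all(morgan == 0.0):
        logger.warning(
            "%s.bim cM column is all zeros: deriving map from bp at 1 cM/Mb", prefix
        )
        morgan = bim["bp"].to_numpy(float) * 1e-8
    markers = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "snp_id": bim["snp_id"],
            "morgan": morgan,
            "bp": bim["bp"].to_numpy(np.int64),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    return GenotypeMatrix(dosages=dosages, sample_ids=fam["iid"].tolist(), markers=markers)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK triplet; inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, L = g.dosages.shape
    fam = pd.DataFrame(
        {
            "fid": g.sample_ids, "iid": g.sample_ids,
            "father": "0", "mother": "0", "sex": "0", "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": g.markers["chrom"],
            "snp_id": g.markers["snp_id"],
            "cm": g.markers["morgan"] * 100.0,
            "bp": g.markers["bp"],
            "a1": g.markers["a1"],
            "a2": g.markers["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    code_lut = np.empty(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        code_lut[dosage % 4] = code  # MISSING=-1 -> index 3
    codes = code_lut[g.dosages.T % 4]  # L x n
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.full((L, pad), 0b01, dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(L, -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV/TSV (id, sire, dam, birth_year) and topologically sort it.

    "0", empty or NA parents are treated as unknown.  Raises
    :class:`PedigreeError` on cycles (naming one individual on the cycle) and
    on duplicated ids.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"id", "sire", "dam", "birth_year"}
    if not required.issubset(df.columns):
        raise FormatError(f"pedigree file missing columns {required - set(df.columns)}")
    df = df.fillna("0")
    df.loc[df["sire"] == "", "sire"] = "0"
    df.loc[df["dam"] == "", "dam"] = "0"
    return build_pedigree(
        df["id"].tolist(), df["sire"].tolist(), df["dam"].tolist(),
        pd.to_numeric(df["birth_year"], errors="coerce").fillna(0).astype(int).tolist(),
    )


def build_pedigree(ids, sires, dams, birth_years) -> Pedigree:
    """Assemble and topologically order a pedigree from parallel columns."""
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise PedigreeError(f"duplicated individual id: {dup}")
    rec = {i: (s, d, y) for i, s, d, y in zip(ids, sires, dams, birth_years)}
    for i, (s, d, _) in rec.items():
        for p in (s, d):
            if p != "0" and p not in rec:
                raise PedigreeError(f"parent {p} of {i} has no record")
    order: list[str] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    for start in ids:
        if start in state:
            continue
        stack = [(start, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle detected at individual {node}")
            state[node] = 0
            stack.append((node, True))
            for p in rec[node][:2]:
                if p != "0" and state.get(p) != 1:
                    if state.get(p) == 0:
                        raise PedigreeError(f"pedigree cycle detected at individual {p}")
                    stack.append((p, False))
    df = pd.DataFrame(
        {
            "id": order,
            "sire": [rec[i][0] for i in order],
            "dam": [rec[i][1] for i in order],
            "birth_year": [int(rec[i][2]) for i in order],
        }
    )
    return Pedigree(records=df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ped.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Allele frequencies and marker filters
# ---------------------------------------------------------------------------

def compute_sample_af(g: GenotypeMatrix) -> AlleleFrequencySet:
    """A1 frequency = mean dosage over non-missing calls / 2, per marker."""
    d = g.dosages
    obs = d != MISSING
    counts = obs.sum(axis=0)
    if np.any(counts == 0):
        bad = g.markers["snp_id"].iloc[np.flatnonzero(counts == 0)].tolist()
        raise ValueError(f"markers with no non-missing calls: {bad[:10]}")
    p = np.where(obs, d, 0).sum(axis=0) / (2.0 * counts)
    return AlleleFrequencySet(frequencies=p, source="sample")


def filter_by_maf(
    g: GenotypeMatrix, af: AlleleFrequencySet, threshold: float = 0.01
) -> tuple[GenotypeMatrix, AlleleFrequencySet]:
    """Drop markers with min(p, 1-p) < threshold; subset metadata consistently."""
    if not 0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    if len(af) != g.n_markers:
        raise ValueError("AF length does not match marker count")
    p = af.frequencies
    keep = np.minimum(p, 1 - p) >= threshold
    if not keep.any():
        raise ValueError("MAF filter removed every marker")
    kept_idx = np.flatnonzero(keep)
    return g.subset_markers(kept_idx), AlleleFrequencySet(p[kept_idx], af.source)


def filter_by_hwe(
    g: GenotypeMatrix, af: AlleleFrequencySet, p_threshold: float = 0.001
) -> tuple[GenotypeMatrix, AlleleFrequencySet]:
    """Optional chi-square Hardy-Weinberg filter (default off in the pipeline)."""
    d = g.dosages
    keep = np.ones(g.n_markers, dtype=bool)
    for j in range(g.n_markers):
        col = d[:, j]
        col = col[col != MISSING]
        n = len(col)
        counts = np.array([(col == 2).sum(), (col == 1).sum(), (col == 0).sum()])
        p = af.frequencies[j]
        exp = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
        ok = exp > 0
        chi2 = ((counts[ok] - exp[ok]) ** 2 / exp[ok]).sum()
        keep[j] = stats.chi2.sf(chi2, df=1) > p_threshold
    kept_idx = np.flatnonzero(keep)
    if len(kept_idx) == 0:
        raise ValueError("HWE filter removed every marker")
    return g.subset_markers(kept_idx), AlleleFrequencySet(
        af.frequencies[kept_idx], af.source
    )
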