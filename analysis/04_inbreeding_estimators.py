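"""Six inbreeding estimators under both allele-frequency sources.

Tabulates F_PED, F_HET, F_UNI, F_GRM-1, F_GRM-2 and F_HBD per individual,
once with the estimated founder allele frequencies and once with the sample
frequencies; prints the cross-source correlation of each estimator (the
allele-frequency-sensitivity ranking) and the annual inbreeding trend by
birth year.

Usage: python analysis/04_inbreeding_estimators.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from idstrat.data_io import AlleleFrequencySet, compute_sample_af, filter_by_maf, read_pedigree, read_plink
from idstrat.estimators import annual_trend, inbreeding_table

sim = Path("results/simulated")
g = read_plink(sim / "cohort")
ped = read_pedigree(sim / "pedigree.csv")
saf = compute_sample_af(g)
g, saf = filter_by_maf(g, saf, 0.01)
founder = pd.read_csv("results/founder_af.tsv", sep="\t").set_index("snp_id")
founder = founder.loc[g.markers["snp_id"]]
keep = np.flatnonzero((founder["flag"] == "kept").to_numpy())
g = g.subset_markers(keep)
faf = AlleleFrequencySet(founder["founder_af"].to_numpy()[keep], "founder_estimated")
saf = AlleleFrequencySet(saf.frequencies[keep], "sample")

tabs = {}
for af, tag in ((faf, "founder"), (saf, "sample")):
    hbd = pd.read_csv(f"results/hbd_{tag}_af.tsv", sep="\t")
    tab = inbreeding_table(g, af, ped=ped, f_hbd=hbd["f_hbd"].to_numpy())
    tab.to_csv(f"results/inbreeding_{tag}_af.tsv", sep="\t")
    tabs[tag] = tab

print("cross-source correlation per estimator (founder vs sample AF):")
for col in ("f_het", "f_uni", "f_grm1", "f_grm2", "f_hbd"):
    c = np.corrcoef(tabs["founder"][col], tabs["sample"][col])[0, 1]
    print(f"  {col:7s} {c:.3f}")

trend = annual_trend(tabs["founder"], ped)
trend.to_csv("results/annual_trend.tsv", sep="\t", index=False)
print("\nannual trend (founder AF), percent F per birth year:")
for _, row in trend.iterrows():
    print(f"  {row['estimator']:7s} {row['slope_percent']:+.2f}")
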