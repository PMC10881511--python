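#!/usr/bin/env python
"""Windowed diversity and per-individual heterozygosity scans.

Computes pi and theta_W in non-overlapping 100-kb windows for every group,
Weir-Cockerham F_ST of each weed strain against the crop, and the
heterozygosity rate of every accession (recent hybrids stand out as
high-het outliers). Writes results/diversity/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from feralscan import divstats
from feralscan.core_io import make_windows, read_population_map, read_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "diversity"


def main() -> None:
    gm = read_vcf(ROOT / "cohort" / "cohort.vcf")
    pm = read_population_map(ROOT / "cohort" / "popmap.tsv")
    OUT.mkdir(parents=True, exist_ok=True)
    lengths = {c: int(gm.pos[gm.chrom == c].max()) for c in dict.fromkeys(gm.chrom)}
    wins = make_windows(lengths, 100_000)

    tab = pd.DataFrame({"chrom": [w[0] for w in wins],
                        "start": [w[1] for w in wins],
                        "end": [w[2] for w in wins]})
    for g in pm.groups:
        samples = pm.samples_in_group(g)
        tab[f"pi_{g}"] = divstats.window_pi(gm, samples, wins)
        tab[f"theta_w_{g}"] = divstats.window_theta_w(gm, samples, wins)
    for g in ("weed_dedom", "weed_intro"):
        tab[f"fst_crop_{g}"] = divstats.wc_fst(
            gm, pm.samples_in_group("crop"), pm.samples_in_group(g), wins)
    with open(OUT / "windows.tsv", "w") as fh:
        fh.write("# 100-kb windowed diversity scan; windows 0-based half-open\n")
        tab.to_csv(fh, sep="\t", index=False, na_rep="NA")

    het = []
    for s in pm.samples:
        r = divstats.heterozygosity_rate(gm, s)
        het.append((s, pm.group_of(s), r.n_variant_sites, r.n_het,
                    r.het_rate if r.het_rate is not None else np.nan))
    het = pd.DataFrame(het, columns=["sample", "group", "n_variant_sites",
                                     "n_het", "het_rate"])
    with open(OUT / "het_per_sample.tsv", "w") as fh:
        fh.write("# heterozygous fraction of each individual's variant sites\n")
        het.to_csv(fh, sep="\t", index=False, na_rep="NA")

    print("genome-wide mean pi per group:")
    for g in pm.groups:
        print(f"  {g:12s} {tab[f'pi_{g}'].mean():.5f} /bp")
    med = het.groupby("group").het_rate.median()
    print("median het rate per group:")
    print(med.to_string())
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
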