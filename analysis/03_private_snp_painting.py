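#!/usr/bin/env python
"""Private-SNP ancestry analysis of the weed strains.

Classifies each SNP as crop-specific / wild-specific / shared against the
two reference panels, computes windowed crop:wild private-allele log-ratios
per strain, paints each weed sample's chromosomes, compares wild-like
blocks with the simulator's tract truth (Jaccard), and genotypes the
diagnostic domestication loci. Writes results/introgression/.
"""

import collections
from pathlib import Path

import numpy as np
import pandas as pd

from feralscan.core_io import make_windows, read_bed, read_population_map, read_vcf, write_bed
from feralscan.introgression import (
    classify_private_snps, genomewide_private_ratio, genotype_diagnostic_loci,
    jaccard_wild_blocks, paint_chromosomes, window_private_ratio,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "introgression"


def truth_wild_tracts(path):
    out = collections.defaultdict(list)
    for chrom, s, e, name, origin in read_bed(path):
        sample, hap = name.rsplit("/", 1)
        if origin == "wild" and hap == "0":
            out[sample].append((chrom, s, e))
    return out


def main() -> None:
    gm = read_vcf(ROOT / "cohort" / "cohort.vcf")
    pm = read_population_map(ROOT / "cohort" / "popmap.tsv")
    OUT.mkdir(parents=True, exist_ok=True)
    lengths = {c: int(gm.pos[gm.chrom == c].max()) for c in dict.fromkeys(gm.chrom)}
    wins = make_windows(lengths, 100_000)
    crop, wild = pm.samples_in_group("crop"), pm.samples_in_group("wild")

    classes = classify_private_snps(gm, crop, wild)
    counts = collections.Counter(classes)
    print("site classes:", dict(counts))

    tracts = truth_wild_tracts(ROOT / "cohort" / "truth_tracts.bed")
    weed_groups = [g for g in pm.groups if pm.entries[pm.samples_in_group(g)[0]][1] == "weed"]
    summary = []
    for g in weed_groups:
        samples = pm.samples_in_group(g)
        tab = window_private_ratio(classes, gm, samples, wins)
        with open(OUT / f"private_ratio_windows_{g}.tsv", "w") as fh:
            fh.write(f"# crop:wild private-allele copies per 100-kb window, {g}\n")
            tab.to_csv(fh, sep="\t", index=False, na_rep="NA")
        for s in samples:
            track = paint_chromosomes(classes, gm, s, wins)
            rows = []
            for which in ("wild_like", "crop_like", "mixed"):
                rows += [(c, a, b, which) for c, a, b in track.blocks(which)]
            write_bed(sorted(rows), OUT / f"painting_{s}.bed",
                      header="window-vote ancestry painting")
            jac = (jaccard_wild_blocks(track, tracts.get(s, []))
                   if s in tracts or track.called_bases("wild_like") else None)
            _, _, ratio = genomewide_private_ratio(classes, gm, [s])
            summary.append((s, g, ratio,
                            track.called_bases("wild_like") / 1e6,
                            jac))
    summary = pd.DataFrame(summary, columns=[
        "sample", "group", "crop_wild_ratio", "wild_like_mb", "jaccard_vs_truth"])
    with open(OUT / "painting_summary.tsv", "w") as fh:
        fh.write("# per-sample private-allele ratio and painting summary\n")
        summary.to_csv(fh, sep="\t", index=False, na_rep="NA")
    for g in weed_groups:
        sub = summary[summary.group == g]
        print(f"{g}: median crop:wild ratio "
              f"{np.median(sub.crop_wild_ratio):.3g}, "
              f"median wild-like Mb {sub.wild_like_mb.median():.2f}")
    intro = summary[summary.group == "weed_intro"].jaccard_vs_truth.dropna()
    if len(intro):
        print(f"introgressed painting vs truth: median Jaccard {intro.median():.3f}")

    loci_path = ROOT / "cohort" / "diagnostic_loci.tsv"
    loci = []
    for line in loci_path.read_text().splitlines()[1:]:
        g_, c_, p_, ca, wa = line.split("\t")
        loci.append((g_, c_, int(p_), ca, wa))
    calls = genotype_diagnostic_loci(gm, loci)
    calls["group"] = [pm.group_of(s) for s in calls["sample"]]
    with open(OUT / "diagnostic_calls.tsv", "w") as fh:
        fh.write("# diagnostic domestication-locus genotype calls\n")
        calls.to_csv(fh, sep="\t", index=False)
    pivot = (calls[calls.group.isin(weed_groups + ["crop", "wild"])]
             .groupby(["group", "call"]).size().unstack(fill_value=0))
    print("diagnostic-locus calls by group:")
    print(pivot.to_string())
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
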