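#!/usr/bin/env python
"""Neighbor-joining phylogeny of the cohort.

Builds the NJ tree on homozygous, complete-data SNPs with Jukes-Cantor
distances and 100 bootstrap replicates, roots it with the outgroup, and
reports where the weed strains attach. Recent F1 hybrids are excluded: they
are heterozygous at every crop/wild diagnostic site, so the homozygous-site
filter cannot place them. Writes results/tree/.
"""

from pathlib import Path

from feralscan import treebuild as tb
from feralscan.core_io import read_population_map, read_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "tree"


def main() -> None:
    gm = read_vcf(ROOT / "cohort" / "cohort.vcf")
    pm = read_population_map(ROOT / "cohort" / "popmap.tsv")
    OUT.mkdir(parents=True, exist_ok=True)
    f1 = set(pm.samples_in_group("weed_f1"))
    keep = [s for s in gm.sample_ids if s not in f1]
    sub = gm.subset_samples(keep)
    sel = tb.select_tree_sites(sub)
    print(f"tree sites (homozygous, complete): {sel.n_sites} of {gm.n_sites}")

    tree = tb.bootstrap_support(sub, B=100, seed=17, model="jc")
    rooted = tb.root_with_outgroup(tree, pm.samples_in_group("outgroup"))
    tb.write_newick(rooted, OUT / "nj_tree.nwk")

    crop = set(pm.samples_in_group("crop"))
    dedom = set(pm.samples_in_group("weed_dedom"))
    wild = set(pm.samples_in_group("wild"))
    clade = tb.smallest_clade_containing(rooted, crop)
    names = clade.leaf_names()
    print(f"smallest clade containing all crop: {len(names)} leaves; "
          f"contains all de-domesticated weeds: {dedom <= names}; "
          f"wild samples inside: {len(wild & names)}")
    sup = tb.clade_support(sub, crop | dedom, wild, B=100, seed=17)
    print(f"bootstrap support for a crop+de-domesticated clade excluding "
          f"wild: {sup:.0f}%")
    intro_in = sum(s in names for s in pm.samples_in_group("weed_intro"))
    print(f"introgressed weeds inside the crop clade: {intro_in} "
          f"of {len(pm.samples_in_group('weed_intro'))} "
          "(the rest attach between crop and wild)")
    print(f"-> {OUT / 'nj_tree.nwk'}")


if __name__ == "__main__":
    main()
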