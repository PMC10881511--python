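# feralscan

Population-genomic scans for detecting wild-relative introgression and
selection in feral (weedy) derivatives of a selfing crop.

Weedy relatives of crops arise in two ways: directly from the crop by
de-domestication, or through hybridization with a reproductively compatible
wild progenitor. Where crop, weed and wild taxa co-occur, telling these
origins apart — and finding the genomic regions selection has acted on —
requires a battery of scans over a multi-sample SNP matrix. `feralscan`
implements that battery as a reusable library with a CLI, exercised
end-to-end on a bundled cohort simulator with exact ancestry truth:

* **Private-SNP ancestry painting** — classify each SNP's alternate allele
  as crop-specific, wild-specific or shared between the two reference
  panels; count the class-specific allele copies a weed carries per 100-kb
  window; call windows crop-like / wild-like / mixed and merge them into
  ancestry blocks. Genome-wide crop:wild copy ratios separate de-domesticated
  weeds (ratio ≫ 1) from wild-introgressed ones (ratio ≲ 1).
* **Windowed diversity scans** — per-site pairwise diversity
  π = 2j(n−j)/(n(n−1)) and Watterson's θ_W = S/(a_{n−1}L) in non-overlapping
  100-kb windows; per-individual heterozygosity rate (high-het individuals
  flag recent hybridization); Weir–Cockerham (1984) F\_ST with windows
  aggregated as ratios of summed a, b, c variance components.
* **Selection scans** — the π_crop/π_weed ratio scan with top-5% windows
  flagged as low-nucleotide-diversity-region (LNDR) candidates, and a
  SweepFinder/SweeD-style composite likelihood ratio (CLR) scan on 2000 grid
  positions per chromosome, using the star-like hitchhiking model in which a
  lineage at distance d escapes the sweep with probability 1 − exp(−λd).
* **Diagnostic domestication loci** — genotype calls (crop / wild / het) at
  trait loci of the *PROG1* / *sh4* / *OsLG1* kind, where allele origin
  diagnoses local ancestry.
* **Phylogeny** — neighbor-joining on homozygous complete-data SNPs with
  Jukes–Cantor distances, site-resampling bootstrap supports and outgroup
  rooting.
* **Candidate sharing** — overlap of candidate windows across weed strains
  and gene-annotation intersection.

## Worked example

The analysis is organized as numbered drivers over a simulated cohort
(20 wild, 24 crop, 8 de-domesticated weeds, 8 introgressed weeds, 3 F1
hybrids, 2 outgroup samples on two 5-Mb chromosomes; one 400-kb sweep
injected into the de-domesticated strain):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_diversity_het_scans.py
python analysis/03_private_snp_painting.py
python analysis/04_sweep_scans.py
python analysis/05_phylogeny.py
python analysis/06_shared_candidates.py
```

Output of the painting and sweep stages (seed 17):

```
site classes: {'wild_specific': 114772, 'shared': 97882, 'crop_specific': 10304, ...}
weed_dedom: median crop:wild ratio inf, median wild-like Mb 0.00
weed_intro: median crop:wild ratio 1.06, median wild-like Mb 2.95
introgressed painting vs truth: median Jaccard 0.932

weed_dedom: 4 LNDR candidate windows; max CLR 1596.2
  true sweep chr1:2300000-2700000 -> CLR argmax at 2.494 Mb (CLR=1596.2), 6 kb from center
```

Reading: de-domesticated weeds carry essentially no wild-private alleles
(infinite crop:wild ratio, zero wild-like painting), while introgressed
weeds carry ~3 Mb of wild-like blocks per genome that match the true
simulated tracts with Jaccard 0.93; the CLR scan lands 6 kb from the true
sweep center, and the LNDR candidates are exactly the sweep-core windows.
The phylogeny stage places every de-domesticated weed inside the crop clade
(bootstrap 100%) and every introgressed weed between the crop and wild
clades.

The same operations are available as a CLI on any VCF + population map:

```bash
feralscan simulate --out-dir fixtures/ --seed 17
feralscan diversity --vcf cohort.vcf --popmap popmap.tsv \
    --crop-group crop --weed-group weed_dedom --out-dir out/
feralscan sweep --vcf cohort.vcf --popmap popmap.tsv --group weed_dedom \
    --out-dir out/ --unfolded
feralscan tree --vcf cohort.vcf --popmap popmap.tsv \
    --outgroup-group outgroup --out-dir out/
```

## Layout

```
src/feralscan/     library: core_io, simdata, divstats, introgression,
                   sweepscan, treebuild, candidates, cli
analysis/          numbered narrative drivers writing under results/
scripts/           acceptance.py (end-to-end reproduction)
tests/             pytest suite with brute-force oracles
docs/methods.md    model and design notes
```
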