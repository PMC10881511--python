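# Methods

## Scope and data model

All analyses operate on a dense diploid genotype matrix over biallelic SNPs
(codes 0/1/2/−1 for hom-ref / het / hom-alt / missing), read from VCF.
Upstream read mapping and variant calling are out of scope; per-genotype
quality control is abstracted as optional GQ/DP thresholds at VCF ingestion
(calls failing a threshold become missing; raising a threshold can only
remove calls). Sites are 1-based (VCF convention); windows and BED
intervals are 0-based half-open. Half-calls (`0/.`) are treated as missing;
haploid calls are promoted to homozygous diploid with a warning.

## Diversity statistics

* **π** per site is the unbiased mean pairwise difference
  2j(n−j)/(n(n−1)), with j the alternate-allele count and n the number of
  non-missing alleles at that site. Window π sums the per-site values and
  divides by the full window length, i.e. all bases are assumed callable
  (the common VCF-based convention). Per-site n varies with missingness.
* **θ_W** per window is S/(a_{n−1}·L) with S the number of segregating
  sites among the selected samples. Because n varies by site, one n must be
  chosen for the harmonic number; the window median is used (a stable,
  documented choice — alternatives differ only when missingness is very
  uneven).
* **Heterozygosity rate** of an individual is het calls / (het + hom-alt
  calls): the fraction of an individual's variant sites that are
  heterozygous. In predominantly selfing taxa this is near zero; values
  orders of magnitude higher flag recent outcrossing.
* **F_ST** is the two-population Weir–Cockerham (1984) estimator. The a, b,
  c variance components are computed per site from sample sizes, allele
  frequencies and observed heterozygote frequencies; windows aggregate as
  Σa / Σ(a+b+c) (ratio of sums — the standard, stable weighting). Sites
  monomorphic across both populations, or with fewer than one genotyped
  individual per side, are skipped; a window with no usable site is NaN.
  Estimates can be negative for undifferentiated pairs.
* **π-ratio (LNDR) scan**: π_crop/π_weed per window; ratios > 1 mean the
  weed lost diversity relative to its crop ancestor. Windows are eligible
  when both groups have ≥ `min_snps` (default 10) SNPs and π_weed > 0; the
  top ⌈0.05·N_eligible⌉ eligible windows (ties included) are sweep
  candidates. The SNP floor guards against empty windows dominating the
  top quantile.

## Private-SNP classification and painting

A site's alternate allele is *crop-specific* when carried by at least
`min_carriers` (default 1) allele copies among non-missing crop-panel calls
and by none in the wild panel, and vice versa; present in both → shared;
present in neither, or either panel missing more than `max_missing_frac` of
its calls → uninformative. The four labels partition all sites, and
swapping the panels swaps the two specific labels exactly.

Windowed ratios and painting count **allele copies** (het = 1, hom = 2)
rather than sites, so heterozygous recent hybrids contribute
proportionally; a site-counting switch is provided. Log-ratios use base 2.
Painting calls a window wild-like when the wild fraction of informative
copies f = n_wild/(n_wild+n_crop) is ≥ 0.8, crop-like when f ≤ 0.2, mixed
between, undetermined below 10 informative copies; adjacent same-call
windows merge into blocks. The 0.8/10 defaults are validated on simulated
truth (median Jaccard ≈ 0.9 against known tracts at the default scenario)
rather than derived from first principles. No HMM smoothing is applied —
window voting matches the granularity of the scans this package mirrors.

Diagnostic domestication loci are genotyped by exact (chrom, pos) match
with allele-orientation checking; a position absent from the matrix, or
with mismatched alleles, yields "absent" (with a warning for mismatches).

## CLR sweep scan

The background model draws each polymorphic site's derived (or minor)
allele count from the genome-wide empirical spectrum Φ; sites with missing
calls are projected to the modal allele number by hypergeometric
expectation. The sweep model at distance d from a grid position is the
star-like hitchhiking approximation: each of n lineages escapes with
probability p_e = 1 − exp(−λd); B ~ Binomial(n, p_e) lineages escape, the
n − B trapped lineages coalesce into one ancestor, the B+1 ancestral
lineages draw a configuration from Φ projected to B+1, and the trapped
ancestor's allele is copied to all trapped lineages. Probabilities are
renormalized over polymorphic outcomes; folded spectra are handled by
symmetric unfolding and refolding. The model is verified against exhaustive
enumeration for n ≤ 8 (1e−12) and satisfies the limits p_e → 1 ⇒ background
and λ → ∞ ⇒ background.

CLR(g) = 2·[max_λ Σ_sites ln P_sweep − Σ_sites ln Φ], maximized over 20
log-spaced λ spanning p_e(1 bp) ≈ 1e−6 to p_e(10 kb) ≈ 0.99 plus a
background sentinel (p_e ≡ 1), which guarantees CLR ≥ 0 and CLR ≡ 0 when
only the sentinel is supplied. Grid positions are the centers of 2000 equal
partitions per chromosome (evaluation positions, in the style of SweeD's
grid semantics). Monomorphic sites and fixed substitutions are excluded
(polymorphic-only likelihood).

Numerics: the default scan bins site positions at 5 kb and grid-to-site
distances into 300 log-spaced bins, precomputing the class-probability
kernel per (λ, distance-bin); sites with p_e > 0.9999 contribute the
background value exactly. The background term is always exact, so the
sentinel identities hold bit-exactly; binned CLR values track the exact
per-site scan (available as `method="exact"`) well within the smoothness
scale of the statistic, and localization error at the default scenario is
a few kb against a 250-kb tolerance. Sites whose allele number differs
from the modal n are dropped by the binned path (complete synthetic data
are unaffected; the exact path handles varying n).

**Permutation null.** `permutation_null_max` shuffles which allele count
sits at which position and returns the max-CLR distribution. This null is
exchangeable only for spatially unstructured data; a real chromosome of a
selfing, few-founder strain has long haplotype blocks that cluster rare
alleles, and its observed max CLR exceeds the permutation null a large
fraction of the time even without sweeps. Calibration checks therefore use
`simulate_sfs_sites` (positions uniform, counts iid from the background
spectrum), for which the observed scan is one draw from the permuted
ensemble by construction.

## Phylogeny

Tree sites are those homozygous and non-missing in every sample (each
sample contributes one base per site). Distances are mismatch fractions,
Jukes–Cantor-corrected by default (−(3/4)ln(1−4p/3)); the composite
likelihood pairwise distance of MEGA-style pipelines is deliberately not
reimplemented, since on biallelic SNP matrices the topology is driven by
mismatch fractions. NJ uses the Saitou–Nei Q-criterion; negative branch
lengths are clamped to zero with the deficit moved to the sister edge (sums
preserved), so additive matrices are recovered exactly. Bootstrap supports
resample sites with replacement (default B = 100; the multinomial weights
enter the distance computation directly) and report the percentage of
replicates containing each original bipartition; `clade_support` reports a
monophyly-style support (replicates in which *some* clade separates one
taxon set from another), which is robust to the unstable placement of taxa
intermediate between the two sides. Outgroup rooting splits the edge
separating a monophyletic outgroup at its midpoint and preserves total tree
length.

## The cohort simulator

The generator is a mosaic/copying simulator, not a coalescent: ancestry
tracts are recorded exactly and runtimes are seconds. All randomness flows
through one numpy PCG64 generator (`default_rng(seed)`); a fixed seed
reproduces byte-identical output files.

* **Wild panel.** Segregating sites are placed per contig as
  Poisson(θ_wild·a_{H−1}·L) with derived counts drawn from the neutral SFS
  (P(i) ∝ 1/i) over the H pool haplotypes; the reference allele is ancestral
  throughout. By construction the Watterson estimator of any subsample is
  unbiased (measured: within 0.1% at the default scenario, averaged over 50
  windows). The pool holds 2·n_wild panel haplotypes plus
  `crop_bottleneck_k` extra haplotypes that found the crop but are *not*
  emitted as samples — unsampled wild ancestors, so that founder alleles
  can legitimately be absent from the sampled wild panel. Wild accessions
  are outbred (random haplotype pairs); this keeps the SFS and Watterson
  contracts exact but makes wild individuals heterozygous at common sites,
  unlike the highly selfing wild accessions of real panels — consequences
  below.
* **Crop.** Founded by k = 4 founder haplotypes used with equal
  probability; individuals are founder crossover mosaics (Poisson crossovers
  at 1 per 10 Mb per gamete) selfed for 10 generations (marginal
  heterozygosity halves each generation). Expected crop π is
  (1−1/k)·θ_wild plus the domestication branch: segregating branch
  mutations at θ = 2e−4/bp (young branch, few segregating mutations) and
  crop-fixed domestication variants at 2e−4/bp, both absent from wild.
  Earlier design iterations used more founders with skewed usage; rare
  founders then carried haplotype segments absent from the sampled crop
  panel that masqueraded as wild-like introgression on de-domesticated
  controls, so the equal-usage k=4 bottleneck is the default.
* **Weed strains.** Each strain is founded by 4 fresh crop individuals
  (not among the sampled crop accessions — weeds descend from unsampled
  cultivars). De-domesticated weeds self from a founder for 5 further
  generations. Introgressed weeds receive wild tracts from an alternating
  exponential renewal process (mean tract 600 kb, stationary coverage 0.3),
  copied onto both haplotypes from random wild panel haplotypes, then
  selfed — both haplotypes share the tract structure, so selfing
  recombination never blurs the recorded truth. F1 hybrids are one crop
  gamete plus one wild gamete, unselfed. Truth tracts are stored per
  haplotype (an F1's two haplotypes have different origins); for selfed
  weeds both haplotypes agree and a per-sample view is exact.
* **Sweeps.** Inside the swept interval every target-strain haplotype is
  replaced by one randomly chosen strain haplotype; the wipe probability
  decays linearly over a 50-kb flank; new singleton mutations are sprinkled
  into the core at Poisson(θ_wild·L_core/10). The default scenario places
  one 400-kb sweep at the center of chr1 in the de-domesticated strain;
  chr2 is sweep-free and serves as a negative control.
* **Outgroup.** Two identical accessions carrying fixed derived alleles at
  private sites (5e−4/bp), hom-ref elsewhere — a clean rooting taxon.

Default cohort: two 5-Mb chromosomes, θ_wild = 0.005/bp, 20 wild, 24 crop,
8 + 8 + 3 weeds, 2 outgroup (~230k SNPs, ~65 samples) — a desk-scale
analogue of a 217-genome resequencing study, with the crop panel larger
than the wild panel as in such studies (a thin crop panel inflates spurious
wild-specific calls). Measured at these conditions: π_wild ≈ 0.0050,
π_crop ≈ 0.0037, π_dedom ≈ 0.0020 < π_intro ≈ 0.0036 < π_crop, F1
heterozygosity ~0.7 versus ~5e−4 for selfed weeds.

**What the simulator does not model**, hence what passing tests do not
show about real data: no coalescent genealogies or LD decay within
founder haplotypes; no selection besides the sweep wipe-out; no gene
conversion or mutation-rate heterogeneity; no genotyping error or
missingness (missing-data paths are exercised by dedicated unit fixtures
instead); wild accessions outbred rather than selfing; ancestral alleles
known exactly (real data would use the folded spectrum, which is the scan
default). One knock-on effect is documented above and in the analysis
drivers: because outbred wild individuals are heterozygous at most common
sites, the homozygous-complete-site filter of the tree stage deletes every
crop/wild fixed difference whenever F1 hybrids are included, so tree
analyses exclude the F1 strain; real panels of selfing accessions do not
have this degeneracy.

## Degenerate inputs and tie-breaking

Windows without SNPs have π = θ_W = 0 and undefined F_ST/ratios (flagged,
never silently zero where a ratio is meant); a sample with no variant sites
has an undefined heterozygosity rate; π-ratio ties at the top-quantile
threshold are all included; NJ ties in the Q matrix resolve to the smallest
index pair (deterministic); the CLR λ-argmax reports the sentinel (∞) when
no finite λ beats the background. Watterson's a_{n−1} uses the
window-median allele number; `site_pi` requires n ≥ 2 and skips sites
below it.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run ten replicate cohorts at the
default scenario for the multi-seed checks (sweep localization within
250 kb, ≥ 8/10; iid-background null calibration ≥ 9/10 at 49 permutations;
painting Jaccard over 80 introgressed weeds; ratio directionality; LNDR
recall of sweep-core windows; crop-clade bootstrap support at B = 100), 50
random small matrices (≤ 10 samples, ≤ 200 sites) for the brute-force
oracle equivalence of π/θ_W/F_ST at 1e−10, and exhaustive enumeration at
n ≤ 8 for the sweep model at 1e−12.
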