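#!/usr/bin/env python
"""Generate the study cohort: wild panel, bottlenecked crop, three weed
strains (de-domesticated, wild-introgressed, F1 hybrids) and an outgroup,
with ancestry-tract and sweep truth files.

Writes results/cohort/{cohort.vcf, popmap.tsv, truth_*.bed, truth_params.json,
diagnostic_loci.tsv}.
"""

from pathlib import Path

from feralscan.simdata import ScenarioConfig, emit_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = ScenarioConfig(seed=17)
    cohort = emit_cohort(cfg, out_dir=OUT)
    gm, pm = cohort.gm, cohort.popmap
    print(f"cohort: {gm.n_samples} samples x {gm.n_sites} biallelic SNPs "
          f"on {len(cfg.contig_lengths)} chromosomes")
    for g in pm.groups:
        print(f"  {g:12s} n={len(pm.samples_in_group(g))}")
    print(f"sweep truth: {cfg.sweep_intervals}")
    print(f"diagnostic loci: {[l[0] for l in cohort.diagnostic_loci]}")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
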