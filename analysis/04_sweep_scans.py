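#!/usr/bin/env python
"""Selection scans on the weed strains.

Runs the pi_crop/pi_weed (LNDR) scan with top-5% candidate flagging and the
composite likelihood ratio (CLR) sweep scan on a 2000-point grid per
chromosome for each selfed weed strain, then checks the CLR peak against
the simulated sweep truth. Writes results/sweeps/.
"""

import json
from pathlib import Path

from feralscan import divstats
from feralscan.core_io import make_windows, read_bed, read_population_map, read_vcf, write_bed
from feralscan.sweepscan import clr_scan

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "sweeps"


def main() -> None:
    gm = read_vcf(ROOT / "cohort" / "cohort.vcf")
    pm = read_population_map(ROOT / "cohort" / "popmap.tsv")
    OUT.mkdir(parents=True, exist_ok=True)
    lengths = {c: int(gm.pos[gm.chrom == c].max()) for c in dict.fromkeys(gm.chrom)}
    params = json.loads((ROOT / "cohort" / "truth_params.json").read_text())
    lengths.update({k: int(v) for k, v in
                    params["config"]["contig_lengths"].items()})
    wins = make_windows(lengths, 100_000)
    crop = pm.samples_in_group("crop")
    sweeps = read_bed(ROOT / "cohort" / "truth_sweeps.bed")

    for g in ("weed_dedom", "weed_intro"):
        samples = pm.samples_in_group(g)
        tab = divstats.pi_ratio_scan(gm, crop, samples, wins)
        with open(OUT / f"lndr_windows_{g}.tsv", "w") as fh:
            fh.write(f"# pi_crop/pi_weed scan, top-5% candidates, {g}\n")
            tab.to_csv(fh, sep="\t", index=False, na_rep="NA")
        cand = tab[tab.is_candidate]
        write_bed([(r.chrom, r.start, r.end) for r in cand.itertuples()],
                  OUT / f"lndr_candidates_{g}.bed",
                  header=f"top-5% pi-ratio windows, {g}")
        scan = clr_scan(gm, samples, contig_lengths=lengths, folded=False)
        with open(OUT / f"clr_{g}.tsv", "w") as fh:
            fh.write(f"# CLR sweep scan, 2000 grid points/chromosome, {g}\n")
            scan.table.to_csv(fh, sep="\t", index=False)
        print(f"{g}: {len(cand)} LNDR candidate windows; "
              f"max CLR {scan.max_clr():.1f}")
        for chrom, lo, hi, target in sweeps:
            if target != g:
                continue
            pos, clr = scan.argmax_position(chrom)
            print(f"  true sweep {chrom}:{lo}-{hi} -> CLR argmax at "
                  f"{pos/1e6:.3f} Mb (CLR={clr:.1f}), "
                  f"{abs(pos-(lo+hi)/2)/1e3:.0f} kb from center")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
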