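#!/usr/bin/env python
"""Cross-strain sharing of selection-candidate windows and gene content.

Overlaps the top-5% LNDR candidate windows of the two selfed weed strains
(identical 100-kb tiling), and intersects the shared windows with a gene
annotation. The annotation here is a synthetic gene map (one ~3-kb gene
every ~8 kb) generated alongside the cohort, standing in for a real GFF3.
Writes results/candidates/.
"""

from pathlib import Path

import numpy as np

from feralscan.candidates import CandidateSet, genes_in_regions, overlap_candidates
from feralscan.core_io import read_bed, read_gff3_genes, write_bed

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "candidates"


def write_synthetic_gff3(path: Path, contig_lengths: dict, seed: int = 17) -> None:
    """Synthetic gene annotation: uniformly spaced genes with jitter."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        i = 0
        for chrom, L in contig_lengths.items():
            pos = 1000
            while pos + 3000 < L:
                i += 1
                start = pos + int(rng.integers(0, 2000))
                end = start + int(rng.integers(1500, 4000))
                fh.write(f"{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\t"
                         f"ID=gene{i:05d}\n")
                pos = end + int(rng.integers(2000, 6000))


def main() -> None:
    import json
    OUT.mkdir(parents=True, exist_ok=True)
    params = json.loads((ROOT / "cohort" / "truth_params.json").read_text())
    contigs = {k: int(v) for k, v in params["config"]["contig_lengths"].items()}

    sets = []
    for g in ("weed_dedom", "weed_intro"):
        rows = read_bed(ROOT / "sweeps" / f"lndr_candidates_{g}.bed")
        sets.append(CandidateSet(g, {(c, s, e) for c, s, e, *_ in rows}))
        print(f"{g}: {len(sets[-1].windows)} candidate windows")
    shared = overlap_candidates(sets, min_strains=2)
    write_bed([tuple(r) for r in shared.itertuples(index=False)],
              OUT / "shared_windows.bed",
              header="LNDR windows shared by both weed strains")
    print(f"windows shared by both strains: {len(shared)}")

    gff = OUT / "synthetic_genes.gff3"
    write_synthetic_gff3(gff, contigs)
    genes = read_gff3_genes(gff)
    union = sorted(set().union(*(s.windows for s in sets)))
    hits = genes_in_regions(union, genes)
    with open(OUT / "candidate_genes.tsv", "w") as fh:
        fh.write("# genes overlapping any strain's LNDR candidate windows\n")
        hits.to_csv(fh, sep="\t", index=False)
    shared_hits = genes_in_regions(
        [(r.chrom, r.start, r.end) for r in shared.itertuples()], genes)
    print(f"genes in candidate windows: {len(hits)} "
          f"(in shared windows: {len(shared_hits)})")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
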