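"""Cross-strain sharing of candidate windows and gene intersection.

Candidate windows (from pi-ratio or CLR scans on a shared window tiling)
are compared across weed strains by identical window identity; genomic
regions are intersected with gene annotations using half-open interval
overlap (>= 1 bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass
class CandidateSet:
    strain: str
    windows: set  # of (chrom, start, end)


def overlap_candidates(sets: list[CandidateSet], min_strains: int = 2
                       ) -> pd.DataFrame:
    """Windows present in at least ``min_strains`` candidate sets.

    Returns a table (chrom, start, end, n_strains, strains) sorted by
    position; ``min_strains=1`` gives the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 candidate sets")
    if min_strains > len(sets):
        raise ValueError(
            f"min_strains={min_strains} exceeds number of sets {len(sets)}"
        )
    membership: dict[tuple, list[str]] = {}
    for cs in sets:
        for w in cs.windows:
            membership.setdefault(tuple(w), []).append(cs.strain)
    rows = [
        (c, s, e, len(strains), ",".join(sorted(strains)))
        for (c, s, e), strains in membership.items()
        if len(strains) >= min_strains
    ]
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_strains", "strains"])


def genes_in_regions(regions, genes) -> pd.DataFrame:
    """Genes overlapping any region by >= 1 bp (half-open intervals).

    ``regions``: iterable of (chrom, start, end); ``genes``: iterable of
    (chrom, start, end, gene_id) as produced by
    :func:`feralscan.core_io.read_gff3_genes`. Deduplicated, sorted.
    """
    regions = list(regions)
    genes = list(genes)
    region_chroms = {r[0] for r in regions}
    gene_chroms = {g[0] for g in genes}
    if regions and genes and not (region_chroms & gene_chroms):
        warnings.warn(
            "no chromosome name shared between regions and annotation; "
            "empty intersection",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["gene", "chrom", "start", "end",
                                     "overlap_start", "overlap_end"])
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in ((r[0], r[1], r[2]) for r in regions):
        by_chrom.setdefault(c, []).append((s, e))
    hits = {}
    for chrom, gs, ge, gid in genes:
        for rs, re in by_chrom.get(chrom, ()):
            if gs < re and rs < ge:
                os_, oe = max(gs, rs), min(ge, re)
                prev = hits.get((gid, chrom, gs, ge))
                if prev is None:
                    hits[(gid, chrom, gs, ge)] = (os_, oe)
                else:
                    hits[(gid, chrom, gs, ge)] = (min(prev[0], os_), max(prev[1], oe))
    rows = [
        (gid, chrom, gs, ge, os_, oe)
        for (gid, chrom, gs, ge), (os_, oe) in hits.items()
    ]
    rows.sort(key=lambda r: (r[1], r[2], r[0]))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "overlap_start", "overlap_end"])
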