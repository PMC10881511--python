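"""Private-SNP classification, chromosome painting and diagnostic loci.

A site's alternate allele is *private* to the crop panel when it is carried
by at least ``min_carriers`` allele copies among non-missing crop calls and
by none among wild calls (and vice versa). Windowed counts of the private
allele copies carried by a target sample (or strain) give the crop:wild
ratio scans and the per-window crop-like / wild-like ancestry painting.

Copies are counted per allele (het = 1, hom-alt = 2) so recent hybrids
contribute proportionally; ``count_sites=True`` restores site counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, WindowSet

SITE_CLASSES = ("crop_specific", "wild_specific", "shared", "uninformative")
PAINT_CALLS = ("crop_like", "wild_like", "mixed", "undetermined")


def classify_private_snps(gm: GenotypeMatrix, crop_samples: Sequence[str],
                          wild_samples: Sequence[str], min_carriers: int = 1,
                          max_missing_frac: float = 0.2) -> np.ndarray:
    """Per-site labels from {crop_specific, wild_specific, shared, uninformative}.

    A group "carries" the alternate allele when its non-missing calls hold at
    least ``min_carriers`` allele copies. Sites where either panel has a
    missing-call fraction above ``max_missing_frac``, or where neither panel
    carries the allele, are uninformative.
    """
    crop_set, wild_set = set(crop_samples), set(wild_samples)
    if not crop_set or not wild_set:
        raise ValueError("both panels must be non-empty")
    if crop_set & wild_set:
        raise ValueError(f"panels overlap: {sorted(crop_set & wild_set)}")
    gc = gm.geno[gm.sample_index(crop_samples)]
    gw = gm.geno[gm.sample_index(wild_samples)]
    miss_c = (gc < 0).mean(axis=0)
    miss_w = (gw < 0).mean(axis=0)
    copies_c = np.where(gc > 0, gc, 0).sum(axis=0)
    copies_w = np.where(gw > 0, gw, 0).sum(axis=0)
    in_c = copies_c >= min_carriers
    in_w = copies_w >= min_carriers
    labels = np.full(gm.n_sites, "uninformative", dtype=object)
    ok = (miss_c <= max_missing_frac) & (miss_w <= max_missing_frac)
    labels[ok & in_c & ~in_w] = "crop_specific"
    labels[ok & ~in_c & in_w] = "wild_specific"
    labels[ok & in_c & in_w] = "shared"
    return labels


def _target_copies(gm: GenotypeMatrix, target_samples: Sequence[str],
                   count_sites: bool) -> np.ndarray:
    g = gm.geno[gm.sample_index(target_samples)]
    if count_sites:
        return (g > 0).any(axis=0).astype(np.int64)
    return np.where(g > 0, g, 0).sum(axis=0).astype(np.int64)


def window_private_ratio(classes: np.ndarray, gm: GenotypeMatrix,
                         target_samples: Sequence[str], windows: WindowSet,
                         log_base: float = 2.0,
                         count_sites: bool = False) -> pd.DataFrame:
    """Windowed crop:wild private-allele counts and log-ratio for a target.

    The log-ratio is NaN (window flagged ``defined=False``) when either count
    is zero.
    """
    copies = _target_copies(gm, target_samples, count_sites)
    widx = windows.assign_sites(gm)
    ok = widx >= 0
    n_crop = np.bincount(
        widx[ok & (classes == "crop_specific")],
        weights=copies[ok & (classes == "crop_specific")],
        minlength=len(windows),
    ).astype(np.int64)
    n_wild = np.bincount(
        widx[ok & (classes == "wild_specific")],
        weights=copies[ok & (classes == "wild_specific")],
        minlength=len(windows),
    ).astype(np.int64)
    defined = (n_crop > 0) & (n_wild > 0)
    ratio = np.full(len(windows), np.nan)
    ratio[defined] = n_crop[defined] / n_wild[defined]
    log_ratio = np.full(len(windows), np.nan)
    log_ratio[defined] = np.log(ratio[defined]) / np.log(log_base)
    return pd.DataFrame(
        {
            "chrom": [w[0] for w in windows],
            "start": [w[1] for w in windows],
            "end": [w[2] for w in windows],
            "n_crop_copies": n_crop,
            "n_wild_copies": n_wild,
            "ratio": ratio,
            "log_ratio": log_ratio,
            "defined": defined,
        }
    )


def genomewide_private_ratio(classes: np.ndarray, gm: GenotypeMatrix,
                             target_samples: Sequence[str],
                             count_sites: bool = False) -> tuple[int, int, float]:
    """Total crop- and wild-private allele copies carried by a target.

    Returns (crop_copies, wild_copies, ratio); ratio is inf when no wild
    copies are carried.
    """
    copies = _target_copies(gm, target_samples, count_sites)
    n_crop = int(copies[classes == "crop_specific"].sum())
    n_wild = int(copies[classes == "wild_specific"].sum())
    ratio = n_crop / n_wild if n_wild > 0 else float("inf")
    return n_crop, n_wild, ratio


@dataclass
class PaintingTrack:
    """Per-window local-ancestry calls for one target sample."""

    sample: str
    windows: WindowSet
    n_crop: np.ndarray
    n_wild: np.ndarray
    call: np.ndarray  # object array over PAINT_CALLS

    def blocks(self, which: str = "wild_like") -> list[tuple[str, int, int]]:
        """Adjacent same-call windows merged into (chrom, start, end) blocks."""
        out: list[tuple[str, int, int]] = []
        for (chrom, s, e), c in zip(self.windows, self.call):
            if c != which:
                continue
            if out and out[-1][0] == chrom and out[-1][2] == s:
                out[-1] = (chrom, out[-1][1], e)
            else:
                out.append((chrom, s, e))
        return out

    def called_bases(self, which: str = "wild_like") -> int:
        return sum(e - s for _, s, e in self.blocks(which))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w[0] for w in self.windows],
                "start": [w[1] for w in self.windows],
                "end": [w[2] for w in self.windows],
                "n_crop_copies": self.n_crop,
                "n_wild_copies": self.n_wild,
                "call": self.call,
            }
        )


def paint_chromosomes(classes: np.ndarray, gm: GenotypeMatrix,
                      target_sample: str, windows: WindowSet,
                      wild_frac_threshold: float = 0.8,
                      min_informative: int = 10) -> PaintingTrack:
    """Window-vote chromosome painting of one sample against the two panels.

    With f = wild / (wild + crop) informative private-allele copies in a
    window, the call is wild_like when f >= threshold, crop_like when
    f <= 1 - threshold, mixed otherwise, and undetermined when fewer than
    ``min_informative`` copies are available.
    """
    tab = window_private_ratio(classes, gm, [target_sample], windows)
    n_crop = tab["n_crop_copies"].to_numpy()
    n_wild = tab["n_wild_copies"].to_numpy()
    total = n_crop + n_wild
    call = np.full(len(windows), "undetermined", dtype=object)
    det = total >= min_informative
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, n_wild / np.maximum(total, 1), np.nan)
    call[det & (f >= wild_frac_threshold)] = "wild_like"
    call[det & (f <= 1.0 - wild_frac_threshold)] = "crop_like"
    call[det & (f > 1.0 - wild_frac_threshold) & (f < wild_frac_threshold)] = "mixed"
    return PaintingTrack(target_sample, windows, n_crop, n_wild, call)


def genotype_diagnostic_loci(gm: GenotypeMatrix,
                             loci: Sequence[tuple[str, str, int, str, str]]
                             ) -> pd.DataFrame:
    """Call each sample at each diagnostic locus.

    ``loci`` rows are (gene, chrom, pos, crop_allele, wild_allele). Calls are
    from {crop, wild, het, missing, absent}: ``absent`` when the position is
    not in the matrix or its ref/alt pair does not match the locus alleles.
    """
    seen = set()
    for gene, chrom, pos, *_ in loci:
        key = (gene, chrom, pos)
        if key in seen:
            raise ValueError(f"duplicate diagnostic locus row {key}")
        seen.add(key)
    site_lookup = {(c, int(p)): j for j, (c, p) in enumerate(zip(gm.chrom, gm.pos))}
    records = []
    for gene, chrom, pos, crop_allele, wild_allele in loci:
        if crop_allele == wild_allele:
            raise ValueError(f"{gene}: crop and wild alleles identical")
        j = site_lookup.get((chrom, int(pos)))
        if j is None:
            for s in gm.sample_ids:
                records.append((gene, s, "absent"))
            continue
        pair = {gm.ref[j], gm.alt[j]}
        if pair != {crop_allele, wild_allele}:
            warnings.warn(
                f"{gene} at {chrom}:{pos}: VCF alleles {sorted(pair)} do not "
                f"match locus alleles; reporting 'absent'",
                stacklevel=2,
            )
            for s in gm.sample_ids:
                records.append((gene, s, "absent"))
            continue
        crop_is_alt = gm.alt[j] == crop_allele
        for s, g in zip(gm.sample_ids, gm.geno[:, j]):
            if g < 0:
                call = "missing"
            elif g == 1:
                call = "het"
            elif (g == 2) == crop_is_alt:
                call = "crop"
            else:
                call = "wild"
            records.append((gene, s, call))
    return pd.DataFrame(records, columns=["gene", "sample", "call"])


def jaccard_wild_blocks(track: PaintingTrack,
                        truth_tracts: Sequence[tuple[str, int, int]]) -> float:
    """Jaccard index between called wild-like bases and truth wild tracts."""
    def _to_mask_keys(intervals):
        return {(c, s, e) for c, s, e in intervals}

    called = track.blocks("wild_like")
    chroms = {c for c, _, _ in called} | {c for c, _, _ in truth_tracts}
    inter = union = 0
    for chrom in chroms:
        pts = sorted(
            {s for c, s, _ in called if c == chrom}
            | {e for c, _, e in called if c == chrom}
            | {s for c, s, _ in truth_tracts if c == chrom}
            | {e for c, _, e in truth_tracts if c == chrom}
        )
        for a, b in zip(pts[:-1], pts[1:]):
            in_called = any(s <= a and b <= e for c, s, e in called if c == chrom)
            in_truth = any(s <= a and b <= e for c, s, e in truth_tracts if c == chrom)
            if in_called and in_truth:
                inter += b - a
            if in_called or in_truth:
                union += b - a
    return inter / union if union else 1.0
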