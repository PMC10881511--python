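"""Windowed diversity, heterozygosity, differentiation and pi-ratio scans.

Statistics are computed over non-overlapping fixed-size windows (100 kb by
default elsewhere in the package). Window denominators use the full window
length, i.e. every base is assumed callable, matching the common VCF-based
convention; per-site allele numbers vary with missingness.

* pi      — unbiased per-site pairwise diversity 2 j (n - j) / (n (n - 1))
            summed over SNPs and divided by window length;
* theta_W — S / (a_{n-1} L), with ``n`` the window-median allele number;
* F_ST    — Weir & Cockerham (1984) two-population estimator, windows
            aggregated as ratio of sums of the a, b, c variance components;
* pi-ratio (LNDR scan) — pi_crop / pi_weed per window, top-quantile windows
            flagged as sweep candidates (ratios > 1 mean the weed lost
            diversity relative to its crop ancestor).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, WindowSet

__all__ = [
    "site_pi",
    "window_pi",
    "window_theta_w",
    "heterozygosity_rate",
    "wc_fst",
    "pi_ratio_scan",
    "HetReport",
]


def _counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alt allele count j and allele number n from genotype codes."""
    present = geno >= 0
    n = 2 * present.sum(axis=0)
    j = np.where(geno > 0, geno, 0).sum(axis=0)
    return j.astype(np.int64), n.astype(np.int64)


def site_pi(j: int, n: int) -> float:
    """Mean pairwise difference among n alleles with j alternate copies."""
    if n < 2:
        raise ValueError("site_pi needs n >= 2 alleles")
    if not 0 <= j <= n:
        raise ValueError(f"j={j} outside [0, {n}]")
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def _site_pi_vec(j: np.ndarray, n: np.ndarray) -> np.ndarray:
    out = np.zeros(len(j), dtype=np.float64)
    ok = n >= 2
    nn = n[ok].astype(np.float64)
    out[ok] = 2.0 * j[ok] * (n[ok] - j[ok]) / (nn * (nn - 1.0))
    return out


def window_pi(gm: GenotypeMatrix, samples: Sequence[str], windows: WindowSet
              ) -> np.ndarray:
    """Per-bp pairwise nucleotide diversity per window."""
    if len(samples) == 0:
        raise ValueError("empty sample set")
    sub = gm.geno[gm.sample_index(samples)]
    j, n = _counts(sub)
    per_site = _site_pi_vec(j, n)
    widx = windows.assign_sites(gm)
    ok = widx >= 0
    sums = np.bincount(widx[ok], weights=per_site[ok], minlength=len(windows))
    return sums / windows.lengths()


def window_theta_w(gm: GenotypeMatrix, samples: Sequence[str],
                   windows: WindowSet) -> np.ndarray:
    """Watterson's theta per bp per window.

    S counts sites segregating among the selected samples; the harmonic
    correction a_{n-1} uses the window-median per-site allele number (per-site
    numbers vary with missingness; the median is a stable single choice).
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    sub = gm.geno[gm.sample_index(samples)]
    j, n = _counts(sub)
    seg = (j > 0) & (j < n) & (n >= 2)
    widx = windows.assign_sites(gm)
    lengths = windows.lengths()
    theta = np.zeros(len(windows), dtype=np.float64)
    for w in range(len(windows)):
        m = (widx == w) & seg
        S = int(m.sum())
        if S == 0:
            continue
        n_med = int(np.median(n[m]))
        a = np.sum(1.0 / np.arange(1, n_med))
        theta[w] = S / (a * lengths[w])
    return theta


@dataclass
class HetReport:
    sample_id: str
    n_variant_sites: int
    n_het: int
    het_rate: float | None  # None when the sample carries no alt allele


def heterozygosity_rate(gm: GenotypeMatrix, sample: str) -> HetReport:
    """Fraction of an individual's variant (alt-carrying) sites that are het."""
    row = gm.geno[gm.sample_index([sample])[0]]
    n_var = int(((row == 1) | (row == 2)).sum())
    n_het = int((row == 1).sum())
    rate = n_het / n_var if n_var > 0 else None
    return HetReport(sample, n_var, n_het, rate)


def _wc_components(g1: np.ndarray, g2: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) a, b, c variance components (r=2).

    Returns (a, b, c, usable-mask); sites with < 2 alleles in either
    population or monomorphic across both are masked out.
    """
    n1 = (g1 >= 0).sum(axis=0).astype(np.float64)
    n2 = (g2 >= 0).sum(axis=0).astype(np.float64)
    j1 = np.where(g1 > 0, g1, 0).sum(axis=0).astype(np.float64)
    j2 = np.where(g2 > 0, g2, 0).sum(axis=0).astype(np.float64)
    h1c = (g1 == 1).sum(axis=0).astype(np.float64)
    h2c = (g2 == 1).sum(axis=0).astype(np.float64)
    usable = (n1 >= 1) & (n2 >= 1) & (2 * (n1 + n2) >= 4)
    jt = j1 + j2
    usable &= (jt > 0) & (jt < 2 * (n1 + n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = j1 / (2 * n1)
        p2 = j2 / (2 * n2)
        h1 = h1c / n1
        h2 = h2c / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    usable &= nbar > 1  # a,b undefined for single-individual pools
    for arr in (a, b, c):
        arr[~usable] = 0.0
    return a, b, c, usable


def wc_fst(gm: GenotypeMatrix, pop_a: Sequence[str], pop_b: Sequence[str],
           windows: WindowSet) -> np.ndarray:
    """Weir-Cockerham F_ST per window (ratio of sums over sites).

    Windows with no usable site are NaN. The per-window estimate can be
    negative for undifferentiated populations.
    """
    if len(pop_a) == 0 or len(pop_b) == 0:
        raise ValueError("both populations must be non-empty")
    g1 = gm.geno[gm.sample_index(pop_a)]
    g2 = gm.geno[gm.sample_index(pop_b)]
    a, b, c, usable = _wc_components(g1, g2)
    widx = windows.assign_sites(gm)
    ok = (widx >= 0) & usable
    num = np.bincount(widx[ok], weights=a[ok], minlength=len(windows))
    den = np.bincount(widx[ok], weights=(a + b + c)[ok], minlength=len(windows))
    has = np.bincount(widx[ok], minlength=len(windows)) > 0
    out = np.full(len(windows), np.nan)
    nz = has & (den != 0)
    out[nz] = num[nz] / den[nz]
    return out


def pi_ratio_scan(gm: GenotypeMatrix, crop_samples: Sequence[str],
                  weed_samples: Sequence[str], windows: WindowSet,
                  top_frac: float = 0.05, min_snps: int = 10) -> pd.DataFrame:
    """LNDR scan: pi_crop / pi_weed per window with top-quantile candidates.

    A window is eligible when both groups have >= ``min_snps`` SNPs in it and
    pi_weed > 0. Candidates are the top ``ceil(top_frac * n_eligible)``
    eligible windows by ratio; ties at the threshold are all included.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    if len(crop_samples) == 0 or len(weed_samples) == 0:
        raise ValueError("both groups must be non-empty")
    pi_c = window_pi(gm, crop_samples, windows)
    pi_w = window_pi(gm, weed_samples, windows)
    widx = windows.assign_sites(gm)

    def _snps(samples):
        sub = gm.geno[gm.sample_index(samples)]
        j, n = _counts(sub)
        seg = (j > 0) & (j < n) & (n >= 2)
        ok = (widx >= 0) & seg
        return np.bincount(widx[ok], minlength=len(windows))

    n_c = _snps(crop_samples)
    n_w = _snps(weed_samples)
    eligible = (n_c >= min_snps) & (n_w >= min_snps) & (pi_w > 0)
    ratio = np.full(len(windows), np.nan)
    ratio[eligible] = pi_c[eligible] / pi_w[eligible]
    is_candidate = np.zeros(len(windows), dtype=bool)
    n_el = int(eligible.sum())
    if n_el:
        k = ceil(top_frac * n_el)
        vals = np.sort(ratio[eligible])[::-1]
        thr = vals[min(k, n_el) - 1]
        is_candidate = eligible & (ratio >= thr)
    rows = pd.DataFrame(
        {
            "chrom": [w[0] for w in windows],
            "start": [w[1] for w in windows],
            "end": [w[2] for w in windows],
            "n_snps_crop": n_c,
            "n_snps_weed": n_w,
            "pi_crop": pi_c,
            "pi_weed": pi_w,
            "pi_ratio": ratio,
            "eligible": eligible,
            "is_candidate": is_candidate,
        }
    )
    return rows
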