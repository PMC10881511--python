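"""Composite likelihood ratio scan for selective sweeps.

At each position on a per-chromosome grid the scan compares two models of
the site frequency spectrum (SFS) at nearby polymorphic sites:

* background — each site draws its derived (or minor) allele count from the
  genome-wide empirical spectrum Phi;
* sweep — a star-like hitchhiking approximation: a lineage at distance
  ``d`` bp from the swept site escapes the sweep with probability
  ``p_e = 1 - exp(-lam * d)``; the ``B ~ Binomial(n, p_e)`` escaped lineages
  plus the single ancestor of all trapped lineages draw their configuration
  from Phi projected to ``B + 1`` lineages; the trapped ancestor's allele is
  then copied to all ``n - B`` trapped lineages. Probabilities are
  renormalized over polymorphic outcomes.

``lam`` is inversely related to sweep footprint: the maximizing value is
reported, and the grid always contains a background-equivalent sentinel
(``p_e = 1`` everywhere, i.e. lam = infinity) so that CLR >= 0.

The default scan aggregates sites into position bins and log-spaced
distance bins with a precomputed probability kernel (fast enough for
thousands of grid points and permutation nulls); ``method="exact"``
evaluates every site at its exact distance and per-site allele number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .core_io import GenotypeMatrix

PE_CUTOFF = 0.9999  # escape probability beyond which a site is background


# ---------------------------------------------------------------------------
# site frequency spectra
# ---------------------------------------------------------------------------


@dataclass
class SFS:
    """Normalized spectrum over polymorphic allele-count classes.

    Unfolded: derived counts 1..n-1. Folded: minor counts 1..n//2.
    """

    n: int
    probs: np.ndarray
    folded: bool

    def __post_init__(self) -> None:
        expect = self.n // 2 if self.folded else self.n - 1
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if len(self.probs) != expect:
            raise ValueError(
                f"probs length {len(self.probs)} != {expect} for n={self.n}"
            )
        if (self.probs < 0).any():
            raise ValueError("negative SFS mass")
        s = self.probs.sum()
        if not np.isclose(s, 1.0):
            raise ValueError("SFS probabilities must sum to 1")

    def class_of(self, k: int) -> int:
        """0-based class index of derived count k (folds if needed)."""
        kk = min(k, self.n - k) if self.folded else k
        return kk - 1


def fold_sfs(sfs: SFS) -> SFS:
    if sfs.folded:
        return sfs
    n = sfs.n
    full = np.zeros(n + 1)
    full[1:n] = sfs.probs
    out = np.array([full[k] + (full[n - k] if n - k != k else 0.0)
                    for k in range(1, n // 2 + 1)])
    return SFS(n, out / out.sum(), True)


def _unfold_symmetric(sfs: SFS) -> np.ndarray:
    """Symmetric unfolded surrogate over 1..n-1 for a folded spectrum."""
    if not sfs.folded:
        return sfs.probs.copy()
    n = sfs.n
    q = np.zeros(n - 1)
    for i, k in enumerate(range(1, n // 2 + 1)):
        if n - k == k:
            q[k - 1] = sfs.probs[i]
        else:
            q[k - 1] += sfs.probs[i] / 2.0
            q[n - k - 1] += sfs.probs[i] / 2.0
    return q


def empirical_sfs(gm: GenotypeMatrix, samples: Sequence[str],
                  folded: bool = True) -> SFS:
    """Empirical SFS of a sample set.

    Sites with missing calls are projected down to the modal complete allele
    number with hypergeometric expectation weights; sites with fewer alleles
    than the modal number are dropped.
    """
    sub = gm.geno[gm.sample_index(samples)]
    present = sub >= 0
    n_i = 2 * present.sum(axis=0)
    k_i = np.where(sub > 0, sub, 0).sum(axis=0)
    poly = (k_i > 0) & (k_i < n_i) & (n_i >= 2)
    if not poly.any():
        raise ValueError("no polymorphic site among the selected samples")
    n_i, k_i = n_i[poly], k_i[poly]
    vals, cnts = np.unique(n_i, return_counts=True)
    n0 = int(vals[np.argmax(cnts)])
    mass = np.zeros(n0 + 1)
    for nv in vals:
        if nv < n0:
            continue
        ks = k_i[n_i == nv]
        if nv == n0:
            mass[: n0 + 1] += np.bincount(ks, minlength=n0 + 1)[: n0 + 1]
        else:
            kk, kc = np.unique(ks, return_counts=True)
            for k, c in zip(kk, kc):
                kp = np.arange(n0 + 1)
                mass += c * hypergeom.pmf(kp, nv, k, n0)
    probs = mass[1:n0]  # polymorphic classes only
    if probs.sum() == 0:
        raise ValueError("no polymorphic mass after projection")
    sfs = SFS(n0, probs / probs.sum(), False)
    return fold_sfs(sfs) if folded else sfs


def _project_full(probs_full: np.ndarray, n: int, m: int) -> np.ndarray:
    """Project a distribution over 0..n allele counts to 0..m (no renorm)."""
    k = np.arange(n + 1)
    kp = np.arange(m + 1)
    M = hypergeom.pmf(kp[:, None], n, k[None, :], m)  # (m+1, n+1)
    return M @ probs_full


def project_sfs(sfs: SFS, m: int) -> SFS:
    """Hypergeometric projection to a smaller sample size.

    The result is renormalized over the polymorphic classes of size ``m``.
    """
    if not 2 <= m <= sfs.n:
        raise ValueError(f"projection size m={m} outside [2, {sfs.n}]")
    if m == sfs.n:
        return SFS(sfs.n, sfs.probs.copy(), sfs.folded)
    n = sfs.n
    full = np.zeros(n + 1)
    full[1:n] = _unfold_symmetric(sfs)
    proj = _project_full(full, n, m)
    out = SFS(m, proj[1:m] / proj[1:m].sum(), False)
    return fold_sfs(out) if sfs.folded else out


# ---------------------------------------------------------------------------
# sweep model kernel
# ---------------------------------------------------------------------------


class _SweepKernel:
    """Precomputed machinery for P(observed count | n, p_e) under the model."""

    def __init__(self, sfs: SFS, n: int | None = None):
        self.sfs = sfs
        n_base = sfs.n
        self.n = n_base if n is None else n
        if self.n > n_base:
            raise ValueError("kernel size exceeds spectrum size")
        full_base = np.zeros(n_base + 1)
        full_base[1:n_base] = _unfold_symmetric(sfs)
        if self.n == n_base:
            full = full_base
        else:
            proj = _project_full(full_base, n_base, self.n)
            full = np.zeros(self.n + 1)
            full[1 : self.n] = proj[1 : self.n] / proj[1 : self.n].sum()
        n = self.n
        self.phi_full = full  # background, polymorphic-only mass over 0..n
        # W[b, k_obs]: observed-count distribution given b escaped lineages
        W = np.zeros((n + 1, n + 1))
        W[n] = full
        for b in range(n):
            m = b + 1
            proj = _project_full(full, n, m)
            for kp in range(m + 1):
                if proj[kp] == 0.0:
                    continue
                p_tr = kp / m
                if kp >= 1:
                    W[b, kp - 1 + n - b] += proj[kp] * p_tr
                W[b, kp] += proj[kp] * (1.0 - p_tr)
        self.W = W
        self.folded = sfs.folded
        if self.folded:
            self.classes = np.arange(1, n // 2 + 1)
        else:
            self.classes = np.arange(1, n)
        bg = self._fold_rows(full[None, :])[0]
        self.bg_probs = bg / bg.sum()

    def _fold_rows(self, rows: np.ndarray) -> np.ndarray:
        """(..., n+1) unfolded observed counts -> (..., K) class probs."""
        n = self.n
        body = rows[..., 1:n]
        if not self.folded:
            return body
        out = np.empty(rows.shape[:-1] + (n // 2,))
        for i, k in enumerate(range(1, n // 2 + 1)):
            if n - k == k:
                out[..., i] = body[..., k - 1]
            else:
                out[..., i] = body[..., k - 1] + body[..., n - k - 1]
        return out

    def class_probs(self, pe: np.ndarray) -> np.ndarray:
        """P(class | p_e) for each escape probability; shape (len(pe), K).

        Renormalized over polymorphic outcomes; rows with no polymorphic mass
        (p_e = 0 with n = 2, say) are returned as zeros.
        """
        pe = np.asarray(pe, dtype=np.float64)
        n = self.n
        weights = binom.pmf(np.arange(n + 1)[None, :], n, pe[:, None])
        dist = weights @ self.W  # (P, n+1) over observed counts
        body = self._fold_rows(dist)
        tot = body.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(tot > 0, body / tot, 0.0)
        return out


def sweep_site_prob(k: int, n: int, d: float, lam: float, sfs: SFS) -> float:
    """Probability of observing count ``k`` at distance ``d`` under the sweep.

    ``lam`` may be ``inf`` (the background sentinel, p_e = 1).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not 1 <= k <= n - 1:
        raise ValueError("k must be polymorphic (1..n-1)")
    kern = _SweepKernel(sfs, n=n)
    pe = 1.0 if np.isinf(lam) else -np.expm1(-lam * d)
    probs = kern.class_probs(np.array([pe]))[0]
    cls = (min(k, n - k) if sfs.folded else k) - 1
    return float(probs[cls])


def simulate_sfs_sites(sfs: SFS, n_sites: int, length: int, seed: int = 0,
                       chrom: str = "chr_null") -> GenotypeMatrix:
    """Spatially unstructured sites drawn iid from a spectrum.

    The no-sweep calibration data for the CLR scan: positions uniform on
    [1, length], allele counts iid from ``sfs`` (no linkage), genotypes
    reconstructed as hom-alt pairs plus one het for odd counts. Useful as an
    exchangeable null for the permutation test; a real chromosome of a
    selfing population is *not* exchangeable (linkage clusters rare alleles)
    and exceeds this null even without sweeps.
    """
    rng = np.random.default_rng(seed)
    n = sfs.n
    n_samples = n // 2
    if sfs.folded:
        classes = np.arange(1, n // 2 + 1)
    else:
        classes = np.arange(1, n)
    ks = rng.choice(classes, size=n_sites, p=sfs.probs)
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_sites,
                             replace=False))
    geno = np.zeros((n_samples, n_sites), dtype=np.int8)
    for j, k in enumerate(ks):
        order = rng.permutation(n_samples)
        full, rem = divmod(int(k), 2)
        geno[order[:full], j] = 2
        if rem:
            geno[order[full], j] = 1
    bases = np.array(list("ACGT"), dtype=object)
    ref = bases[rng.integers(0, 4, size=n_sites)]
    alt = np.array(["ACGT"[("ACGT".index(r) + int(s)) % 4]
                    for r, s in zip(ref, rng.integers(1, 4, size=n_sites))],
                   dtype=object)
    return GenotypeMatrix([f"n{i}" for i in range(n_samples)],
                          np.full(n_sites, chrom, dtype=object), pos, ref, alt,
                          geno)


def default_lam_grid() -> np.ndarray:
    """20 log-spaced sweep-footprint parameters plus the background sentinel.

    The span runs from p_e(1 bp) ~ 1e-6 (chromosome-scale footprint) to
    p_e(10 kb) ~ 0.99 (footprint of a few kb).
    """
    lo = 1e-6
    hi = -np.log(0.01) / 1e4
    return np.concatenate([np.geomspace(lo, hi, 20), [np.inf]])


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


@dataclass
class CLRScan:
    """Grid positions, CLR values and maximizing lam per chromosome."""

    table: pd.DataFrame  # chrom, pos, clr, lambda_hat

    def argmax_position(self, chrom: str) -> tuple[float, float]:
        sub = self.table[self.table["chrom"] == chrom]
        i = sub["clr"].idxmax()
        return float(sub.loc[i, "pos"]), float(sub.loc[i, "clr"])

    def max_clr(self) -> float:
        return float(self.table["clr"].max())


def _group_site_data(gm: GenotypeMatrix, samples: Sequence[str]):
    sub = gm.geno[gm.sample_index(samples)]
    present = sub >= 0
    n_i = 2 * present.sum(axis=0)
    k_i = np.where(sub > 0, sub, 0).sum(axis=0)
    poly = (k_i > 0) & (k_i < n_i) & (n_i >= 2)
    return k_i, n_i, poly


class _BinnedChromScan:
    """Shared precompute for the binned CLR scan of one chromosome.

    Positions are aggregated into ``pos_bin``-bp bins and grid-to-bin
    distances into log-spaced distance bins; the per-class log-probabilities
    are evaluated once per (lam, distance-bin). The background term is exact,
    so the sentinel identity CLR(lam grid = {sentinel}) = 0 holds bit-exactly.
    """

    def __init__(self, pos0: np.ndarray, kcls: np.ndarray, length: int,
                 kern: _SweepKernel, grid_n: int, pos_bin: int = 5_000,
                 n_dist_bins: int = 300):
        self.kern = kern
        self.K = len(kern.classes)
        self.PB = int(length // pos_bin) + 1
        self.pbin = (pos0 // pos_bin).astype(np.int64)
        self.kcls = kcls
        self.grid = (np.arange(grid_n) + 0.5) * (length / grid_n)
        centers = (np.arange(self.PB) + 0.5) * pos_bin
        edges = np.geomspace(1.0, max(2.0, float(length)), n_dist_bins + 1)
        self.dcent = np.sqrt(edges[:-1] * edges[1:])
        d = np.abs(self.grid[:, None] - centers[None, :])
        self.dbin = np.clip(
            np.searchsorted(edges, np.maximum(d, 1.0), side="right") - 1,
            0, n_dist_bins - 1,
        ).astype(np.int32)
        self.logbg_site = np.log(kern.bg_probs[kcls])
        self.S_bg = float(self.logbg_site.sum())
        self._pb_range = np.arange(self.PB)[None, :]

    def counts(self, kcls: np.ndarray) -> np.ndarray:
        flat = kcls * self.PB + self.pbin
        return (
            np.bincount(flat, minlength=self.K * self.PB)
            .reshape(self.K, self.PB)
            .astype(np.float64)
        )

    def log_m(self, lam: float) -> np.ndarray:
        """(K, n_dist_bins) log class probabilities at distance-bin centers."""
        if np.isinf(lam):
            pe = np.ones_like(self.dcent)
        else:
            pe = -np.expm1(-lam * self.dcent)
        probs = self.kern.class_probs(pe)  # (D, K)
        # empty spectrum classes never occur in the data (counts are zero
        # there), so a large finite floor keeps 0 * log(0) out of the sums
        logbg = np.log(np.maximum(self.kern.bg_probs, 1e-300))
        out = np.log(np.maximum(probs.T, 1e-300))
        far = pe > PE_CUTOFF
        out[:, far] = logbg[:, None]
        return out

    def scan(self, lam_grid: np.ndarray, kcls: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
        """CLR and maximizing lam over the grid (optionally permuted classes)."""
        cnt = self.counts(self.kcls if kcls is None else kcls)
        G = len(self.grid)
        S = np.full((G, len(lam_grid)), -np.inf)
        for li, lam in enumerate(lam_grid):
            if np.isinf(lam):
                S[:, li] = self.S_bg
                continue
            B = cnt.T @ self.log_m(lam)  # (PB, D)
            S[:, li] = B[self._pb_range, self.dbin].sum(axis=1)
        best = S.argmax(axis=1)
        smax = S[np.arange(G), best]
        clr = 2.0 * np.maximum(smax - self.S_bg, 0.0)
        lam_hat = np.where(clr > 0, lam_grid[best], np.inf)
        return clr, lam_hat


def clr_scan(gm: GenotypeMatrix, samples: Sequence[str],
             grid_per_chrom: int = 2000,
             lam_grid: np.ndarray | None = None,
             folded: bool = False,
             contig_lengths: Mapping[str, int] | None = None,
             method: str = "binned",
             sfs: SFS | None = None) -> CLRScan:
    """CLR sweep scan over ``grid_per_chrom`` positions per chromosome.

    Grid points are the centers of equal partitions of each chromosome. The
    background spectrum is the group's genome-wide empirical SFS unless one
    is supplied. ``method="exact"`` evaluates each site at its exact
    distance and per-site allele number (slow; for small data and testing).
    """
    if lam_grid is None:
        lam_grid = default_lam_grid()
    lam_grid = np.asarray(lam_grid, dtype=np.float64)
    if len(lam_grid) == 0:
        raise ValueError("lam_grid must be non-empty")
    if (lam_grid < 0).any():
        raise ValueError("lam values must be >= 0")
    if not np.isinf(lam_grid).any():
        lam_grid = np.concatenate([lam_grid, [np.inf]])
    if sfs is None:
        sfs = empirical_sfs(gm, samples, folded=folded)
    k_i, n_i, poly = _group_site_data(gm, samples)
    rows = []
    chroms = list(dict.fromkeys(gm.chrom))
    for chrom in chroms:
        mask = (gm.chrom == chrom) & poly
        if contig_lengths is not None:
            length = int(contig_lengths[chrom])
        else:
            on_chrom = gm.pos[gm.chrom == chrom]
            length = int(on_chrom.max()) if len(on_chrom) else 1
        if method == "binned":
            use = mask & (n_i == sfs.n)
            kern = _SweepKernel(sfs)
            kcls = np.array(
                [kern.sfs.class_of(k) for k in k_i[use]], dtype=np.int64
            )
            if len(kcls) == 0:
                grid = (np.arange(grid_per_chrom) + 0.5) * (length / grid_per_chrom)
                for g in grid:
                    rows.append((chrom, g, 0.0, np.inf))
                continue
            sc = _BinnedChromScan(gm.pos[use] - 1.0, kcls, length, kern,
                                  grid_per_chrom)
            clr, lam_hat = sc.scan(lam_grid)
            rows.extend(zip([chrom] * len(sc.grid), sc.grid, clr, lam_hat))
        elif method == "exact":
            clr, lam_hat, grid = _exact_chrom_scan(
                gm.pos[mask] - 1.0, k_i[mask], n_i[mask], length,
                grid_per_chrom, lam_grid, sfs,
            )
            rows.extend(zip([chrom] * len(grid), grid, clr, lam_hat))
        else:
            raise ValueError(f"unknown method {method!r}")
    table = pd.DataFrame(rows, columns=["chrom", "pos", "clr", "lambda_hat"])
    return CLRScan(table)


def _exact_chrom_scan(pos0, k_i, n_i, length, grid_n, lam_grid, sfs):
    grid = (np.arange(grid_n) + 0.5) * (length / grid_n)
    kerns = {int(nv): _SweepKernel(sfs, n=int(nv))
             for nv in np.unique(n_i) if nv >= 2 and nv <= sfs.n}
    usable = np.array([int(nv) in kerns for nv in n_i])
    pos0, k_i, n_i = pos0[usable], k_i[usable], n_i[usable]
    cls = np.array(
        [(min(int(k), int(nv) - int(k)) if sfs.folded else int(k)) - 1
         for k, nv in zip(k_i, n_i)],
        dtype=np.int64,
    )
    logbg = np.array([np.log(kerns[int(nv)].bg_probs[c])
                      for c, nv in zip(cls, n_i)])
    S_bg = float(logbg.sum())
    G = len(grid)
    clr = np.zeros(G)
    lam_hat = np.full(G, np.inf)
    finite = lam_grid[~np.isinf(lam_grid)]
    for gi, g in enumerate(grid):
        d = np.abs(pos0 - g)
        best = S_bg
        best_lam = np.inf
        for lam in finite:
            pe = -np.expm1(-lam * d)
            total = 0.0
            near = pe <= PE_CUTOFF
            total += logbg[~near].sum()
            for nv in np.unique(n_i[near]):
                m = near & (n_i == nv)
                probs = kerns[int(nv)].class_probs(pe[m])
                p = probs[np.arange(m.sum()), cls[m]]
                if (p <= 0).any():
                    total = -np.inf
                    break
                total += np.log(p).sum()
            if total > best:
                best, best_lam = total, lam
        clr[gi] = 2.0 * max(best - S_bg, 0.0)
        lam_hat[gi] = best_lam if clr[gi] > 0 else np.inf
    return clr, lam_hat, grid


def permutation_null_max(gm: GenotypeMatrix, samples: Sequence[str],
                         chrom: str, grid_per_chrom: int = 2000,
                         lam_grid: np.ndarray | None = None,
                         folded: bool = False,
                         contig_length: int | None = None,
                         n_perm: int = 49, seed: int = 0,
                         sfs: SFS | None = None
                         ) -> tuple[float, np.ndarray]:
    """Observed max CLR on one chromosome and a permutation null sample.

    Each permutation shuffles which allele count sits at which position,
    destroying any spatial sweep signal while preserving the spectrum.
    Returns (observed_max, null_max_array).
    """
    if lam_grid is None:
        lam_grid = default_lam_grid()
    lam_grid = np.asarray(lam_grid, dtype=np.float64)
    if not np.isinf(lam_grid).any():
        lam_grid = np.concatenate([lam_grid, [np.inf]])
    if sfs is None:
        sfs = empirical_sfs(gm, samples, folded=folded)
    k_i, n_i, poly = _group_site_data(gm, samples)
    mask = (gm.chrom == chrom) & poly & (n_i == sfs.n)
    if contig_length is None:
        contig_length = int(gm.pos[gm.chrom == chrom].max())
    kern = _SweepKernel(sfs)
    kcls = np.array([sfs.class_of(int(k)) for k in k_i[mask]], dtype=np.int64)
    sc = _BinnedChromScan(gm.pos[mask] - 1.0, kcls, contig_length, kern,
                          grid_per_chrom)
    obs_clr, _ = sc.scan(lam_grid)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        clr_p, _ = sc.scan(lam_grid, kcls=rng.permutation(kcls))
        null[p] = clr_p.max()
    return float(obs_clr.max()), null
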