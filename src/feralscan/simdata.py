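"""Mosaic crop/wild/weed cohort simulator with exact ancestry truth.

The generator emulates the statistical structure of a resequencing panel of
a selfing crop, its outcrossing wild progenitor, and feral (weedy) strains
of three origins:

* ``dedomesticated`` — weeds descended directly from crop individuals and
  then selfed (endoferal origin);
* ``introgressed``  — crop-background weeds carrying wild haplotype tracts
  (exponentially distributed lengths) on both chromosomes of each pair,
  then selfed;
* ``f1``            — recent crop x wild hybrids (one crop gamete, one wild
  gamete, no selfing), heterozygous genome-wide.

Wild variation is laid down directly from the neutral site frequency
spectrum (P(derived count = i) proportional to 1/i) so that Watterson's
estimator is unbiased by construction. The crop is founded by a small
number of wild haplotypes that are *not* emitted as wild panel samples
(they play the role of unsampled wild ancestors) and receives post-split
"domestication branch" mutations, a fraction of which are fixed among the
founders. Copying haplotypes instead of running a coalescent keeps ancestry
tract truth exact and runtimes in seconds.

All randomness flows through one ``numpy.random.Generator`` (PCG64); the
same seed reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_io import (
    GenotypeMatrix,
    PopulationMap,
    write_bed,
    write_population_map,
    write_vcf,
)

WEED_MODES = ("dedomesticated", "introgressed", "f1")

#: synthetic stand-ins for the classic rice domestication/improvement loci
#: (erect growth, shattering, panicle architecture, awns, hull colour ...);
#: in the simulator these are crop-fixed derived variants absent from wild.
DIAGNOSTIC_GENE_NAMES = ("PROG1", "sh4", "OsLG1", "An-1", "LABA1", "Bh4", "Phr1")


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale analogue of a wild/crop/weed resequencing
    panel: a diverse wild panel, a bottlenecked highly-selfing crop, and
    three weed strains of distinct origin, with one selective sweep placed
    centrally on chr1 in the de-domesticated strain (chr2 stays sweep-free
    and doubles as a no-sweep control).
    """

    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_wild: int = 20
    n_crop: int = 24
    n_outgroup: int = 2
    #: strain name -> (mode, number of samples)
    weed_strains: dict[str, tuple[str, int]] = field(
        default_factory=lambda: {
            "weed_dedom": ("dedomesticated", 8),
            "weed_intro": ("introgressed", 8),
            "weed_f1": ("f1", 3),
        }
    )
    theta_wild: float = 0.005            # per-bp expected pairwise diversity, wild
    crop_bottleneck_k: int = 4           # founder haplotypes
    selfing_generations: int = 10        # crop selfing after founding
    weed_selfing_generations: int = 5    # extra selfing within weed strains
    weed_founders: int = 4               # crop parents founding each weed strain
    introgression_fraction: float = 0.3  # genome fraction of wild tracts
    tract_length_mean: float = 600_000.0 # bp, exponential tract lengths
    founder_skew: float = 1.0            # geometric founder-usage ratio (1 = equal)
    theta_crop_branch: float = 2e-4      # per-bp, segregating post-split crop mutations
    crop_fixed_rate: float = 2e-4        # per-bp, crop-fixed (domestication) variants
    outgroup_divergence: float = 5e-4    # per-bp, fixed outgroup differences
    crossover_rate: float = 1e-7         # per bp per gamete (1 per 10 Mb)
    sweep_intervals: list[tuple[str, int, int, str]] = field(
        default_factory=lambda: [("chr1", 2_300_000, 2_700_000, "weed_dedom")]
    )
    sweep_flank: int = 50_000
    seed: int = 17

    def validate(self) -> None:
        if self.n_wild < 1 or self.n_crop < 1 or self.n_outgroup < 0:
            raise ValueError("sample counts must be >= 1")
        for name, (mode, n) in self.weed_strains.items():
            if mode not in WEED_MODES:
                raise ValueError(f"strain {name!r}: unknown weed mode {mode!r}")
            if n < 1:
                raise ValueError(f"strain {name!r}: count must be >= 1")
        if not 0 <= self.introgression_fraction < 1:
            raise ValueError("introgression_fraction must be in [0,1)")
        if self.tract_length_mean < 10_000:
            raise ValueError("tract_length_mean must be >= 10 kb")
        if self.crop_bottleneck_k < 1:
            raise ValueError("crop_bottleneck_k must be >= 1")
        if self.theta_wild < 0:
            raise ValueError("theta_wild must be >= 0")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, grp in self.sweep_intervals:
            if chrom not in self.contig_lengths:
                raise ValueError(f"sweep interval on unknown contig {chrom!r}")
            if not 0 <= s < e <= self.contig_lengths[chrom]:
                raise ValueError("sweep interval outside contig")
            for s2, e2 in seen.get((grp, chrom), []):
                if s < e2 and s2 < e:
                    raise ValueError(
                        f"overlapping sweep intervals for group {grp!r} on {chrom}"
                    )
            seen.setdefault((grp, chrom), []).append((s, e))

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["weed_strains"] = {k: tuple(v) for k, v in d["weed_strains"].items()}
        d["sweep_intervals"] = [tuple(v) for v in d["sweep_intervals"]]
        return cls(**d)


@dataclass
class TruthSet:
    """Machine-readable ground truth for one simulated cohort.

    Ancestry tracts are stored per haplotype (keys ``(sample, hap)`` with
    hap in {0, 1}); for selfed weeds both haplotypes carry the same origin
    structure, so :meth:`sample_tracts` recovers the per-sample view. F1
    hybrids have one all-crop and one all-wild haplotype.
    """

    ancestry_tracts: dict[tuple[str, int], list[tuple[str, int, int, str]]]
    sweep_intervals: list[tuple[str, int, int, str]]
    params: dict

    def sample_tracts(self, sample: str) -> list[tuple[str, int, int, str]]:
        t0 = self.ancestry_tracts[(sample, 0)]
        t1 = self.ancestry_tracts[(sample, 1)]
        if t0 != t1:
            raise ValueError(
                f"{sample}: haplotypes differ in ancestry (hybrid); "
                "no single per-sample tract tiling exists"
            )
        return t0

    def wild_tracts(self, sample: str) -> list[tuple[str, int, int]]:
        return [
            (c, s, e) for c, s, e, o in self.sample_tracts(sample) if o == "wild"
        ]

    def tract_bed_rows(self) -> list[tuple]:
        rows = []
        for (sample, hap), tracts in self.ancestry_tracts.items():
            for c, s, e, origin in tracts:
                rows.append((c, s, e, f"{sample}/{hap}", origin))
        return rows


@dataclass
class Cohort:
    """Assembled synthetic cohort: genotypes, groups, and truth."""

    gm: GenotypeMatrix
    popmap: PopulationMap
    truth: TruthSet
    diagnostic_loci: list[tuple[str, str, int, str, str]]  # gene,chrom,pos,crop,wild
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# low-level machinery
# ---------------------------------------------------------------------------


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n + 1))) if n >= 1 else 0.0


def _unique_positions(n: int, length: int, taken: np.ndarray, rng,
                      lo: int = 1) -> np.ndarray:
    """Draw up to ``n`` distinct 1-based positions in [lo, length], avoiding
    ``taken``."""
    if n <= 0:
        return np.array([], dtype=np.int64)
    cand = rng.integers(lo, length + 1, size=2 * n + 16)
    cand = np.setdiff1d(cand, taken)  # unique + sorted
    if len(cand) > n:
        cand = np.sort(rng.choice(cand, size=n, replace=False))
    return cand.astype(np.int64)


def _sfs_counts(n_sites: int, n_haps: int, rng) -> np.ndarray:
    """Derived-allele counts drawn from the neutral SFS P(i) ~ 1/i."""
    if n_sites == 0 or n_haps < 2:
        return np.zeros(0, dtype=np.int64)
    i = np.arange(1, n_haps)
    w = 1.0 / i
    return rng.choice(i, size=n_sites, p=w / w.sum())


def _place_derived(n_haps: int, counts: np.ndarray, rng) -> np.ndarray:
    """(n_haps, n_sites) 0/1 matrix with column sums equal to ``counts``."""
    S = len(counts)
    out = np.zeros((n_haps, S), dtype=np.uint8)
    chunk = 50_000
    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        r = rng.random((n_haps, hi - lo))
        rank = r.argsort(axis=0).argsort(axis=0)
        out[:, lo:hi] = rank < counts[lo:hi][None, :]
    return out


def _recomb_gamete(h1: np.ndarray, h2: np.ndarray, pos: np.ndarray,
                   length: int, rate: float, rng) -> np.ndarray:
    """One gamete from a haplotype pair; Poisson(rate * length) crossovers."""
    nx = rng.poisson(rate * length)
    start = rng.integers(0, 2)
    if nx == 0:
        return (h1 if start == 0 else h2).copy()
    breaks = np.sort(rng.integers(1, length, size=nx))
    seg = np.searchsorted(breaks, pos - 1, side="right")
    phase = (seg + start) % 2
    return np.where(phase == 0, h1, h2).astype(np.uint8)


def _founder_gamete(founders: np.ndarray, pos: np.ndarray, length: int,
                    rate: float, rng, weights: np.ndarray | None = None
                    ) -> np.ndarray:
    """A gamete drawn as a crossover mosaic of the founder haplotypes.

    ``weights`` are founder usage probabilities; unequal usage mimics the
    skewed varietal contributions of a domestication bottleneck and lowers
    crop diversity below the wild level.
    """
    k = founders.shape[0]
    nx = rng.poisson(rate * length)
    breaks = np.sort(rng.integers(1, length, size=nx)) if nx else np.array([], dtype=np.int64)
    choice = rng.choice(k, size=nx + 1, p=weights)
    seg = np.searchsorted(breaks, pos - 1, side="right")
    return founders[choice[seg], np.arange(len(pos))]


Individual = dict  # chrom -> (2, S_chrom) uint8 haplotype pair


def _self_individual(ind: Individual, positions, contig_lengths, gens: int,
                     rate: float, rng) -> Individual:
    """``gens`` generations of self-fertilization with recombination.

    Marginal heterozygosity halves each generation at every site.
    """
    for _ in range(gens):
        new = {}
        for c in positions:
            pos, L = positions[c], contig_lengths[c]
            h1 = _recomb_gamete(ind[c][0], ind[c][1], pos, L, rate, rng)
            h2 = _recomb_gamete(ind[c][0], ind[c][1], pos, L, rate, rng)
            new[c] = np.stack([h1, h2])
        ind = new
    return ind


# ---------------------------------------------------------------------------
# spec operations
# ---------------------------------------------------------------------------


@dataclass
class WildPool:
    """Haplotype pool: panel haplotypes first, unsampled crop founders last."""

    positions: dict[str, np.ndarray]     # 1-based, sorted per chrom
    haps: dict[str, np.ndarray]          # (H, S_chrom) uint8, 1 = derived
    n_panel_haps: int

    @property
    def n_haps(self) -> int:
        first = next(iter(self.haps.values()))
        return first.shape[0]


def simulate_wild_panel(cfg: ScenarioConfig, rng=None) -> WildPool:
    """Neutral wild haplotype pool.

    ``2*n_wild + crop_bottleneck_k`` haplotypes; segregating sites are placed
    as Poisson(theta * a_{H-1} * L) per contig with derived counts from the
    neutral SFS, so the Watterson estimator of any subsample has expectation
    theta. The reference allele is ancestral throughout.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    H = 2 * cfg.n_wild + cfg.crop_bottleneck_k
    aH = _harmonic(H - 1)
    positions, haps = {}, {}
    for chrom, L in cfg.contig_lengths.items():
        S = rng.poisson(cfg.theta_wild * aH * L) if cfg.theta_wild > 0 else 0
        pos = _unique_positions(S, L, np.array([], dtype=np.int64), rng)
        counts = _sfs_counts(len(pos), H, rng)
        positions[chrom] = pos
        haps[chrom] = _place_derived(H, counts, rng)
    return WildPool(positions, haps, 2 * cfg.n_wild)


@dataclass
class CropModel:
    """Crop gene pool: founders plus sampled individuals.

    ``positions`` is the union of wild-pool and crop-branch sites; the wild
    panel haplotypes are re-expressed on this coordinate system (ancestral
    at branch sites).
    """

    positions: dict[str, np.ndarray]
    founders: dict[str, np.ndarray]          # (k, S)
    panel_haps: dict[str, np.ndarray]        # (2*n_wild, S)
    individuals: list[Individual]
    fixed_sites: dict[str, np.ndarray]       # positions of crop-fixed variants
    contig_lengths: dict[str, int]
    crossover_rate: float
    founder_weights: np.ndarray | None = None


def _new_crop_individual(founders, positions, contig_lengths, gens, rate, rng,
                         weights=None) -> Individual:
    ind = {}
    for c in positions:
        g1 = _founder_gamete(founders[c], positions[c], contig_lengths[c], rate, rng, weights)
        g2 = _founder_gamete(founders[c], positions[c], contig_lengths[c], rate, rng, weights)
        ind[c] = np.stack([g1, g2])
    return _self_individual(ind, positions, contig_lengths, gens, rate, rng)


def simulate_crop(pool: WildPool, cfg: ScenarioConfig, rng=None) -> CropModel:
    """Bottlenecked selfing crop derived from the last ``k`` pool haplotypes.

    Founders receive post-split branch mutations (segregating, neutral-SFS
    frequencies among founders) and crop-fixed domestication variants; crop
    individuals are founder crossover mosaics selfed for
    ``selfing_generations`` generations.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    k = cfg.crop_bottleneck_k
    if k > pool.n_haps:
        raise ValueError(
            f"crop_bottleneck_k={k} exceeds pool size {pool.n_haps}"
        )
    positions, founders, panel, fixed = {}, {}, {}, {}
    a_k = _harmonic(k - 1)
    for chrom, L in cfg.contig_lengths.items():
        pos0 = pool.positions[chrom]
        f0 = pool.haps[chrom][-k:]
        p0 = pool.haps[chrom][: pool.n_panel_haps]
        S_seg = rng.poisson(cfg.theta_crop_branch * a_k * L) if k > 1 else 0
        S_fix = rng.poisson(cfg.crop_fixed_rate * L)
        new_pos = _unique_positions(S_seg + S_fix, L, pos0, rng)
        rng.shuffle(new_pos)
        seg_pos = np.sort(new_pos[:S_seg]) if S_seg else np.array([], dtype=np.int64)
        seg_pos = seg_pos[: S_seg]
        fix_pos = np.sort(new_pos[len(seg_pos):])
        seg_mat = _place_derived(k, _sfs_counts(len(seg_pos), k, rng), rng)
        fix_mat = np.ones((k, len(fix_pos)), dtype=np.uint8)
        allpos = np.concatenate([pos0, seg_pos, fix_pos])
        order = np.argsort(allpos, kind="stable")
        positions[chrom] = allpos[order]
        founders[chrom] = np.concatenate([f0, seg_mat, fix_mat], axis=1)[:, order]
        pz = np.zeros((pool.n_panel_haps, len(seg_pos) + len(fix_pos)), dtype=np.uint8)
        panel[chrom] = np.concatenate([p0, pz], axis=1)[:, order]
        fixed[chrom] = fix_pos
    r = cfg.founder_skew
    w = np.power(r, np.arange(k)) if 0 < r < 1 else np.ones(k)
    w = w / w.sum()
    individuals = [
        _new_crop_individual(founders, positions, cfg.contig_lengths,
                             cfg.selfing_generations, cfg.crossover_rate, rng, w)
        for _ in range(cfg.n_crop)
    ]
    return CropModel(positions, founders, panel, individuals, fixed,
                     dict(cfg.contig_lengths), cfg.crossover_rate, w)


def _alternating_tracts(length: int, frac: float, mean_tract: float, rng):
    """Wild tracts from an alternating exponential (renewal) process."""
    if frac <= 0:
        return []
    mean_gap = mean_tract * (1.0 - frac) / frac
    tracts = []
    x = 0
    wild = bool(rng.random() < frac)
    while x < length:
        ln = max(1, int(round(rng.exponential(mean_tract if wild else mean_gap))))
        if wild:
            tracts.append((x, min(x + ln, length)))
        x += ln
        wild = not wild
    return tracts


def _tile_from_wild(length: int, wild_tracts) -> list[tuple[int, int, str]]:
    """Complement wild tracts with crop tracts to tile [0, length)."""
    tiles = []
    x = 0
    for s, e in wild_tracts:
        if s > x:
            tiles.append((x, s, "crop"))
        tiles.append((s, e, "wild"))
        x = e
    if x < length:
        tiles.append((x, length, "crop"))
    return tiles


def simulate_weed(crop: CropModel, mode: str, cfg: ScenarioConfig, rng,
                  n: int) -> tuple[list[Individual], dict[int, dict[int, list]]]:
    """One weed strain of ``n`` samples plus per-haplotype ancestry truth.

    The strain is founded by ``weed_founders`` fresh crop individuals (not
    among the sampled crop accessions, mimicking unsampled crop ancestors).
    Returns (individuals, tracts) with tracts[sample_index][hap] a list of
    (chrom, start, end, origin) tiling each contig.
    """
    if mode not in WEED_MODES:
        raise ValueError(f"unknown weed mode {mode!r}")
    contigs = crop.contig_lengths
    rate = crop.crossover_rate
    parents = [
        _new_crop_individual(crop.founders, crop.positions, contigs,
                             cfg.selfing_generations, rate, rng,
                             crop.founder_weights)
        for _ in range(cfg.weed_founders)
    ]
    n_panel = next(iter(crop.panel_haps.values())).shape[0]
    individuals, truth = [], {}
    for i in range(n):
        if mode == "f1":
            parent = parents[rng.integers(len(parents))]
            wild_j = rng.integers(n_panel // 2)
            ind = {}
            for c in crop.positions:
                g_crop = _recomb_gamete(parent[c][0], parent[c][1],
                                        crop.positions[c], contigs[c], rate, rng)
                g_wild = _recomb_gamete(crop.panel_haps[c][2 * wild_j],
                                        crop.panel_haps[c][2 * wild_j + 1],
                                        crop.positions[c], contigs[c], rate, rng)
                ind[c] = np.stack([g_crop, g_wild])
            truth[i] = {
                0: [(c, 0, contigs[c], "crop") for c in contigs],
                1: [(c, 0, contigs[c], "wild") for c in contigs],
            }
        else:
            parent = parents[rng.integers(len(parents))]
            ind = {c: parent[c].copy() for c in crop.positions}
            tracts_by_chrom = {c: [] for c in contigs}
            if mode == "introgressed":
                for c in crop.positions:
                    pos = crop.positions[c]
                    tracts = _alternating_tracts(
                        contigs[c], cfg.introgression_fraction,
                        cfg.tract_length_mean, rng)
                    tracts_by_chrom[c] = tracts
                    for s, e in tracts:
                        m = (pos - 1 >= s) & (pos - 1 < e)
                        src1 = crop.panel_haps[c][rng.integers(n_panel)]
                        src2 = crop.panel_haps[c][rng.integers(n_panel)]
                        ind[c][0][m] = src1[m]
                        ind[c][1][m] = src2[m]
            ind = _self_individual(ind, crop.positions, contigs,
                                   cfg.weed_selfing_generations, rate, rng)
            tiles = []
            for c in contigs:
                tiles.extend(
                    (c, s, e, o)
                    for s, e, o in _tile_from_wild(contigs[c], tracts_by_chrom[c])
                )
            truth[i] = {0: tiles, 1: list(tiles)}
        individuals.append(ind)
    return individuals, truth


def inject_sweep(individuals: list[Individual], positions, contig_lengths,
                 interval: tuple[str, int, int], cfg: ScenarioConfig, rng
                 ) -> dict[str, list[tuple[int, int]]]:
    """Wipe diversity in ``interval`` across a group, in place.

    Inside the core every haplotype is replaced by one randomly chosen group
    haplotype; the wipe probability decays linearly to zero over
    ``sweep_flank`` bp on each side. New singleton mutations
    (Poisson(theta_wild * L_core / 10)) are re-sprinkled inside the core.

    Returns the new singleton sites as {chrom: [(pos, hap_index)]}, to be
    appended to the cohort site table by the caller.
    """
    chrom, s, e = interval[:3]
    pos = positions[chrom]
    flank = cfg.sweep_flank
    H = np.concatenate([ind[chrom] for ind in individuals], axis=0)
    n_h = H.shape[0]
    template = H[rng.integers(n_h)].copy()
    pos0 = pos - 1
    core = (pos0 >= s) & (pos0 < e)
    d_left = np.where((pos0 >= s - flank) & (pos0 < s), s - pos0, -1)
    d_right = np.where((pos0 >= e) & (pos0 < e + flank), pos0 - e + 1, -1)
    dist = np.maximum(d_left, d_right)
    in_flank = dist > 0
    wipe = core.copy()
    if in_flank.any():
        p = 1.0 - dist[in_flank] / float(flank)
        wipe[in_flank] = rng.random(in_flank.sum()) < p
    for ind in individuals:
        ind[chrom][0][wipe] = template[wipe]
        ind[chrom][1][wipe] = template[wipe]
    n_new = rng.poisson(cfg.theta_wild * (e - s) / 10.0)
    new_pos = _unique_positions(n_new, e, pos, rng, lo=s + 1)
    carriers = rng.integers(0, n_h, size=len(new_pos))
    return {chrom: list(zip(new_pos.tolist(), carriers.tolist()))}


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _sample_names(cfg: ScenarioConfig) -> dict[str, list[str]]:
    names = {
        "wild": [f"wild_{i+1:02d}" for i in range(cfg.n_wild)],
        "crop": [f"crop_{i+1:02d}" for i in range(cfg.n_crop)],
        "outgroup": [f"outgroup_{i+1:02d}" for i in range(cfg.n_outgroup)],
    }
    for strain, (_, n) in cfg.weed_strains.items():
        names[strain] = [f"{strain}_{i+1:02d}" for i in range(n)]
    return names


def emit_cohort(cfg: ScenarioConfig, out_dir=None) -> Cohort:
    """Generate a full cohort (and optionally write all fixture files).

    Files written under ``out_dir``: ``cohort.vcf``, ``popmap.tsv``,
    ``truth_tracts.bed``, ``truth_sweeps.bed``, ``truth_params.json`` and
    ``diagnostic_loci.tsv``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pool = simulate_wild_panel(cfg, rng)
    crop = simulate_crop(pool, cfg, rng)
    contigs = dict(cfg.contig_lengths)
    names = _sample_names(cfg)

    strains: dict[str, list[Individual]] = {}
    tract_truth: dict[tuple[str, int], list] = {}
    for strain, (mode, n) in cfg.weed_strains.items():
        individuals, truth = simulate_weed(crop, mode, cfg, rng, n)
        strains[strain] = individuals
        for i, per_hap in truth.items():
            for hap, tiles in per_hap.items():
                tract_truth[(names[strain][i], hap)] = tiles

    sweep_singletons: dict[str, list[tuple[int, int, str]]] = {c: [] for c in contigs}
    for chrom, s, e, group in cfg.sweep_intervals:
        if group not in strains:
            raise ValueError(f"sweep target group {group!r} is not a weed strain")
        new = inject_sweep(strains[group], crop.positions, contigs,
                           (chrom, s, e), cfg, rng)
        for c, entries in new.items():
            sweep_singletons[c].extend((p, h, group) for p, h in entries)

    # outgroup-private fixed differences
    out_pos = {}
    for chrom, L in contigs.items():
        S_out = rng.poisson(cfg.outgroup_divergence * L)
        taken = np.concatenate(
            [crop.positions[chrom],
             np.array([p for p, _, _ in sweep_singletons[chrom]], dtype=np.int64)]
        )
        out_pos[chrom] = _unique_positions(S_out, L, taken, rng)

    # ---- union site table and per-sample genotype codes -------------------
    sample_order: list[str] = (
        names["wild"] + names["crop"]
        + [s for strain in cfg.weed_strains for s in names[strain]]
        + names["outgroup"]
    )
    chrom_arr, pos_arr, geno_cols = [], [], []
    loci_candidates: list[tuple[str, int]] = []
    for chrom in sorted(contigs, key=str):
        base_pos = crop.positions[chrom]
        sw = sorted(sweep_singletons[chrom])
        sw_pos = np.array([p for p, _, _ in sw], dtype=np.int64)
        op = out_pos[chrom]
        union = np.concatenate([base_pos, sw_pos, op])
        order = np.argsort(union, kind="stable")
        union = union[order]
        nU = len(union)
        idx_base = np.searchsorted(union, base_pos)
        idx_sw = np.searchsorted(union, sw_pos)
        idx_out = np.searchsorted(union, op)

        geno = np.zeros((len(sample_order), nU), dtype=np.int8)
        row = 0
        for i in range(cfg.n_wild):
            h = crop.panel_haps[chrom][2 * i] + crop.panel_haps[chrom][2 * i + 1]
            geno[row, idx_base] = h
            row += 1
        for ind in crop.individuals:
            geno[row, idx_base] = ind[chrom][0] + ind[chrom][1]
            row += 1
        strain_rows: dict[str, list[int]] = {}
        for strain in cfg.weed_strains:
            strain_rows[strain] = []
            for ind in strains[strain]:
                geno[row, idx_base] = ind[chrom][0] + ind[chrom][1]
                strain_rows[strain].append(row)
                row += 1
        for _ in range(cfg.n_outgroup):
            geno[row, idx_out] = 2
            row += 1
        # sweep singletons: one derived copy on one haplotype of the target group
        for (p, hap_idx, group), j in zip(sw, idx_sw):
            geno[strain_rows[group][hap_idx // 2], j] = 1

        keep = (geno > 0).any(axis=0)
        chrom_arr.append(np.full(keep.sum(), chrom, dtype=object))
        pos_arr.append(union[keep])
        geno_cols.append(geno[:, keep])
        kept_fixed = np.intersect1d(crop.fixed_sites[chrom], union[keep])
        loci_candidates.extend((chrom, int(p)) for p in kept_fixed)

    chrom_all = np.concatenate(chrom_arr)
    pos_all = np.concatenate(pos_arr)
    geno_all = np.concatenate(geno_cols, axis=1)
    nS = len(pos_all)
    ref = np.array(list("ACGT"), dtype=object)[rng.integers(0, 4, size=nS)]
    shift = rng.integers(1, 4, size=nS)
    bases = "ACGT"
    alt = np.array(
        [bases[(bases.index(r) + s) % 4] for r, s in zip(ref, shift)], dtype=object
    )
    gm = GenotypeMatrix(sample_order, chrom_all, pos_all, ref, alt, geno_all)

    entries: dict[str, tuple[str, str]] = {}
    for s in names["wild"]:
        entries[s] = ("wild", "wild")
    for s in names["crop"]:
        entries[s] = ("crop", "crop")
    for strain in cfg.weed_strains:
        for s in names[strain]:
            entries[s] = (strain, "weed")
    for s in names["outgroup"]:
        entries[s] = ("outgroup", "outgroup")
    popmap = PopulationMap(entries)

    # crop samples / outgroup ancestry truth (trivial, but lets every sample
    # carry a tract record)
    for s in names["crop"]:
        for hap in (0, 1):
            tract_truth[(s, hap)] = [(c, 0, contigs[c], "crop") for c in contigs]

    loci = _pick_diagnostic_loci(loci_candidates, gm, rng)
    truth = TruthSet(
        ancestry_tracts=tract_truth,
        sweep_intervals=list(cfg.sweep_intervals),
        params={
            "config": asdict(cfg),
            "n_sites": int(gm.n_sites),
            "n_samples": int(gm.n_samples),
            "ancestral_allele": "ref",
            "rng": "numpy PCG64 (default_rng)",
        },
    )
    cohort = Cohort(gm, popmap, truth, loci, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(gm, out / "cohort.vcf", contig_lengths=contigs)
        write_population_map(popmap, out / "popmap.tsv")
        write_bed(truth.tract_bed_rows(), out / "truth_tracts.bed",
                  header="ancestry truth; 0-based half-open; name=sample/hap, col5=origin")
        write_bed([(c, s, e, g) for c, s, e, g in cfg.sweep_intervals],
                  out / "truth_sweeps.bed",
                  header="sweep truth; 0-based half-open; name=target group")
        with open(out / "truth_params.json", "w") as fh:
            json.dump(truth.params, fh, indent=1)
        with open(out / "diagnostic_loci.tsv", "w") as fh:
            fh.write("gene\tchrom\tpos\tcrop_allele\twild_allele\n")
            for gene, chrom, p, ca, wa in loci:
                fh.write(f"{gene}\t{chrom}\t{p}\t{ca}\t{wa}\n")
    return cohort


def _pick_diagnostic_loci(candidates: list[tuple[str, int]], gm: GenotypeMatrix,
                          rng) -> list[tuple[str, str, int, str, str]]:
    """Choose crop-fixed sites, spread along the genome, as diagnostic loci."""
    if not candidates:
        return []
    candidates = sorted(candidates)
    n = min(len(DIAGNOSTIC_GENE_NAMES), len(candidates))
    picks_idx = np.unique(
        np.linspace(0, len(candidates) - 1, n).round().astype(int)
    )
    site_lookup = {(c, int(p)): j for j, (c, p) in enumerate(zip(gm.chrom, gm.pos))}
    loci = []
    for gene, ci in zip(DIAGNOSTIC_GENE_NAMES, picks_idx):
        chrom, p = candidates[ci]
        j = site_lookup[(chrom, p)]
        loci.append((gene, chrom, int(p), str(gm.alt[j]), str(gm.ref[j])))
    return loci
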