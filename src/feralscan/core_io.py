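"""Genotype matrix model and readers/writers for the standard formats.

Coordinate conventions used throughout the package:

* variant sites are 1-based (VCF convention);
* genomic windows and BED intervals are 0-based, half-open.

The in-memory genotype model is a dense samples x sites matrix of diploid
genotype codes: ``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.
Only biallelic SNPs are represented; multiallelic and non-SNP records are
dropped at ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1
VALID_ROLES = ("wild", "crop", "weed", "outgroup")
_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be decoded into genotype codes."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP-sites diploid genotype codes.

    Attributes
    ----------
    sample_ids : list of unique sample names.
    chrom, pos, ref, alt : per-site arrays; ``pos`` is 1-based. Sites are
        sorted by (chrom, pos) with no duplicates.
    geno : int8 array of shape (n_samples, n_sites) with codes in
        {-1, 0, 1, 2}.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise ValueError("geno must be 2-D (samples x sites)")
        if self.geno.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.pos)} sites"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        """Check the full set of invariants (biallelic, sorted, codes)."""
        for r, a in zip(self.ref, self.alt):
            if r not in _BASES or a not in _BASES or r == a:
                raise ValueError(f"not a biallelic SNP: ref={r!r} alt={a!r}")
        bad = ~np.isin(self.geno, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes outside {-1,0,1,2}")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(self.n_sites)):
            raise ValueError("sites not sorted by (chrom, pos)")
        key = list(zip(self.chrom, self.pos))
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chrom, pos)")

    # -- selection helpers --------------------------------------------------

    def sample_index(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(samples)
        return GenotypeMatrix(
            list(samples), self.chrom, self.pos, self.ref, self.alt,
            self.geno[idx],
        )

    def take_sites(self, mask_or_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.chrom[mask_or_idx],
            self.pos[mask_or_idx],
            self.ref[mask_or_idx],
            self.alt[mask_or_idx],
            self.geno[:, mask_or_idx],
        )

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites inside the half-open window [start, end)."""
        return (self.chrom == chrom) & (self.pos - 1 >= start) & (self.pos - 1 < end)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.geno, other.geno)
        )


@dataclass
class PopulationMap:
    """sample -> (group, role) with roles from {wild, crop, weed, outgroup}."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, (group, role) in self.entries.items():
            if role not in VALID_ROLES:
                raise ValueError(
                    f"sample {sample!r}: unknown role {role!r} "
                    f"(expected one of {VALID_ROLES})"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    def group_of(self, sample: str) -> str:
        return self.entries[sample][0]

    def role_of(self, sample: str) -> str:
        return self.entries[sample][1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, (g, _) in self.entries.items() if g == group]

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, (_, r) in self.entries.items() if r == role]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g, _ in self.entries.values():
            seen.setdefault(g)
        return list(seen)


@dataclass
class WindowSet:
    """Ordered non-overlapping fixed-size windows tiling each contig.

    Windows are 0-based half-open; the last window of a contig may be short.
    """

    windows: list[tuple[str, int, int]]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        return self.windows[i]

    def lengths(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.windows], dtype=np.int64)

    def assign_sites(self, gm: GenotypeMatrix) -> np.ndarray:
        """Window index of each site of ``gm`` (-1 if no window covers it)."""
        out = np.full(gm.n_sites, -1, dtype=np.int64)
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for wi, (c, s, e) in enumerate(self.windows):
            by_chrom.setdefault(c, []).append((s, e, wi))
        for c, wins in by_chrom.items():
            starts = np.array([w[0] for w in wins])
            ends = np.array([w[1] for w in wins])
            idx = np.array([w[2] for w in wins])
            mask = gm.chrom == c
            pos0 = gm.pos[mask] - 1
            j = np.searchsorted(starts, pos0, side="right") - 1
            ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, None)])
            vals = np.full(pos0.shape, -1, dtype=np.int64)
            vals[ok] = idx[j[ok]]
            out[mask] = vals
        return out


def make_windows(contig_lengths: Mapping[str, int], size: int) -> WindowSet:
    """Tile each contig from 0 with non-overlapping windows of ``size`` bp."""
    if size <= 0:
        raise ValueError(f"window size must be positive, got {size}")
    windows = []
    for chrom in contig_lengths:
        length = int(contig_lengths[chrom])
        for start in range(0, length, size):
            windows.append((chrom, start, min(start + size, length)))
    return WindowSet(windows)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(
    path,
    region: tuple[str, int, int] | None = None,
    min_gq: float | None = None,
    min_dp: float | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped. Genotypes whose GQ or DP
    falls below the thresholds are set missing. Phased and unphased calls are
    treated identically; half-calls (``0/.``) become missing; haploid calls
    are promoted to the homozygous diploid code with a warning.

    ``region`` is a (chrom, start, end) half-open 0-based interval.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    warned_haploid = False
    with open(path) as fh:
        n_header = sum(1 for line in fh if line.startswith("#"))
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            continue
        if region is not None:
            c, s, e = region
            if rec.CHROM != c or not (s <= rec.POS - 1 < e):
                continue
        try:
            arr = rec.genotype.array()
        except Exception as exc:
            raise VcfParseError(
                f"{path} line {n_header + i + 1}: malformed GT ({exc})"
            ) from exc
        if arr is None or arr.shape[1] < 2:
            raise VcfParseError(f"{path} line {n_header + i + 1}: malformed GT field")
        # last column is the phase flag; width - 1 is the record's max ploidy
        a1 = arr[:, 0].astype(np.int64)
        if arr.shape[1] == 2:  # all-haploid record
            a2 = np.full_like(a1, -2)
        else:
            a2 = arr[:, 1].astype(np.int64)
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        haploid = a2 == -2
        if haploid.any() and not warned_haploid:
            warnings.warn(
                f"{path}: haploid GT calls promoted to homozygous diploid",
                stacklevel=2,
            )
            warned_haploid = True
        a2 = np.where(haploid, a1, a2)
        if (a1 > 1).any() or (a2 > 1).any():
            raise VcfParseError(
                f"{path} line {n_header + i + 1}: allele index >1 in biallelic record"
            )
        full = (a1 >= 0) & (a2 >= 0)
        codes[full] = (a1 + a2)[full]
        if min_gq is not None:
            gq = rec.gt_quals
            codes[(gq < min_gq) | (gq < 0)] = MISSING
        if min_dp is not None:
            dp = rec.format("DP")
            if dp is None:
                codes[:] = MISSING
            else:
                dp = dp[:, 0].astype(np.float64)
                codes[(dp < min_dp) | (dp < -1e17)] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(ref)
        alts.append(alt)
        rows.append(codes)
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        samples,
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        geno,
    )
    order = np.lexsort((gm.pos, gm.chrom.astype(str)))
    if not np.array_equal(order, np.arange(gm.n_sites)):
        gm = gm.take_sites(order)
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a GT-only VCF 4.2. Codes map 0->0/0, 1->0/1, 2->1/1, -1->./.."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={int(ln)}>\n")
        else:
            for c in dict.fromkeys(gm.chrom):
                fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + gm.sample_ids)
        fh.write(cols + "\n")
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in gm.geno[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# population map, GFF3, BED
# ---------------------------------------------------------------------------


def read_population_map(path) -> PopulationMap:
    """Read a ``sample<TAB>group<TAB>role`` TSV (lines starting '#' skipped)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["sample", "group", "role"], dtype=str)
    if df["sample"].duplicated().any():
        dups = df["sample"][df["sample"].duplicated()].tolist()
        raise ValueError(f"duplicate sample(s) in population map: {dups}")
    entries = {
        r["sample"]: (r["group"], r["role"]) for _, r in df.iterrows()
    }
    return PopulationMap(entries)


def write_population_map(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample\tgroup\trole\n")
        for sample, (group, role) in pm.entries.items():
            fh.write(f"{sample}\t{group}\t{role}\n")


def read_gff3_genes(path) -> list[tuple[str, int, int, str]]:
    """Gene features from a GFF3 as (chrom, start, end, gene_id).

    Intervals are converted to 0-based half-open (GFF3 is 1-based closed).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append((feat.seqid, feat.start - 1, feat.end, gid))
    genes.sort(key=lambda g: (g[0], g[1], g[2]))
    return genes


def read_bed(path) -> list[tuple]:
    """Read BED3+ rows as (chrom, start, end[, name[, score[, strand]]])."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            rows.append(tuple([chrom, start, end] + parts[3:6]))
    return rows


def write_bed(intervals: Iterable[tuple], path, header: str | None = None) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
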