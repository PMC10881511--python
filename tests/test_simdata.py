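import json

import numpy as np
import pytest

from feralscan import divstats
from feralscan.core_io import make_windows, read_bed, read_vcf, write_bed
from feralscan.simdata import (
    ScenarioConfig, emit_cohort, inject_sweep, simulate_crop,
    simulate_weed, simulate_wild_panel,
)

from conftest import small_config


def tiny_config(**kw):
    base = dict(
        contig_lengths={"chr1": 200_000},
        n_wild=10, n_crop=6, n_outgroup=1,
        weed_strains={"weed_dedom": ("dedomesticated", 4),
                      "weed_intro": ("introgressed", 4),
                      "weed_f1": ("f1", 2)},
        tract_length_mean=30_000,
        sweep_intervals=[],
        seed=5,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestWildPanel:
    def test_zero_theta_zero_sites(self):
        pool = simulate_wild_panel(tiny_config(theta_wild=0.0))
        assert all(len(p) == 0 for p in pool.positions.values())

    def test_deterministic_given_seed(self):
        a = simulate_wild_panel(tiny_config(seed=9))
        b = simulate_wild_panel(tiny_config(seed=9))
        for c in a.positions:
            assert np.array_equal(a.positions[c], b.positions[c])
            assert np.array_equal(a.haps[c], b.haps[c])

    def test_watterson_estimator_unbiased(self):
        """theta_W from emitted panels averages within 5% of the target."""
        theta = 0.005
        ests = []
        for seed in range(25):
            cfg = ScenarioConfig(
                contig_lengths={"chr1": 500_000}, n_wild=20,
                theta_wild=theta, sweep_intervals=[], seed=300 + seed,
            )
            pool = simulate_wild_panel(cfg)
            pos = pool.positions["chr1"]
            panel = pool.haps["chr1"][: 2 * cfg.n_wild]
            counts = panel.sum(axis=0)
            S = int(((counts > 0) & (counts < panel.shape[0])).sum())
            a = np.sum(1.0 / np.arange(1, panel.shape[0]))
            ests.append(S / (a * 500_000))
            del pos
        assert abs(np.mean(ests) - theta) / theta < 0.05


class TestCrop:
    def test_single_founder_monomorphic_crop(self):
        cfg = tiny_config(crop_bottleneck_k=1)
        pool = simulate_wild_panel(cfg)
        crop = simulate_crop(pool, cfg)
        g0 = crop.individuals[0]["chr1"]
        for ind in crop.individuals:
            assert np.array_equal(ind["chr1"][0], ind["chr1"][1])  # homozygous
            assert np.array_equal(ind["chr1"], g0)  # identical individuals

    def test_bottleneck_exceeding_pool_rejected(self):
        cfg = tiny_config()
        pool = simulate_wild_panel(cfg)
        cfg.crop_bottleneck_k = pool.n_haps + 1
        with pytest.raises(ValueError, match="exceeds pool"):
            simulate_crop(pool, cfg)

    def test_no_selfing_matches_hardy_weinberg(self):
        """Mean het of unselfed crop equals the HW expectation from founder
        frequencies (weighted by founder usage), within 3 s.e."""
        cfg = tiny_config(selfing_generations=0, n_crop=40, founder_skew=0.45)
        rng = np.random.default_rng(21)
        pool = simulate_wild_panel(cfg, rng)
        crop = simulate_crop(pool, cfg, rng)
        w = crop.founder_weights
        f = (w[:, None] * crop.founders["chr1"]).sum(axis=0)
        exp_het_per_site = 2 * f * (1 - f)
        expected = exp_het_per_site.sum()
        hets = [
            (ind["chr1"][0] != ind["chr1"][1]).sum() for ind in crop.individuals
        ]
        se = np.std(hets, ddof=1) / np.sqrt(len(hets))
        assert abs(np.mean(hets) - expected) <= 3 * max(se, 1.0)

    def test_crop_less_diverse_than_wild(self):
        """Bottlenecked crop pi below wild pi in >= 49/50 replicates."""
        wins = None
        successes = 0
        for seed in range(50):
            cfg = tiny_config(seed=700 + seed)
            co = emit_cohort(cfg)
            wins = make_windows(cfg.contig_lengths, 200_000)
            pi_w = divstats.window_pi(co.gm, co.popmap.samples_in_group("wild"), wins)
            pi_c = divstats.window_pi(co.gm, co.popmap.samples_in_group("crop"), wins)
            successes += pi_c.mean() < pi_w.mean()
        assert successes >= 49


class TestWeeds:
    def test_f1_heterozygous_at_fixed_differences(self, small_cohort):
        gm, pm = small_cohort.gm, small_cohort.popmap
        crop = gm.geno[gm.sample_index(pm.samples_in_group("crop"))]
        wild = gm.geno[gm.sample_index(pm.samples_in_group("wild"))]
        fixed_diff = (crop == 2).all(axis=0) & (wild == 0).all(axis=0)
        assert fixed_diff.sum() > 100
        for s in pm.samples_in_group("weed_f1"):
            row = gm.geno[gm.sample_index([s])[0]]
            assert (row[fixed_diff] == 1).all()

    def test_zero_introgression_gives_all_crop_tracts(self):
        cfg = tiny_config(introgression_fraction=0.0)
        co = emit_cohort(cfg)
        for s in co.popmap.samples_in_group("weed_intro"):
            assert all(o == "crop" for *_, o in co.truth.sample_tracts(s))

    def test_realized_tract_fraction(self):
        """Mean realized wild-tract fraction within 30% of the target."""
        cfg = small_config(seed=31)
        cfg.weed_strains = {"weed_intro": ("introgressed", 20)}
        cfg.sweep_intervals = []
        co = emit_cohort(cfg)
        genome = sum(cfg.contig_lengths.values())
        fracs = [
            sum(e - s for _, s, e in co.truth.wild_tracts(smp)) / genome
            for smp in co.popmap.samples_in_group("weed_intro")
        ]
        target = cfg.introgression_fraction
        assert abs(np.mean(fracs) - target) / target < 0.30

    def test_unknown_mode_rejected(self):
        cfg = tiny_config()
        pool = simulate_wild_panel(cfg)
        crop = simulate_crop(pool, cfg)
        with pytest.raises(ValueError, match="mode"):
            simulate_weed(crop, "hybrid_swarm", cfg, np.random.default_rng(0), 2)


class TestSweepInjection:
    def _strain(self, cfg, rng):
        pool = simulate_wild_panel(cfg, rng)
        crop = simulate_crop(pool, cfg, rng)
        inds, _ = simulate_weed(crop, "dedomesticated", cfg, rng, 6)
        return crop, inds

    def test_core_diversity_wiped_flank_untouched(self):
        cfg = tiny_config(contig_lengths={"chr1": 400_000})
        rng = np.random.default_rng(13)
        crop, inds = self._strain(cfg, rng)
        pos = crop.positions["chr1"]

        def group_pi(individuals, lo, hi):
            m = (pos - 1 >= lo) & (pos - 1 < hi)
            H = np.concatenate([i["chr1"][:, m] for i in individuals])
            n = H.shape[0]
            j = H.sum(axis=0)
            return (2.0 * j * (n - j) / (n * (n - 1))).sum() / (hi - lo)

        before_core = group_pi(inds, 150_000, 250_000)
        far_before = [ind["chr1"][:, (pos - 1 < 50_000)].copy() for ind in inds]
        inject_sweep(inds, crop.positions, cfg.contig_lengths,
                     ("chr1", 150_000, 250_000), cfg, rng)
        after_core = group_pi(inds, 150_000, 250_000)
        assert after_core < 0.05 * before_core
        for ind, before in zip(inds, far_before):
            assert np.array_equal(ind["chr1"][:, (pos - 1 < 50_000)], before)

    def test_overlapping_sweeps_rejected(self):
        cfg = tiny_config()
        cfg.sweep_intervals = [("chr1", 0, 50_000, "weed_dedom"),
                               ("chr1", 40_000, 90_000, "weed_dedom")]
        with pytest.raises(ValueError, match="overlapping"):
            cfg.validate()

    def test_truth_bed_roundtrip(self, tmp_path, small_cohort):
        rows = small_cohort.truth.tract_bed_rows()
        p = tmp_path / "t.bed"
        write_bed(rows, p)
        back = read_bed(p)
        assert [(c, s, e, n, o) for c, s, e, n, o in back] == \
            [(c, s, e, n, o) for c, s, e, n, o in rows]


class TestEmitCohort:
    def test_outputs_exist_and_load(self, tmp_path):
        cfg = tiny_config()
        co = emit_cohort(cfg, out_dir=tmp_path)
        for name in ("cohort.vcf", "popmap.tsv", "truth_tracts.bed",
                     "truth_sweeps.bed", "truth_params.json",
                     "diagnostic_loci.tsv"):
            assert (tmp_path / name).exists()
        gm = read_vcf(tmp_path / "cohort.vcf")
        assert gm.n_sites == co.gm.n_sites > 0
        assert gm.equals(co.gm)
        params = json.loads((tmp_path / "truth_params.json").read_text())
        assert params["config"]["seed"] == cfg.seed

    def test_same_seed_identical_files(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        emit_cohort(tiny_config(), out_dir=a)
        emit_cohort(tiny_config(), out_dir=b)
        for name in ("cohort.vcf", "popmap.tsv", "truth_tracts.bed",
                     "truth_params.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_popmap_groups_match_config(self, small_cohort):
        cfg = small_cohort.config
        expect = {"wild", "crop", "outgroup"} | set(cfg.weed_strains)
        assert set(small_cohort.popmap.groups) == expect

    def test_wild_specific_alleles_concentrate_in_truth_tracts(self, small_cohort):
        """Introgressed weeds carry >= 90% of their wild-private allele
        copies inside their truth tracts."""
        from feralscan.introgression import classify_private_snps

        gm, pm, truth = small_cohort.gm, small_cohort.popmap, small_cohort.truth
        classes = classify_private_snps(
            gm, pm.samples_in_group("crop"), pm.samples_in_group("wild"))
        wild_sites = classes == "wild_specific"
        for s in pm.samples_in_group("weed_intro"):
            row = gm.geno[gm.sample_index([s])[0]]
            copies = np.where(row > 0, row, 0) * wild_sites
            in_tract = np.zeros(gm.n_sites, dtype=bool)
            for c, lo, hi in truth.wild_tracts(s):
                in_tract |= (gm.chrom == c) & (gm.pos - 1 >= lo) & (gm.pos - 1 < hi)
            total = copies.sum()
            if total == 0:
                continue
            assert copies[in_tract].sum() / total >= 0.90
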