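import numpy as np
import pytest

from feralscan import divstats
from feralscan.core_io import GenotypeMatrix, make_windows
from feralscan.divstats import (
    heterozygosity_rate, pi_ratio_scan, site_pi, wc_fst, window_pi,
    window_theta_w,
)

from conftest import random_gm
from _oracles import brute_fst, brute_theta_w, brute_window_pi


def gm_from_codes(codes, positions=None, chrom="1"):
    codes = np.asarray(codes, dtype=np.int8)
    n_samples, n_sites = codes.shape
    pos = np.arange(1, n_sites + 1) * 10 if positions is None else np.asarray(positions)
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)],
        np.array([chrom] * n_sites, dtype=object), pos,
        np.array(["A"] * n_sites, dtype=object),
        np.array(["T"] * n_sites, dtype=object), codes,
    )


class TestSitePi:
    @pytest.mark.parametrize("j,n,expect", [
        (0, 4, 0.0),            # monomorphic
        (2, 4, 4.0 / 6.0),      # 6 allele pairs, 4 differ
        (1, 2, 1.0),            # the single pair differs
        (4, 4, 0.0),
    ])
    def test_examples(self, j, n, expect):
        assert site_pi(j, n) == pytest.approx(expect, abs=1e-12)

    def test_equals_mean_pairwise_difference(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            j = int(rng.integers(0, n + 1))
            alleles = [1] * j + [0] * (n - j)
            diffs = sum(
                alleles[x] != alleles[y]
                for x in range(n) for y in range(x + 1, n)
            )
            assert site_pi(j, n) == pytest.approx(diffs / (n * (n - 1) / 2))

    def test_undefined_below_two_alleles(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)


class TestWindowPi:
    def test_single_snp_example(self):
        gm = gm_from_codes([[1], [1], [-1]], positions=[50])
        ws = make_windows({"1": 100_000}, 100_000)
        # j=2, n=4 -> 2/3 over 100 kb
        assert window_pi(gm, gm.sample_ids, ws)[0] == pytest.approx(6.6667e-6, rel=1e-4)

    def test_empty_window_zero(self):
        gm = gm_from_codes([[1], [0]], positions=[5])
        ws = make_windows({"1": 200}, 100)
        assert window_pi(gm, gm.sample_ids, ws)[1] == 0.0

    def test_matches_bruteforce_pairwise_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            gm = random_gm(rng, n_samples=6, n_sites=30, miss_frac=0.15)
            L = int(gm.pos.max())
            ws = make_windows({"1": L}, max(L // 3, 1))
            got = window_pi(gm, gm.sample_ids, ws)
            for w, (c, s, e) in enumerate(ws):
                mask = (gm.pos - 1 >= s) & (gm.pos - 1 < e)
                expect = brute_window_pi(gm.geno, mask, e - s)
                assert got[w] == pytest.approx(expect, abs=1e-15, rel=1e-12)

    def test_empty_sample_set_rejected(self):
        gm = gm_from_codes([[1], [0]])
        ws = make_windows({"1": 100}, 100)
        with pytest.raises(ValueError):
            window_pi(gm, [], ws)


class TestWindowThetaW:
    def test_harmonic_example(self):
        # S=3 segregating among n=4 alleles over 100 bp
        gm = gm_from_codes([[1, 1, 1], [0, 1, 0]], positions=[10, 20, 30])
        ws = make_windows({"1": 100}, 100)
        got = window_theta_w(gm, gm.sample_ids, ws)[0]
        assert got == pytest.approx(3 / ((1 + 0.5 + 1 / 3) * 100), rel=1e-9)

    def test_no_segregation_zero(self):
        gm = gm_from_codes([[0, 2], [0, 2]])
        ws = make_windows({"1": 100}, 100)
        assert window_theta_w(gm, gm.sample_ids, ws)[0] == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            gm = random_gm(rng, n_samples=5, n_sites=25, miss_frac=0.2)
            L = int(gm.pos.max())
            ws = make_windows({"1": L}, max(L // 2, 1))
            got = window_theta_w(gm, gm.sample_ids, ws)
            for w, (c, s, e) in enumerate(ws):
                mask = (gm.pos - 1 >= s) & (gm.pos - 1 < e)
                assert got[w] == pytest.approx(
                    brute_theta_w(gm.geno, mask, e - s), abs=1e-15, rel=1e-12)


class TestHeterozygosity:
    def test_example_codes(self):
        gm = gm_from_codes([[1, 2, 2, 2, 0, -1]])
        r = heterozygosity_rate(gm, "s0")
        assert (r.n_variant_sites, r.n_het) == (4, 1)
        assert r.het_rate == pytest.approx(0.25)

    def test_all_hom_alt_zero(self):
        gm = gm_from_codes([[2, 2, 2]])
        assert heterozygosity_rate(gm, "s0").het_rate == 0.0

    def test_no_variant_sites_undefined(self):
        gm = gm_from_codes([[0, 0, -1]])
        assert heterozygosity_rate(gm, "s0").het_rate is None

    def test_unknown_sample(self):
        gm = gm_from_codes([[0]])
        with pytest.raises(KeyError):
            heterozygosity_rate(gm, "nope")


class TestWcFst:
    def test_complete_fixation(self):
        gm = gm_from_codes([[0, 0], [0, 0], [2, 2], [2, 2]])
        ws = make_windows({"1": 100}, 100)
        got = wc_fst(gm, ["s0", "s1"], ["s2", "s3"], ws)
        assert got[0] == pytest.approx(1.0)

    def test_identical_pops_nonpositive_and_matches_oracle(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, size=(4, 12)).astype(np.int8)
        gm = gm_from_codes(np.vstack([col, col]))
        ws = make_windows({"1": int(gm.pos.max())}, int(gm.pos.max()))
        a = [f"s{i}" for i in range(4)]
        b = [f"s{i}" for i in range(4, 8)]
        got = wc_fst(gm, a, b, ws)[0]
        expect = brute_fst(gm.geno[:4], gm.geno[4:])
        assert got <= 1e-12
        assert got == pytest.approx(expect, abs=1e-12)

    def test_matches_wc84_component_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            gm = random_gm(rng, n_samples=10, n_sites=30, miss_frac=0.1)
            a = gm.sample_ids[:5]
            b = gm.sample_ids[5:]
            L = int(gm.pos.max())
            ws = make_windows({"1": L}, L)
            got = wc_fst(gm, a, b, ws)[0]
            expect = brute_fst(gm.geno[:5], gm.geno[5:])
            if expect is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        gm = random_gm(rng, n_samples=8, n_sites=40)
        L = int(gm.pos.max())
        ws = make_windows({"1": L}, L // 2)
        a, b = gm.sample_ids[:4], gm.sample_ids[4:]
        ref = wc_fst(gm, a, b, ws)
        perm = wc_fst(gm, a[::-1], b[::-1], ws)
        np.testing.assert_allclose(ref, perm, atol=1e-14)

    def test_empty_pop_rejected(self):
        gm = gm_from_codes([[0], [2]])
        ws = make_windows({"1": 100}, 100)
        with pytest.raises(ValueError):
            wc_fst(gm, [], ["s1"], ws)


class TestPiRatioScan:
    def _two_group_gm(self, rng, n_sites=400):
        gm = random_gm(rng, n_samples=8, n_sites=n_sites, miss_frac=0.0)
        return gm, gm.sample_ids[:4], gm.sample_ids[4:]

    def test_ratio_value(self):
        # crop window pi 0.004, weed 0.001 -> ratio 4
        crop = np.tile([1, 1, 0, 0], (40, 1)).T.astype(np.int8)
        weed = np.zeros((4, 40), dtype=np.int8)
        weed[0, :10] = 1
        gm = gm_from_codes(np.vstack([crop, weed]),
                           positions=np.arange(1, 41) * 2)
        ws = make_windows({"1": 100}, 100)
        tab = pi_ratio_scan(gm, gm.sample_ids[:4], gm.sample_ids[4:], ws,
                            min_snps=5)
        got = tab.pi_ratio[0]
        pi_c = window_pi(gm, gm.sample_ids[:4], ws)[0]
        pi_w = window_pi(gm, gm.sample_ids[4:], ws)[0]
        assert got == pytest.approx(pi_c / pi_w)

    def test_zero_weed_pi_ineligible(self):
        crop = np.tile([1, 0], (10, 1)).T.astype(np.int8)
        weed = np.zeros((2, 10), dtype=np.int8)
        gm = gm_from_codes(np.vstack([crop, weed]))
        ws = make_windows({"1": 200}, 200)
        tab = pi_ratio_scan(gm, gm.sample_ids[:2], gm.sample_ids[2:], ws,
                            min_snps=1)
        assert not tab.eligible[0] and np.isnan(tab.pi_ratio[0])

    def test_top_fraction_counting(self):
        """100 eligible windows at top_frac 0.05 -> exactly 5 candidates."""
        rng = np.random.default_rng(6)
        n_win, per = 100, 12
        codes = []
        for w in range(n_win):
            block = rng.integers(0, 3, size=(8, per)).astype(np.int8)
            # guarantee segregation in both halves
            block[0, :] = 1
            block[4, :] = 1
            codes.append(block)
        codes = np.concatenate(codes, axis=1)
        positions = np.concatenate(
            [np.arange(per) * 5 + w * 100 + 1 for w in range(n_win)])
        gm = gm_from_codes(codes, positions=positions)
        ws = make_windows({"1": n_win * 100}, 100)
        tab = pi_ratio_scan(gm, gm.sample_ids[:4], gm.sample_ids[4:], ws,
                            top_frac=0.05, min_snps=1)
        assert int(tab.eligible.sum()) == 100
        ratios = tab.pi_ratio[tab.eligible]
        # no ties at the threshold in continuous random data
        assert int(tab.is_candidate.sum()) == 5
        assert set(tab.pi_ratio[tab.is_candidate]) == set(sorted(ratios)[-5:])

    def test_bad_top_frac(self):
        gm = gm_from_codes([[1], [0]])
        ws = make_windows({"1": 100}, 100)
        with pytest.raises(ValueError):
            pi_ratio_scan(gm, ["s0"], ["s1"], ws, top_frac=0.0)


class TestInvariants:
    def test_pi_theta_zero_iff_no_segregation(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            gm = random_gm(rng, n_samples=4, n_sites=20, miss_frac=0.3)
            L = int(gm.pos.max())
            ws = make_windows({"1": L}, max(L // 4, 1))
            pi = window_pi(gm, gm.sample_ids, ws)
            th = window_theta_w(gm, gm.sample_ids, ws)
            np.testing.assert_array_equal(pi == 0, th == 0)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(8)
        gm = random_gm(rng, n_samples=6, n_sites=30, miss_frac=0.1)
        L = int(gm.pos.max())
        ws = make_windows({"1": L}, L)
        perm = list(rng.permutation(gm.sample_ids))
        assert window_pi(gm, gm.sample_ids, ws)[0] == pytest.approx(
            window_pi(gm, perm, ws)[0], rel=1e-14)
        assert window_theta_w(gm, gm.sample_ids, ws)[0] == pytest.approx(
            window_theta_w(gm, perm, ws)[0], rel=1e-14)
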