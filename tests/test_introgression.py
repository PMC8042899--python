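"""ABBA/BABA D, block jackknife, f3, fd scan and region calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popgenscan.introgression import (SitePatterns, assign_blocks,
                                      call_introgressed_regions, f3_test,
                                      fd_scan, patterson_d, site_patterns,
                                      weighted_block_jackknife)
from popgenscan.popio import MISSING, PopulationMap

from conftest import make_table


def quartet_map():
    """2 diploids each for P1/P2/P3 plus one outgroup diploid."""
    m = {}
    for i, pop in enumerate(["P1", "P1", "P2", "P2", "P3", "P3", "O"]):
        m[f"s{i}"] = pop
    return PopulationMap(m, {"O"})


def patterns_from_freqs(p1, p2, p3, pos=None, chrom=None):
    """Build SitePatterns directly from derived-frequency triplets."""
    p1, p2, p3 = (np.asarray(x, dtype=float) for x in (p1, p2, p3))
    n = len(p1)
    return SitePatterns(
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n,
                       dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n + 1) * 10,
                       dtype=np.int64),
        p1=p1, p2=p2, p3=p3,
        abba=(1 - p1) * p2 * p3, baba=p1 * (1 - p2) * p3, n_excluded=0)


class TestSitePatterns:
    def test_pure_abba_and_uninformative(self):
        pm = quartet_map()
        # site1: p1=0, p2=1, p3=1 (outgroup ancestral) -> abba=1
        # site2: p3=0 -> both terms 0
        vt = make_table([[0, 0, 2, 2, 2, 2, 0],
                         [2, 2, 0, 0, 0, 0, 0]])
        pat = site_patterns(vt, pm, "P1", "P2", "P3", "O")
        assert pat.abba[0] == 1.0 and pat.baba[0] == 0.0
        assert pat.abba[1] == 0.0 and pat.baba[1] == 0.0

    def test_product_arithmetic(self):
        pm = quartet_map()
        # p1=0.25, p2=0.75, p3=0.5 with outgroup fixed ref
        vt = make_table([[1, 0, 1, 2, 1, 1, 0]])
        pat = site_patterns(vt, pm, "P1", "P2", "P3", "O")
        assert pat.abba[0] == pytest.approx(0.75 * 0.75 * 0.5)
        assert pat.baba[0] == pytest.approx(0.25 * 0.25 * 0.5)

    def test_overlapping_populations_rejected(self):
        pm = PopulationMap({"s0": "P1", "s1": "P2", "s2": "P3", "s3": "O"})
        pm.assignments["s1"] = "P1"  # P2 now empty -> use same sample twice
        vt = make_table([[0, 0, 0, 0]])
        with pytest.raises(KeyError):
            site_patterns(vt, pm, "P1", "P2", "P3", "O")

    def test_count_mode_rounds_to_majority(self):
        pm = quartet_map()
        vt = make_table([[1, 0, 1, 2, 1, 1, 0]])
        pat = site_patterns(vt, pm, "P1", "P2", "P3", "O", mode="count")
        assert pat.p1[0] == 0.0 and pat.p2[0] == 1.0 and pat.p3[0] == 0.0


class TestPattersonD:
    def test_three_site_fixture_term_by_term(self):
        pat = patterns_from_freqs([0.2, 0.5, 0.1], [0.8, 0.5, 0.3],
                                  [0.6, 0.9, 0.7],
                                  pos=[10, 2_000_010, 4_000_010])
        # brute-force oracle: six products summed by hand
        abba = [(1 - .2) * .8 * .6, (1 - .5) * .5 * .9, (1 - .1) * .3 * .7]
        baba = [.2 * (1 - .8) * .6, .5 * (1 - .5) * .9, .1 * (1 - .3) * .7]
        expected = (sum(abba) - sum(baba)) / (sum(abba) + sum(baba))
        res = patterson_d(pat, block_size_bp=2_000_000)
        assert res.estimate == pytest.approx(expected, rel=1e-12)
        assert res.estimate == pytest.approx(0.45620437956, rel=1e-9)
        assert res.n_blocks == 3

    def test_symmetric_counts_give_zero(self):
        pat = patterns_from_freqs([0.2, 0.8], [0.8, 0.2], [0.5, 0.5],
                                  pos=[10, 1_000_010])
        res = patterson_d(pat, block_size_bp=1_000_000)
        assert res.estimate == pytest.approx(0.0, abs=1e-15)

    def test_identical_blocks_zero_se_infinite_z(self):
        pat = patterns_from_freqs([0.2, 0.2], [0.8, 0.8], [0.6, 0.6],
                                  pos=[10, 3_000_010])
        res = patterson_d(pat, block_size_bp=2_000_000)
        assert res.se == 0.0 and np.isinf(res.z)

    def test_all_uninformative_raises(self):
        pat = patterns_from_freqs([0.5, 0.5], [0.5, 0.5], [0.0, 0.0],
                                  pos=[10, 3_000_010])
        with pytest.raises(ZeroDivisionError):
            patterson_d(pat, block_size_bp=2_000_000)

    def test_swapping_p1_p2_negates_d(self, rng):
        p1, p2, p3 = rng.random((3, 60))
        pos = np.arange(60) * 500_000 + 1
        a = patterson_d(patterns_from_freqs(p1, p2, p3, pos), 2_000_000)
        b = patterson_d(patterns_from_freqs(p2, p1, p3, pos), 2_000_000)
        assert a.estimate == pytest.approx(-b.estimate, rel=1e-12)
        assert abs(a.estimate) <= 1.0

    def test_remove_and_restore_block_identity(self, rng):
        p1, p2, p3 = rng.random((3, 40))
        pos = np.arange(40) * 700_000 + 1
        pat = patterns_from_freqs(p1, p2, p3, pos)
        res = patterson_d(pat, 2_000_000)
        num, den = pat.abba - pat.baba, pat.abba + pat.baba
        blocks = assign_blocks(pat.chrom, pat.pos, 2_000_000)
        for b in np.unique(blocks):
            m = blocks == b
            loo = num[~m].sum() / den[~m].sum()
            restored = (loo * den[~m].sum() + num[m].sum()) / den.sum()
            assert restored == pytest.approx(res.estimate, abs=1e-12)


class TestWeightedJackknife:
    def test_se_matches_closed_form_oracle(self, rng):
        num = rng.normal(size=100)
        den = rng.random(100) + 0.5
        blocks = np.repeat(np.arange(10), 10)
        est, se, loo, m = weighted_block_jackknife(num, den, blocks)
        # independent transcription of the weighted delete-one formula
        theta = num.sum() / den.sum()
        loo_o = np.array([num[blocks != b].sum() / den[blocks != b].sum()
                          for b in range(10)])
        mj = np.array([den[blocks == b].sum() for b in range(10)])
        n, g = mj.sum(), 10
        h = n / mj
        theta_J = g * theta - np.sum((1 - mj / n) * loo_o)
        tau = h * theta - (h - 1) * loo_o
        var = np.sum((tau - theta_J) ** 2 / (h - 1)) / g
        assert est == pytest.approx(theta, rel=1e-14)
        assert se == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_reduces_to_classical_jackknife_for_equal_weights(self, rng):
        num = rng.normal(size=50)
        blocks = np.repeat(np.arange(10), 5)
        den = np.ones(50)
        _, se, loo, _ = weighted_block_jackknife(num, den, blocks)
        g = 10
        classical = np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2))
        assert se == pytest.approx(classical, rel=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_recombination_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(2, 12)
        sizes = rng.integers(1, 8, size=g)
        num = rng.normal(size=sizes.sum())
        den = rng.random(sizes.sum()) + 0.1
        blocks = np.repeat(np.arange(g), sizes)
        est, _, loo, m = weighted_block_jackknife(num, den, blocks)
        n = m.sum()
        # the global ratio is the weight-share mix of the within-block
        # ratios, and equivalently of any delete-one/block pair
        block_num = np.array([num[blocks == b].sum() for b in range(g)])
        theta_blocks = block_num / m
        assert np.sum(m / n * theta_blocks) == pytest.approx(est, rel=1e-10)
        for j in range(g):
            restored = (loo[j] * (n - m[j]) + block_num[j]) / n
            assert restored == pytest.approx(est, abs=1e-12)


class TestMigrationSignal:
    """Simulation-level properties: gene flow produces positive, significant
    D, and more admixture never weakens the tract-level fd signal."""

    def test_p3_to_p2_migration_gives_positive_significant_d(self):
        # DomCN<->SEASA gene flow (registry model M3, strong continuous
        # migration) versus Wild as P1, on the full default panel: D > 0
        # with Z > 3 in >= 90% of replicates. The full sample sizes matter
        # - per-site frequency noise at 5 diploids/population drowns the
        # Z signal. The no-migration calibration of the D machinery lives
        # in the acceptance suite.
        from popgenscan.synth import (DEFAULT_TRUE_PARAMS, ScenarioConfig,
                                      generate_fixture)

        n_ok = 0
        reps = 10
        for seed in range(1, reps + 1):
            cfg = ScenarioConfig(
                chrom_lengths={"chr1": 8_000_000}, locus_bp=10_000,
                model_name="M3",
                params=dict(DEFAULT_TRUE_PARAMS, M_DOM_SEASA=20.0),
                seed=seed)
            fx = generate_fixture(cfg)
            pat = site_patterns(fx.vt, fx.popmap, "Wild", "DomCN", "SEASA",
                                "Outgroup")
            res = patterson_d(pat, block_size_bp=200_000)
            n_ok += bool(res.estimate > 0 and res.z > 3)
        assert n_ok >= 0.9 * reps

    def test_fd_grows_with_admixture_fraction(self):
        from popgenscan.popio import make_windows
        from popgenscan.synth import (IntrogressionPlant, ScenarioConfig,
                                      generate_fixture)

        tract = ("chr1", 400_001, 800_000)
        means = []
        for fraction in (0.25, 0.5, 1.0):
            vals = []
            for seed in (1, 2, 3):
                cfg = ScenarioConfig(
                    sample_sizes={"Wild": 5, "DomCN": 8, "SEASA": 5,
                                  "Outgroup": 2},
                    chrom_lengths={"chr1": 1_200_000}, locus_bp=10_000,
                    model_name="M1", seed=seed,
                    introgression=IntrogressionPlant(
                        "SEASA", "DomCN", *tract, fraction=fraction))
                fx = generate_fixture(cfg)
                pat = site_patterns(fx.vt, fx.popmap, "Wild", "DomCN",
                                    "SEASA", "Outgroup")
                win = make_windows(fx.vt, 100_000, 20_000)
                fdw = fd_scan(pat, win, min_snps=50)
                in_tract = (fdw["start"] >= tract[1]) & (fdw["end"]
                                                         <= tract[2])
                vals.append(fdw.loc[in_tract, "fd"].mean())
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


class TestF3:
    def test_admixed_midpoint_is_negative(self):
        # pA = (pB+pC)/2 with pB != pC: raw term -((pB-pC)/2)^2 < 0
        pm = PopulationMap({"a1": "A", "a2": "A", "a3": "A", "a4": "A",
                            "b1": "B", "b2": "B", "c1": "C", "c2": "C"})
        rng = np.random.default_rng(5)
        pb = np.array([1.0, 0.0, 1.0] * 10)
        pc = np.array([0.0, 1.0, 0.0] * 10)
        g = np.zeros((30, 8), dtype=np.int8)
        g[:, 4:6] = (2 * pb[:, None]).astype(np.int8)
        g[:, 6:8] = (2 * pc[:, None]).astype(np.int8)
        g[:, 0:4] = 1  # pA = 0.5 exactly
        vt = make_table(g, pos=np.arange(30) * 300_000 + 1,
                        samples=["a1", "a2", "a3", "a4", "b1", "b2",
                                 "c1", "c2"])
        res = f3_test(vt, pm, "A", "B", "C", block_size_bp=2_000_000)
        assert res.estimate < 0

    def test_symmetric_in_sources(self, rng):
        pm = PopulationMap({f"s{i}": p for i, p in enumerate(
            ["A"] * 3 + ["B"] * 2 + ["C"] * 2)})
        g = rng.integers(0, 3, size=(40, 7)).astype(np.int8)
        vt = make_table(g, pos=np.arange(40) * 200_000 + 1)
        ab = f3_test(vt, pm, "A", "B", "C")
        ba = f3_test(vt, pm, "A", "C", "B")
        assert ab.estimate == pytest.approx(ba.estimate, rel=1e-14)

    def test_twenty_site_hand_summed_oracle(self, rng):
        pm = PopulationMap({f"s{i}": p for i, p in enumerate(
            ["A"] * 3 + ["B"] * 2 + ["C"] * 2)})
        g = rng.integers(0, 3, size=(20, 7)).astype(np.int8)
        vt = make_table(g, pos=np.arange(20) * 500_000 + 1)
        res = f3_test(vt, pm, "A", "B", "C", block_size_bp=2_000_000)
        terms = []
        for s in range(20):
            na = 6
            pa = g[s, :3].sum() / na
            pb = g[s, 3:5].sum() / 4
            pc = g[s, 5:7].sum() / 4
            ha = pa * (1 - pa) * na / (na - 1)
            terms.append((pa - pb) * (pa - pc) - ha / na)
        assert res.estimate == pytest.approx(np.mean(terms), rel=1e-12)


class TestFdScan:
    def win(self, start=1, end=1000):
        return pd.DataFrame([{"chrom": "chr1", "start": start, "end": end,
                              "n_snps": 2, "excluded": False}])

    def test_p2_equals_p3_gives_fd_one(self):
        pat = patterns_from_freqs([0.1, 0.0], [0.8, 0.7], [0.8, 0.7])
        out = fd_scan(pat, self.win(), min_snps=1)
        assert out["fd"].iloc[0] == pytest.approx(1.0)

    def test_negative_window_d_zeroed(self):
        pat = patterns_from_freqs([0.9, 0.8], [0.1, 0.2], [0.9, 0.9])
        out = fd_scan(pat, self.win(), min_snps=1)
        assert out["d_window"].iloc[0] < 0
        assert out["fd"].iloc[0] == 0.0

    def test_two_site_hand_evaluated_products(self):
        # sites (0, 0.5, 1.0) and (0, 1.0, 0.5): num = 1.0, den = 2.0
        pat = patterns_from_freqs([0.0, 0.0], [0.5, 1.0], [1.0, 0.5])
        out = fd_scan(pat, self.win(), min_snps=1)
        assert out["fd"].iloc[0] == pytest.approx(0.5, rel=1e-12)

    def test_min_snps_exclusion_flag(self):
        pat = patterns_from_freqs([0.1], [0.8], [0.8])
        out = fd_scan(pat, self.win(), min_snps=100)
        assert bool(out["excluded"].iloc[0])


class TestRegionCalling:
    def fdw(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "fd"])
        df["excluded"] = False
        df["n_snps"] = 200
        return df

    def test_no_passing_windows_empty(self):
        out = call_introgressed_regions(
            self.fdw([("chr1", 1, 100_000, 0.3)]))
        assert len(out) == 0

    def test_six_overlapping_windows_span_exactly_200kb(self):
        rows = [("chr1", s, s + 99_999, 0.6)
                for s in range(1, 100_002, 20_000)]
        out = call_introgressed_regions(self.fdw(rows), 0.5, 200_000)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["start"], r["end"]) == (1, 200_000)
        assert r["end"] - r["start"] + 1 == 200_000
        assert r["n_windows"] == 6

    def test_isolated_window_below_min_length_dropped(self):
        out = call_introgressed_regions(
            self.fdw([("chr1", 1, 100_000, 0.9)]), 0.5, 200_000)
        assert len(out) == 0

    def test_hand_enumerated_merge_with_gap(self):
        rows = [("chr1", 1, 100_000, 0.6),
                ("chr1", 80_001, 180_000, 0.7),
                ("chr1", 100_001, 200_000, 0.55),   # bookended to previous
                ("chr1", 500_001, 600_000, 0.8),    # isolated -> dropped
                ("chr2", 1, 100_000, 0.9),
                ("chr2", 100_001, 200_000, 0.5)]    # bookended pair on chr2
        out = call_introgressed_regions(self.fdw(rows), 0.5, 200_000)
        assert len(out) == 2
        assert out.iloc[0][["chrom", "start", "end"]].tolist() == \
            ["chr1", 1, 200_000]
        assert out.iloc[0]["peak_fd"] == pytest.approx(0.7)
        assert out.iloc[0]["mean_fd"] == pytest.approx((0.6 + 0.7 + 0.55) / 3)
        assert out.iloc[1][["chrom", "start", "end"]].tolist() == \
            ["chr2", 1, 200_000]

    def test_excluded_windows_never_seed_regions(self):
        df = self.fdw([("chr1", 1, 100_000, 0.9),
                       ("chr1", 100_001, 200_000, 0.9)])
        df.loc[0, "excluded"] = True
        out = call_introgressed_regions(df, 0.5, 100_000)
        assert len(out) == 1 and out.iloc[0]["start"] == 100_001
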