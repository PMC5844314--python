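"""Window statistics against brute-force oracles, and outlier calling."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from popsweep import scan
from popsweep.annotate import GeneModel
from popsweep.matrix import MISSING
from popsweep.sim import SimConfig, simulate_dataset

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles


def brute_site_pi(alt: int, n: int) -> float:
    """Fraction of differing allele pairs, by exhaustive enumeration."""
    alleles = [1] * alt + [0] * (n - alt)
    pairs = list(combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_window_pi(matrix, population, window):
    rows = matrix.sample_indices(population)
    total = 0.0
    v = matrix.variants
    for j in range(matrix.n_variants):
        if v["contig"].iat[j] != window.contig:
            continue
        p0 = int(v["pos"].iat[j]) - 1
        if not window.start <= p0 < window.end:
            continue
        alleles = []
        for r in rows:
            d = int(matrix.dosages[r, j])
            if d != MISSING:
                alleles += [1] * d + [0] * (2 - d)
        if len(alleles) < 2:
            continue
        pairs = list(combinations(alleles, 2))
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total / window.length


def brute_window_fst(matrix, pop1, pop2, window):
    num_sum = den_sum = 0.0
    v = matrix.variants
    r1 = matrix.sample_indices(pop1)
    r2 = matrix.sample_indices(pop2)
    for j in range(matrix.n_variants):
        if v["contig"].iat[j] != window.contig:
            continue
        p0 = int(v["pos"].iat[j]) - 1
        if not window.start <= p0 < window.end:
            continue

        def freq(rows):
            alleles = []
            for r in rows:
                d = int(matrix.dosages[r, j])
                if d != MISSING:
                    alleles += [1] * d + [0] * (2 - d)
            return (sum(alleles) / len(alleles), len(alleles)) if len(alleles) >= 2 else (None, 0)

        p1, n1 = freq(r1)
        p2, n2 = freq(r2)
        if p1 is None or p2 is None:
            continue
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        num_sum += num
        den_sum += den
    return num_sum / den_sum if den_sum else float("nan")


# ---------------------------------------------------------------------------


class TestSitePi:
    @pytest.mark.parametrize(
        "alt,n,expected",
        [(2, 4, 4 / 6), (0, 8, 0.0), (1, 2, 1.0), (3, 10, None)],
    )
    def test_matches_exhaustive_pair_count(self, alt, n, expected):
        value = scan.site_pi(alt, n)
        oracle = brute_site_pi(alt, n)
        assert value == pytest.approx(oracle, abs=1e-12)
        if expected is not None:
            assert value == pytest.approx(expected, abs=1e-9)

    def test_too_few_alleles_rejected(self):
        with pytest.raises(ValueError):
            scan.site_pi(0, 1)


class TestHudsonFstSite:
    def test_fixed_difference(self):
        num, den = scan.hudson_fst_site(1.0, 10, 0.0, 10)
        assert (num, den) == (1.0, 1.0)

    def test_plug_in_arithmetic(self):
        num, den = scan.hudson_fst_site(0.5, 10, 0.5, 10)
        assert num == pytest.approx(-0.05555555, abs=1e-6)
        assert den == pytest.approx(0.5)

    def test_no_differentiation_large_n(self):
        num, _ = scan.hudson_fst_site(0.3, 10**9, 0.3, 10**9)
        assert abs(num) < 1e-8

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            scan.hudson_fst_site(0.5, 1, 0.5, 10)


class TestMakeWindows:
    def test_enumeration(self):
        w = scan.make_windows({"c": 100_000}, 40_000, 20_000)
        assert [x.start for x in w] == [0, 20_000, 40_000, 60_000]
        assert all(x.end - x.start == 40_000 for x in w)

    def test_contig_shorter_than_window(self):
        assert scan.make_windows({"c": 39_999}, 40_000, 20_000) == []

    def test_step_equals_size_tiles(self):
        w = scan.make_windows({"c": 120_000}, 40_000, 40_000)
        assert [(x.start, x.end) for x in w] == [
            (0, 40_000),
            (40_000, 80_000),
            (80_000, 120_000),
        ]

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            scan.make_windows({"c": 100}, 0, 1)
        with pytest.raises(ValueError):
            scan.make_windows({"c": 100}, 10, 20)


class TestWindowStatistics:
    def test_window_pi_hand_set(self):
        dos = np.array(
            [  # 10 samples x 3 sites, with one missing call
                [0, 1, 2],
                [1, 0, 2],
                [2, 1, 1],
                [0, 0, 2],
                [1, 2, 0],
                [0, 1, 2],
                [2, 0, 1],
                [1, 1, 2],
                [0, 2, MISSING],
                [1, 0, 2],
            ]
        )
        m = make_matrix(dos, positions=[100, 200, 300])
        w = scan.Window("chr1", 0, 1_000)
        assert scan.window_pi(m, None, w) == pytest.approx(
            brute_window_pi(m, None, w), abs=1e-12
        )

    def test_window_without_snps_is_zero(self):
        m = make_matrix(np.array([[1], [0]]), positions=[5_000])
        assert scan.window_pi(m, None, scan.Window("chr1", 0, 1_000)) == 0.0

    def test_doubling_length_halves_pi(self):
        dos = np.random.default_rng(0).integers(0, 3, size=(10, 5))
        m = make_matrix(dos, positions=[10, 20, 30, 40, 50])
        a = scan.window_pi(m, None, scan.Window("chr1", 0, 100))
        b = scan.window_pi(m, None, scan.Window("chr1", 0, 200))
        assert a == pytest.approx(2 * b)

    def test_window_fst_hand_set_five_sites(self):
        dos = np.array(
            [
                [0, 2, 1, 0, 2],
                [1, 2, 0, 0, 2],
                [0, 1, 1, 1, 2],
                [2, 0, 2, 2, 0],
                [2, 0, 2, 1, 0],
                [1, 0, 2, 2, MISSING],
            ]
        )
        pops = ["p1"] * 3 + ["p2"] * 3
        m = make_matrix(dos, positions=[10, 20, 30, 40, 50], populations=pops)
        w = scan.Window("chr1", 0, 100)
        assert scan.window_fst(m, "p1", "p2", w) == pytest.approx(
            brute_window_fst(m, "p1", "p2", w), abs=1e-12
        )

    def test_all_fixed_differences_give_one(self):
        dos = np.array([[0, 0, 0]] * 4 + [[2, 2, 2]] * 4)
        pops = ["p1"] * 4 + ["p2"] * 4
        m = make_matrix(dos, populations=pops)
        assert scan.window_fst(m, "p1", "p2", scan.Window("chr1", 0, 1_000)) == 1.0

    def test_oracle_equivalence_on_simulation(self):
        """window_scan equals brute-force enumeration on every window."""
        cfg = SimConfig(
            contigs=[("c1", 100_000)],
            pop_names=["x", "y"],
            samples_per_pop=[25, 25],
            f_per_pop=[0.15, 0.15],
            snp_density=0.002,
            missing_rate=0.05,
            seed=21,
        )
        matrix, _ = simulate_dataset(cfg)
        assert matrix.n_samples == 50 and matrix.n_variants >= 180
        lengths = {"c1": 100_000}
        stats = scan.window_scan(matrix, "x", "y", lengths, 40_000, 20_000)
        for _, row in stats.iterrows():
            w = scan.Window(row["contig"], int(row["start"]), int(row["end"]))
            assert row["pi_target"] == pytest.approx(
                brute_window_pi(matrix, "x", w), abs=1e-9
            )
            assert row["pi_reference"] == pytest.approx(
                brute_window_pi(matrix, "y", w), abs=1e-9
            )
            bf = brute_window_fst(matrix, "x", "y", w)
            if np.isnan(bf):
                assert np.isnan(row["fst"])
            else:
                assert row["fst"] == pytest.approx(bf, abs=1e-9)

    def test_fst_bounded_above_by_one(self, two_pop_dataset):
        matrix, _ = two_pop_dataset
        stats = scan.window_scan(matrix, "a", "b", {"chr1": 200_000})
        assert np.nanmax(stats["fst"]) <= 1.0

    def test_fst_calibration_window_level(self):
        fsts = []
        for seed in range(10):
            cfg = SimConfig(
                contigs=[("c1", 200_000)],
                pop_names=["x", "y"],
                samples_per_pop=[20, 20],
                f_per_pop=[0.15, 0.15],
                snp_density=0.01,
                missing_rate=0.0,
                seed=50 + seed,
            )
            matrix, _ = simulate_dataset(cfg)
            stats = scan.window_scan(matrix, "x", "y", {"c1": 200_000})
            fsts.append(np.nanmean(stats["fst"]))
        assert abs(np.mean(fsts) - 0.15) < 0.03

    def test_scale_invariance(self):
        """Same SNPs on stretched coordinates: FST and π-ratio unchanged."""
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(20, 50))
        pos = np.sort(rng.choice(80_000, size=50, replace=False)) + 1
        pops = ["p1"] * 10 + ["p2"] * 10
        m1 = make_matrix(dos, positions=pos, populations=pops)
        m2 = make_matrix(dos, positions=pos * 2 - 1, populations=pops)
        s1 = scan.window_scan(m1, "p1", "p2", {"chr1": 80_000}, 20_000, 10_000)
        s2 = scan.window_scan(m2, "p1", "p2", {"chr1": 160_000}, 40_000, 20_000)
        assert s1["n_snps"].tolist() == s2["n_snps"].tolist()
        assert np.allclose(s1["fst"], s2["fst"], equal_nan=True)
        assert np.allclose(s1["pi_ratio"], s2["pi_ratio"], equal_nan=True)
        # per-bp diversity scales inversely with the stretch factor
        assert np.allclose(s1["pi_target"], 2 * s2["pi_target"], equal_nan=True)


class TestOutlierCalling:
    def _null_stats(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "contig": "c1",
                "start": np.arange(n) * 20_000,
                "end": np.arange(n) * 20_000 + 40_000,
                "n_snps": 50,
                "fst": rng.normal(0.1, 0.01, n),
                "pi_target": 0.001,
                "pi_reference": 0.001,
                "pi_ratio": np.exp(rng.normal(0, 0.05, n)),
                "log2_ratio": rng.normal(0, 0.05, n),
            }
        )

    def test_single_double_extreme_window_is_the_only_region(self):
        # noise ranks anti-correlated between the two statistics, so no
        # background window can sit in both top-5% sets; window 57 is
        # extreme in both by construction
        stats = self._null_stats()
        n = len(stats)
        stats["fst"] = 0.1 + 0.0001 * np.arange(n)
        stats["log2_ratio"] = 0.0001 * np.arange(n)[::-1]
        stats.loc[57, "fst"] = 0.9
        stats.loc[57, "log2_ratio"] = 3.0
        scored, regions = scan.call_sweep_regions(stats, top_frac=0.05)
        assert len(regions) == 1
        r = regions[0]
        assert r.start <= 57 * 20_000 < r.end
        assert scored.loc[57, "is_outlier"]
        assert scored["is_outlier"].sum() == 1

    def test_top_frac_one_selects_everything(self):
        stats = self._null_stats()
        scored, regions = scan.call_sweep_regions(stats, top_frac=1.0)
        assert scored["is_outlier"].all()
        assert len(regions) == 1  # merged into one region per contig

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="20 windows"):
            scan.call_sweep_regions(self._null_stats(n=10))

    def test_joint_calling_is_stricter_than_marginal(self):
        stats = self._null_stats(seed=5)
        joint, _ = scan.call_sweep_regions(stats, joint=True)
        union, _ = scan.call_sweep_regions(stats, joint=False)
        assert joint["is_outlier"].sum() <= union["is_outlier"].sum()

    def test_null_joint_fraction_reflects_statistic_coupling(self):
        """With a small target panel the two z-scores are positively
        correlated through shared sampling noise, so the joint outlier
        fraction falls between the independence expectation q² and the
        marginal q."""
        tot = n = 0
        for seed in range(5):
            cfg = SimConfig(contigs=[("c1", 2_000_000)], seed=100 + seed)
            matrix, _ = simulate_dataset(cfg)
            stats = scan.window_scan(matrix, "target", "reference", {"c1": 2_000_000})
            scored, _ = scan.call_sweep_regions(stats)
            tot += int(scored["is_outlier"].sum())
            n += len(scored)
        frac = tot / n
        assert 0.05**2 <= frac <= 0.05

    def test_planted_sweep_recovered(self, sweep_dataset):
        cfg, matrix, truth = sweep_dataset
        stats = scan.window_scan(matrix, "target", "reference", dict(cfg.contigs))
        _, regions = scan.call_sweep_regions(stats)
        sw = truth.sweep_intervals[0]
        assert any(r.start < sw.end and r.end > sw.start for r in regions)


class TestAssignGenes:
    def _genes(self):
        return [
            GeneModel("gA", "c1", "+", exons=[(1_000, 2_000)]),
            GeneModel("gB", "c1", "+", exons=[(15_000, 18_000)]),
            GeneModel("gC", "c1", "-", exons=[(30_000, 31_000)]),
        ]

    def test_known_overlaps(self):
        regions = [
            scan.SweepRegion("c1", 0, 16_000, 1.0, 1.0),
            scan.SweepRegion("c1", 17_000, 25_000, 1.0, 1.0),
        ]
        regions, all_genes = scan.assign_genes(regions, self._genes())
        assert regions[0].genes == ["gA", "gB"]
        assert regions[1].genes == ["gB"]
        assert all_genes == ["gA", "gB"]  # gB deduplicated globally

    def test_region_without_genes(self):
        regions = [scan.SweepRegion("c1", 50_000, 60_000, 1.0, 1.0)]
        regions, all_genes = scan.assign_genes(regions, self._genes())
        assert regions[0].genes == []
        assert all_genes == []
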