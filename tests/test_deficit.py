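"""Window enumeration, haplotype extraction, homozygote expectation and the
exact binomial deficit test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from layervar.deficit import (
    DEFAULT_WINDOW_SIZES,
    binomial_deficit_test,
    enumerate_windows,
    expected_homozygotes,
    extract_haplotypes,
    het_progeny_fraction,
    merge_significant_loci,
    qc_filter_panel,
    scan,
)
from layervar.population import build_mating_table

from conftest import build_population, het_by_het_population


def poisson_binomial_cdf(observed, probs):
    """Exact Poisson-binomial lower tail by dynamic programming (oracle)."""
    dist = np.zeros(len(probs) + 1)
    dist[0] = 1.0
    for p in probs:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return float(dist[: observed + 1].sum())


class TestPanelQC:
    def _toy(self):
        # 6 SNPs x 5 animals; SNP3 monomorphic (MAF 0), SNP4 call rate 0.75
        # after the low-call-rate animal is dropped, SNP5 on chromosome Z;
        # animal 4 has call rate 0.4 on the autosomal SNPs.
        snp_map = pd.DataFrame(
            {"chrom": ["1", "1", "1", "1", "2", "Z"], "bp": [10, 20, 30, 40, 10, 10]}
        )
        g = np.array(
            [
                [0, 1, 2, 0, 1, 0],
                [1, 0, 1, 0, 2, 1],
                [2, 1, 0, 0, 1, 0],
                [1, 2, 1, 0, -1, 1],
                [-1, -1, 0, 0, -1, 1],
            ]
        )
        return g, snp_map

    def test_hand_enumerated_fixture(self):
        g, snp_map = self._toy()
        out, animals, snps, report = qc_filter_panel(g, snp_map)
        assert out.shape == (4, 3)
        assert list(snps) == [0, 1, 2]
        assert list(animals) == [0, 1, 2, 3]
        assert report["removed_unmapped_or_sex_snps"] == 1
        assert report["removed_animals_callrate"] == 1
        assert report["removed_snps_maf"] == 1
        assert report["removed_snps_callrate"] == 1

    def test_clean_matrix_unchanged(self):
        g = np.array([[0, 1], [1, 2], [2, 0], [1, 1]])
        snp_map = pd.DataFrame({"chrom": ["1", "1"], "bp": [10, 20]})
        out, animals, snps, _ = qc_filter_panel(g, snp_map)
        assert np.array_equal(out, g)

    def test_maf_exactly_at_threshold_removed(self):
        # 100 animals, one heterozygote: MAF exactly 0.01 fails "higher than"
        g = np.zeros((100, 2), dtype=int)
        g[0, 0] = 2
        g[:50, 1] = 1  # companion SNP with MAF 0.25
        snp_map = pd.DataFrame({"chrom": ["1", "1"], "bp": [10, 20]})
        out, _, snps, _ = qc_filter_panel(g, snp_map)
        assert list(snps) == [1]

    def test_everything_filtered_errors(self):
        g = np.full((3, 2), -1)
        snp_map = pd.DataFrame({"chrom": ["1", "1"], "bp": [10, 20]})
        with pytest.raises(ValueError, match="stage counts"):
            qc_filter_panel(g, snp_map)


class TestEnumerateWindows:
    def _map(self, n, length, chrom="1"):
        return pd.DataFrame(
            {"chrom": chrom, "bp": np.linspace(0, length - 1, n, dtype=int)}
        )

    def test_seven_windows_on_two_megabases(self):
        snp_map = self._map(200, 2_000_000)
        wins = enumerate_windows(
            snp_map, [500_000], 0.5, chrom_lengths={"1": 2_000_000}
        )
        assert [w.start for w in wins] == [0, 250_000, 500_000, 750_000,
                                           1_000_000, 1_250_000, 1_500_000]
        assert all(w.size == 500_000 for w in wins)

    def test_short_chromosome_single_window(self):
        snp_map = self._map(10, 100_000)
        wins = enumerate_windows(snp_map, [500_000], 0.5,
                                 chrom_lengths={"1": 100_000})
        assert len(wins) == 1
        assert (wins[0].start, wins[0].end) == (0, 100_000)

    def test_final_anchored_window_added(self):
        snp_map = self._map(100, 1_100_000)
        wins = enumerate_windows(snp_map, [500_000], 0.5,
                                 chrom_lengths={"1": 1_100_000})
        assert wins[-1].start == 600_000 and wins[-1].end == 1_100_000

    def test_interior_coverage_at_default_sizes(self):
        """Every interior bp is covered by >= 2 overlapping windows per size."""
        snp_map = self._map(600, 3_000_000)
        for size in DEFAULT_WINDOW_SIZES:
            wins = enumerate_windows(snp_map, [size], 0.5,
                                     chrom_lengths={"1": 3_000_000})
            step = size // 2
            for bp in range(size, 3_000_000 - size, 7919):
                n_cover = sum(w.start <= bp < w.end for w in wins)
                assert n_cover >= 2, (size, bp)

    def test_unsorted_map_errors(self):
        snp_map = pd.DataFrame({"chrom": ["1", "1"], "bp": [20, 10]})
        with pytest.raises(ValueError, match="sorted"):
            enumerate_windows(snp_map, [500_000])


class TestExtractHaplotypes:
    def test_single_homozygous_haplotype(self):
        inds = [
            (f"I{i}", "L", None, None, "M", 0, ("0101", "0101")) for i in range(4)
        ]
        pop = build_population([10, 20, 30, 40], inds)
        wins = enumerate_windows(pop.snp_map, [50], 1.0, chrom_lengths={"1": 50})
        haps, n = extract_haplotypes(pop, wins[0])
        assert n == 1
        assert haps[0].alleles == "0101"
        assert haps[0].frequency == 1.0
        assert (haps[0].copies == 2).all()

    def test_rare_haplotype_filtered_at_half_percent(self):
        # 1,000 individuals; 9 of 2,000 chromosomes carry "11" -> 0.0045
        inds = []
        for i in range(1000):
            h = "11" if i < 9 else "00"
            inds.append((f"I{i}", "L", None, None, "M", 0, (h, "00")))
        pop = build_population([10, 20], inds)
        wins = enumerate_windows(pop.snp_map, [30], 1.0, chrom_lengths={"1": 30})
        haps, _ = extract_haplotypes(pop, wins[0], freq_min=0.005)
        assert [h.alleles for h in haps] == ["00"]

    def test_missing_alleles_exclude_individual(self):
        inds = [
            ("A", "L", None, None, "M", 0, ("11", "11")),
            ("B", "L", None, None, "M", 0, ("1.", "11")),
        ]
        pop = build_population([10, 20], inds)
        wins = enumerate_windows(pop.snp_map, [30], 1.0, chrom_lengths={"1": 30})
        haps, _ = extract_haplotypes(pop, wins[0])
        assert haps[0].frequency == 1.0  # denominator excludes B
        assert haps[0].copies[1] == -1

    def test_lethal_haplotype_recovered_at_configured_frequency(
        self, lethal_config, lethal_population
    ):
        chrom, start, end = lethal_config.lethal_window
        idx = lethal_population.window_snp_indices(chrom, start, end)
        from layervar.deficit import Window

        win = Window(chrom=chrom, start=start, end=end, snp_indices=idx)
        haps, _ = extract_haplotypes(lethal_population, win)
        founders = lethal_population.individuals["generation"].to_numpy() == 0
        tags = lethal_population.lethal_tags[founders]
        tag_freq = tags.mean()
        # the most frequent haplotype containing every tagged chromosome
        top = haps[0]
        n_chrom = 2 * founders.sum()
        se = np.sqrt(0.05 * 0.95 / n_chrom)
        assert top.frequency >= tag_freq - 1e-12
        assert abs(tag_freq - 0.05) < 3 * se


class TestExpectedHomozygotes:
    def test_het_by_het_is_quarter_of_offspring(self):
        pop = het_by_het_population(n_offspring=20)
        wins = enumerate_windows(pop.snp_map, [10_000], 1.0,
                                 chrom_lengths={"1": 10_000})
        haps, _ = extract_haplotypes(pop, wins[0])
        target = [h for h in haps if h.alleles == "1111"][0]
        E, n = expected_homozygotes(target, pop)
        assert n == 20
        assert E == pytest.approx(20 / 4)

    def test_homozygous_sire_doubles_expectation(self):
        inds = [
            ("S", "L", None, None, "M", 0, ("11", "11")),
            ("D", "L", None, None, "F", 0, ("11", "00")),
        ]
        inds += [(f"O{i}", "L", "S", "D", "M", 1, ("11", "00")) for i in range(10)]
        pop = build_population([10, 20], inds)
        wins = enumerate_windows(pop.snp_map, [30], 1.0, chrom_lengths={"1": 30})
        haps, _ = extract_haplotypes(pop, wins[0])
        target = [h for h in haps if h.alleles == "11"][0]
        E, n = expected_homozygotes(target, pop)
        assert (E, n) == (5.0, 10)

    def test_no_carrier_matings(self):
        pop = het_by_het_population(n_offspring=5)
        wins = enumerate_windows(pop.snp_map, [10_000], 1.0,
                                 chrom_lengths={"1": 10_000})
        haps, _ = extract_haplotypes(pop, wins[0])
        other = [h for h in haps if h.alleles == "0101"][0]  # offspring-only
        E, n = expected_homozygotes(other, pop)
        assert (E, n) == (0.0, 0)

    def test_matches_poisson_binomial_mean(self):
        """E equals the exact Poisson-binomial mean; and for observed 0 the
        Binomial(n, E/n) tail bounds the Poisson-binomial tail from above
        (the aggregated test is conservative)."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            n_matings = rng.integers(2, 8)
            hs = rng.integers(1, 3, n_matings)
            hd = rng.integers(1, 3, n_matings)
            n_off = rng.integers(1, 6, n_matings)
            probs = np.repeat(hs * hd / 4.0, n_off)
            E = float(probs.sum())
            n = int(probs.size)
            p_binom, _ = binomial_deficit_test(0, n, E)
            p_pb = poisson_binomial_cdf(0, probs)
            assert E == pytest.approx(float(np.sum(n_off * hs * hd / 4.0)))
            assert p_binom >= p_pb - 1e-15


class TestBinomialDeficitTest:
    def test_closed_form_at_observed_zero(self):
        p, sig = binomial_deficit_test(0, 20, 5.0)
        assert p == 0.75**20
        assert sig  # 3.17e-3 < 0.005

    def test_full_lower_tail_is_one(self):
        p, sig = binomial_deficit_test(17, 17, 4.0)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_flag_iff_below_alpha(self):
        p19, sig19 = binomial_deficit_test(0, 19, 19 / 4)
        p18, sig18 = binomial_deficit_test(0, 18, 18 / 4)
        assert sig19 and p19 < 0.005
        assert not sig18 and p18 > 0.005

    def test_untestable_raises(self):
        with pytest.raises(ValueError, match="untestable"):
            binomial_deficit_test(0, 0, 0.0)

    @given(n=st.integers(1, 400), obs_frac=st.floats(0, 1), rate=st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_scipy_binomial_cdf(self, n, obs_frac, rate):
        obs = int(round(obs_frac * n))
        p, _ = binomial_deficit_test(obs, n, rate * n)
        assert p == pytest.approx(float(stats.binom.cdf(obs, n, rate)), rel=1e-9)


class TestHetProgenyFraction:
    def _family(self, offspring_haps):
        inds = [
            ("S", "L", None, None, "M", 0, ("11", "00")),
            ("D", "L", None, None, "F", 0, ("11", "00")),
        ]
        inds += [
            (f"O{i}", "L", "S", "D", "M", 1, h) for i, h in enumerate(offspring_haps)
        ]
        return build_population([10, 20], inds)

    def test_all_heterozygous_is_100(self):
        pop = self._family([("11", "00")] * 6)
        wins = enumerate_windows(pop.snp_map, [30], 1.0, chrom_lengths={"1": 30})
        haps, _ = extract_haplotypes(pop, wins[0])
        target = [h for h in haps if h.alleles == "11"][0]
        pct, n = het_progeny_fraction(target, pop)
        assert (pct, n) == (100.0, 6)

    def test_mendelian_mixture_is_50(self):
        pop = self._family(
            [("11", "00"), ("11", "00"), ("11", "11"), ("00", "00")]
        )
        wins = enumerate_windows(pop.snp_map, [30], 1.0, chrom_lengths={"1": 30})
        haps, _ = extract_haplotypes(pop, wins[0])
        target = [h for h in haps if h.alleles == "11"][0]
        pct, _ = het_progeny_fraction(target, pop)
        assert pct == pytest.approx(50.0)

    def test_no_cxc_progeny_raises(self):
        inds = [
            ("S", "L", None, None, "M", 0, ("11", "00")),
            ("D", "L", None, None, "F", 0, ("00", "00")),
            ("O", "L", "S", "D", "M", 1, ("11", "00")),
        ]
        pop = build_population([10, 20], inds)
        wins = enumerate_windows(pop.snp_map, [30], 1.0, chrom_lengths={"1": 30})
        haps, _ = extract_haplotypes(pop, wins[0])
        target = [h for h in haps if h.alleles == "11"][0]
        with pytest.raises(ValueError, match="carrier-by-carrier"):
            het_progeny_fraction(target, pop)


class TestScan:
    def test_empty_window_list_gives_empty_table(self, lethal_population):
        res = scan(lethal_population, windows=[])
        assert len(res) == 0
        assert "p_value" in res.columns

    def test_frequencies_within_window_sum_to_at_most_one(self, lethal_population):
        res = scan(
            lethal_population,
            window_sizes=[500_000],
            chrom_lengths={"1": 4_000_000},
        )
        sums = res.groupby(["chrom", "start"])["frequency"].sum()
        assert (sums <= 1.0 + 1e-12).all()

    def test_merge_loci_never_exceeds_window_count(self, lethal_population):
        res = scan(lethal_population, chrom_lengths={"1": 4_000_000})
        sig = res[res["significant"]]
        loci = merge_significant_loci(res)
        n_sig_windows = len(sig.drop_duplicates(["chrom", "start", "end"]))
        assert len(loci) <= n_sig_windows

    def test_reported_coordinates_are_one_based(self, lethal_population):
        res = scan(
            lethal_population,
            window_sizes=[500_000],
            chrom_lengths={"1": 4_000_000},
        )
        assert res["start"].min() == 1
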