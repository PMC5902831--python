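"""AFS binning, pooled heterozygosity, zHp scan and intolerant-variant sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from layervar.selection import (
    afs_histogram,
    fixed_intolerant,
    line_specific_high_freq,
    pooled_heterozygosity,
    sweep_overlap,
    zhp_scan,
)


class TestAfsHistogram:
    def test_edge_rule_enumeration(self):
        hist = afs_histogram(np.array([0.02, 0.04, 0.97, 1.0]))
        assert hist.counts[0] == 2
        assert hist.counts[19] == 2
        assert hist.counts[1:19].sum() == 0

    def test_exact_boundary_goes_to_upper_bin(self):
        hist = afs_histogram(np.array([0.05]))
        assert hist.counts[1] == 1

    def test_empty_class_flagged(self):
        hist = afs_histogram(np.array([]), "empty")
        assert hist.empty
        assert hist.counts.sum() == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition_property(self, afs):
        """Bins partition the class: counts sum to the class size and
        proportions to 1."""
        hist = afs_histogram(np.array(afs))
        assert hist.counts.sum() == len(afs)
        assert hist.proportions.sum() == pytest.approx(1.0)


class TestPooledHeterozygosity:
    def test_hand_example(self):
        # two SNPs with (major, minor) = (150, 50) and (140, 60)
        assert pooled_heterozygosity([150, 140], [50, 60]) == 0.39875

    def test_fixed_windows_are_zero(self):
        assert pooled_heterozygosity([100, 80], [0, 0]) == 0.0

    def test_balanced_counts_reach_maximum(self):
        assert pooled_heterozygosity([100, 50], [50, 100]) == 0.5

    @given(
        maj=st.lists(st.integers(0, 500), min_size=1, max_size=30),
        minr=st.lists(st.integers(0, 500), min_size=1, max_size=30),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_swap_invariance(self, maj, minr):
        n = min(len(maj), len(minr))
        maj, minr = np.array(maj[:n]), np.array(minr[:n])
        if maj.sum() + minr.sum() == 0:
            return
        hp = pooled_heterozygosity(maj, minr)
        assert 0.0 <= hp <= 0.5
        assert hp == pooled_heterozygosity(minr, maj)


def grid_catalog(n_windows=60, per_window=25, an=200, seed=0, sweep_at=None):
    """Variants on a 20-kb grid with controllable allele counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for w in range(n_windows):
        for v in range(per_window):
            if sweep_at is not None and w == sweep_at:
                ac = rng.integers(0, 2)  # near-fixed: almost no diversity
            else:
                ac = rng.integers(40, 160)
            rows.append(
                {
                    "chrom": "1",
                    "pos": w * 20_000 + 100 + v * 700,
                    "ac_W1": ac,
                    "an_W1": an,
                }
            )
    return pd.DataFrame(rows)


class TestZhpScan:
    def test_standardization_identity(self):
        df = grid_catalog()
        out = zhp_scan(df, "W1")
        z = out.loc[out["scored"], "zHp"]
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_constructed_sweep_is_minimum_and_flagged(self):
        df = grid_catalog(sweep_at=30)
        out = zhp_scan(df, "W1")
        lowest = out.loc[out["zHp"].idxmin()]
        assert lowest["start"] == 30 * 20_000
        assert bool(lowest["sweep_flag"])

    def test_underfilled_windows_unscored(self):
        df = grid_catalog(per_window=25)
        df = pd.concat(
            [df, pd.DataFrame([{"chrom": "2", "pos": 100, "ac_W1": 50, "an_W1": 200}])],
            ignore_index=True,
        )
        out = zhp_scan(df, "W1")
        chrom2 = out[out["chrom"] == "2"]
        assert not chrom2["scored"].any()
        assert np.isnan(chrom2["Hp"]).all()

    def test_identical_hp_errors(self):
        rows = []
        for w in range(3):
            for v in range(25):
                rows.append(
                    {"chrom": "1", "pos": w * 20_000 + v, "ac_W1": 100, "an_W1": 200}
                )
        with pytest.raises(ValueError, match="identical"):
            zhp_scan(pd.DataFrame(rows), "W1")

    def test_too_few_windows_errors(self):
        df = grid_catalog(n_windows=1)
        with pytest.raises(ValueError, match="at least 2"):
            zhp_scan(df, "W1")

    def test_pooled_mode_combines_lines(self, sim_catalog):
        pooled = zhp_scan(sim_catalog.variants, pooled_lines=sim_catalog.lines,
                          min_variants=10)
        assert (pooled["line"] == "+".join(sim_catalog.lines)).all()
        per_line = zhp_scan(sim_catalog.variants, sim_catalog.lines[0],
                            min_variants=10)
        # pooling three lines scores at least as many windows as one line
        assert pooled["scored"].sum() >= per_line["scored"].sum()
        with pytest.raises(ValueError, match="exactly one"):
            zhp_scan(sim_catalog.variants)

    def test_count_scaling_invariance(self):
        """Doubling every allele count leaves Hp and zHp unchanged."""
        df = grid_catalog()
        doubled = df.copy()
        doubled["ac_W1"] *= 2
        doubled["an_W1"] *= 2
        a = zhp_scan(df, "W1")
        b = zhp_scan(doubled, "W1")
        np.testing.assert_allclose(a["Hp"], b["Hp"])
        np.testing.assert_allclose(a["zHp"], b["zHp"])


def af_catalog(rows):
    defaults = dict(chrom="1", pos=100, deleterious_final=True, label="lof")
    out = []
    for i, (afs_by_line) in enumerate(rows):
        rec = dict(defaults, pos=100 + i * 1000)
        for line, af in afs_by_line.items():
            an = 200
            rec[f"ac_{line}"] = int(round(af * an))
            rec[f"an_{line}"] = an
        out.append(rec)
    return pd.DataFrame(out)


class TestIntolerantSets:
    LINES = ("WA", "WD", "W1")

    def test_fixed_in_all_lines(self):
        df = af_catalog([{"WA": 1.0, "WD": 1.0, "W1": 1.0}])
        out = fixed_intolerant(df, self.LINES)
        assert len(out) == 1
        assert bool(out["fixed"].iat[0])

    def test_nearly_fixed_single_line(self):
        df = af_catalog([{"WA": 0.95, "WD": 0.2, "W1": 0.1}])
        out = fixed_intolerant(df, self.LINES)
        assert len(out) == 1
        assert bool(out["nearfixed_WA"].iat[0])
        assert not bool(out["nearfixed_WD"].iat[0])
        assert not bool(out["fixed"].iat[0])

    def test_hand_enumerated_catalog(self):
        df = af_catalog(
            [
                {"WA": 1.0, "WD": 1.0, "W1": 1.0},   # fixed
                {"WA": 0.95, "WD": 0.2, "W1": 0.1},  # nearly fixed WA
                {"WA": 0.5, "WD": 0.5, "W1": 0.5},   # excluded
                {"WA": 0.91, "WD": 0.95, "W1": 0.2}, # nearly fixed WA+WD
            ]
        )
        out = fixed_intolerant(df, self.LINES)
        assert list(out["pos"]) == [100, 1100, 3100]

    def test_non_deleterious_excluded(self):
        df = af_catalog([{"WA": 1.0, "WD": 1.0, "W1": 1.0}])
        df["deleterious_final"] = False
        assert len(fixed_intolerant(df, self.LINES)) == 0

    def test_line_specific_rules(self):
        df = af_catalog(
            [
                {"WA": 0.8, "WD": 0.0, "W1": 0.0},   # specific to WA
                {"WA": 0.8, "WD": 0.01, "W1": 0.0},  # not absent elsewhere
                {"WA": 0.65, "WD": 0.0, "W1": 0.0},  # below threshold
            ]
        )
        sets = line_specific_high_freq(df, self.LINES)
        assert list(sets["WA"]["pos"]) == [100]
        assert len(sets["WD"]) == 0 and len(sets["W1"]) == 0

    def test_line_specific_sets_disjoint(self, sim_catalog):
        from layervar.catalog import classify_variants

        v = classify_variants(sim_catalog.variants)
        sets = line_specific_high_freq(v, sim_catalog.lines)
        keys = [
            set(zip(s["chrom"], s["pos"], s["ref"], s["alt"]))
            for s in sets.values()
        ]
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                assert not (keys[i] & keys[j])

    def test_truth_private_variants_recovered(self, sim_catalog):
        from layervar.catalog import classify_variants, per_line_af

        v = classify_variants(sim_catalog.variants)
        sets = line_specific_high_freq(v, sim_catalog.lines)
        for line in sim_catalog.lines:
            af = per_line_af(v, line)
            truth = (
                (v["truth_private_line"] == line)
                & (np.nan_to_num(af, nan=0.0) > 0.7)
            )
            got = set(zip(sets[line]["chrom"], sets[line]["pos"]))
            for chrom, pos in zip(v.loc[truth, "chrom"], v.loc[truth, "pos"]):
                assert (chrom, pos) in got


class TestSweepOverlap:
    def _sweeps(self):
        return pd.DataFrame(
            [
                {"line": "WA", "chrom": "1", "start": 20_000, "end": 40_000,
                 "sweep_flag": True},
                {"line": "WA", "chrom": "1", "start": 40_000, "end": 60_000,
                 "sweep_flag": False},
            ]
        )

    def test_variant_in_flagged_window_included(self):
        fixed = af_catalog([{"WA": 0.95, "WD": 0.0, "W1": 0.0}])
        fixed["pos"] = 20_010
        out = sweep_overlap(fixed, self._sweeps())
        assert len(out) == 1
        assert out["sweep_lines"].iat[0] == "WA"

    def test_variant_in_unflagged_window_excluded(self):
        fixed = af_catalog([{"WA": 0.95, "WD": 0.0, "W1": 0.0}])
        fixed["pos"] = 40_010
        assert len(sweep_overlap(fixed, self._sweeps())) == 0

    def test_low_af_variant_excluded(self):
        fixed = af_catalog([{"WA": 0.5, "WD": 0.0, "W1": 0.0}])
        fixed["pos"] = 20_010
        assert len(sweep_overlap(fixed, self._sweeps())) == 0
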