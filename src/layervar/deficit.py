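"""Missing-homozygosity scan over sliding haplotype windows.

A recessive lethal reveals itself on a SNP chip as a haplotype whose
homozygotes are rarer than Mendelian expectation.  For every mating in which
the sire carries ``h_s`` and the dam ``h_d`` copies of a haplotype, each
offspring is homozygous with probability ``(h_s/2)(h_d/2)``; summing over
matings with genotyped offspring gives the expected homozygote count ``E``
among ``n`` at-risk progeny, and a one-sided lower-tail exact binomial test
of the observed count against ``Binomial(n, E/n)`` flags a deficit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .population import MISSING_ALLELE, MatingTable, PhasedPopulation, build_mating_table

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "HaplotypeAllele",
    "DeficitTestResult",
    "qc_filter_panel",
    "enumerate_windows",
    "extract_haplotypes",
    "expected_homozygotes",
    "binomial_deficit_test",
    "het_progeny_fraction",
    "scan",
    "scan_by_line",
    "merge_significant_loci",
    "summarize_scan",
]

DEFAULT_WINDOW_SIZES = (250_000, 500_000, 1_000_000)


# ---------------------------------------------------------------------------
# chip QC
# ---------------------------------------------------------------------------


def qc_filter_panel(
    genotypes: np.ndarray,
    snp_map: pd.DataFrame,
    maf_min: float = 0.01,
    snp_callrate_min: float = 0.85,
    animal_callrate_min: float = 0.7,
    sex_chroms: Sequence[str] = ("Z", "W"),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Pre-phasing panel QC on a diploid genotype matrix.

    ``genotypes`` is (animals x SNPs) coded 0/1/2 with ``-1`` missing.
    Filters are applied in order: unmapped/sex-chromosome SNPs, then animal
    call rate, then SNP MAF and call rate (both strict "higher than"
    thresholds, so a SNP at exactly the threshold is removed).  No
    Hardy-Weinberg filter is applied: the deficit signal *is* an HWE
    deviation.

    Returns ``(filtered matrix, kept animal rows, kept SNP columns, report)``.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[1] != len(snp_map):
        raise ValueError("genotypes must be (n_animals, n_snps) matching snp_map")
    report: dict[str, int] = {
        "input_snps": genotypes.shape[1],
        "input_animals": genotypes.shape[0],
    }

    chrom = snp_map["chrom"].astype(object).to_numpy()
    mapped = np.array(
        [c is not None and str(c) not in ("", "0", "nan") for c in chrom]
    )
    autosomal = mapped & ~np.isin(chrom.astype(str), list(sex_chroms))
    report["removed_unmapped_or_sex_snps"] = int((~autosomal).sum())
    snp_keep = autosomal.copy()

    sub = genotypes[:, snp_keep]
    called = sub >= 0
    animal_cr = called.mean(axis=1) if sub.shape[1] else np.zeros(len(genotypes))
    animal_keep = animal_cr >= animal_callrate_min  # "lower than 0.7" discarded
    report["removed_animals_callrate"] = int((~animal_keep).sum())

    sub = genotypes[animal_keep][:, snp_keep]
    called = sub >= 0
    with np.errstate(invalid="ignore"):
        snp_cr = (
            called.mean(axis=0) if sub.shape[0] else np.zeros(sub.shape[1])
        )
        alt = np.where(sub > 0, sub, 0).sum(axis=0)
        an = 2 * called.sum(axis=0)
        af = np.divide(alt, an, out=np.zeros_like(alt, dtype=float), where=an > 0)
    maf = np.minimum(af, 1 - af)
    pass_maf = maf > maf_min
    pass_cr = snp_cr > snp_callrate_min
    report["removed_snps_maf"] = int((~pass_maf).sum())
    report["removed_snps_callrate"] = int((pass_maf & ~pass_cr).sum())
    keep_cols_local = pass_maf & pass_cr

    snp_cols = np.flatnonzero(snp_keep)[keep_cols_local]
    animal_rows = np.flatnonzero(animal_keep)
    report["output_snps"] = len(snp_cols)
    report["output_animals"] = len(animal_rows)
    if len(snp_cols) == 0 or len(animal_rows) == 0:
        raise ValueError(f"no data survive panel QC; stage counts: {report}")
    return genotypes[np.ix_(animal_rows, snp_cols)], animal_rows, snp_cols, report


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    snp_indices: np.ndarray = field(compare=False, repr=False)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must precede end")
        if len(self.snp_indices) < 2:
            raise ValueError("a window requires at least 2 SNPs")

    @property
    def size(self) -> int:
        return self.end - self.start


def enumerate_windows(
    snp_map: pd.DataFrame,
    window_sizes: Iterable[int] = DEFAULT_WINDOW_SIZES,
    step_factor: float = 0.5,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[Window]:
    """Overlapping sliding windows per chromosome and window size.

    Windows start at multiples of ``step_factor * size`` with
    ``start + size <= chrom_end``; a final window anchored at
    ``chrom_end - size`` is added when not already on the grid.  A
    chromosome shorter than the window size yields a single whole-chromosome
    window.  Windows with fewer than 2 SNPs are dropped.
    """
    chrom_col = snp_map["chrom"].to_numpy()
    bp = snp_map["bp"].to_numpy()
    order_check = pd.DataFrame({"chrom": chrom_col, "bp": bp})
    for _, grp in order_check.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["bp"].to_numpy()) > 0):
            raise ValueError("snp_map must be sorted by (chrom, bp) without ties")

    windows: list[Window] = []
    for chrom in pd.unique(chrom_col):
        idx = np.flatnonzero(chrom_col == chrom)
        pos = bp[idx]
        chrom_end = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(pos[-1]) + 1
        )
        for size in window_sizes:
            step = max(int(round(step_factor * size)), 1)
            if chrom_end < size:
                starts = [0]
                ends = [chrom_end]
            else:
                starts = list(range(0, chrom_end - size + 1, step))
                final = chrom_end - size
                if final not in starts:
                    starts.append(final)
                ends = [s + size for s in starts]
            for start, end in zip(starts, ends):
                lo = np.searchsorted(pos, start, side="left")
                hi = np.searchsorted(pos, end, side="left")
                if hi - lo < 2:
                    continue
                windows.append(
                    Window(chrom=str(chrom), start=start, end=end,
                           snp_indices=idx[lo:hi])
                )
    return windows


# ---------------------------------------------------------------------------
# haplotype extraction
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeAllele:
    """One distinct allele string within a window.

    ``copies`` holds per-individual copy counts (0/1/2, ``-1`` for
    individuals excluded for missing alleles or not genotyped) over all rows
    of the source population.
    """

    window: Window
    alleles: str
    frequency: float
    copies: np.ndarray = field(repr=False)

    @property
    def carrier_ids(self) -> np.ndarray:
        return np.flatnonzero(self.copies >= 1)

    @property
    def homozygote_ids(self) -> np.ndarray:
        return np.flatnonzero(self.copies == 2)


def extract_haplotypes(
    population: PhasedPopulation,
    window: Window,
    freq_min: float = 0.005,
) -> tuple[list[HaplotypeAllele], int]:
    """Distinct window haplotypes with frequency strictly above ``freq_min``.

    Individuals with any missing allele inside the window are excluded from
    that window's counts (and get copy count ``-1``).  Returns the retained
    haplotypes sorted by decreasing frequency plus the retained-haplotype
    count.
    """
    sub = population.haplotypes[:, :, window.snp_indices]
    genotyped = population.individuals["genotyped"].to_numpy(dtype=bool)
    complete = ~(sub == MISSING_ALLELE).any(axis=2).any(axis=1)
    use = genotyped & complete
    n_excluded = int((genotyped & ~complete).sum())
    if n_excluded:
        logger.info(
            "window %s:%d-%d: excluded %d individuals with missing alleles",
            window.chrom, window.start, window.end, n_excluded,
        )
    rows = np.flatnonzero(use)
    if rows.size == 0:
        return [], 0
    flat = sub[rows].reshape(-1, sub.shape[2])
    uniq, inverse, counts = np.unique(
        flat, axis=0, return_inverse=True, return_counts=True
    )
    inverse = inverse.reshape(-1, 2)
    denom = 2 * rows.size
    freqs = counts / denom

    retained = np.flatnonzero(freqs > freq_min)
    retained = retained[np.argsort(-freqs[retained], kind="stable")]
    out = []
    for h in retained:
        copies = np.full(population.n_individuals, -1, dtype=np.int8)
        copies[rows] = (inverse == h).sum(axis=1)
        out.append(
            HaplotypeAllele(
                window=window,
                alleles="".join(map(str, uniq[h])),
                frequency=float(freqs[h]),
                copies=copies,
            )
        )
    return out, len(out)


# ---------------------------------------------------------------------------
# expectation and test
# ---------------------------------------------------------------------------


def expected_homozygotes(
    haplotype: HaplotypeAllele,
    population: PhasedPopulation,
    matings: Optional[MatingTable] = None,
) -> tuple[float, int]:
    """Expected homozygotes ``E`` and the number of at-risk progeny.

    For each mating with ``h_s`` and ``h_d`` parental copies, each genotyped
    offspring is homozygous with ``p = (h_s/2)(h_d/2)``; ``E`` sums
    ``n_offspring * p`` and at-risk progeny sum ``n_offspring`` over matings
    with ``p > 0``.  Matings whose parents are excluded from the window
    (missing alleles or ungenotyped) are skipped.
    """
    if matings is None:
        matings = build_mating_table(population)
    cs = haplotype.copies[matings.sire_idx].astype(float)
    cd = haplotype.copies[matings.dam_idx].astype(float)
    valid = (cs >= 0) & (cd >= 0)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("expected_homozygotes: skipped %d matings with excluded parents",
                     n_skipped)
    p = np.where(valid, cs * cd / 4.0, 0.0)
    at_risk = valid & (p > 0)
    E = float(np.sum(matings.n_offspring * p))
    n_at_risk = int(np.sum(matings.n_offspring[at_risk]))
    return E, n_at_risk


def observed_homozygotes(
    haplotype: HaplotypeAllele,
    matings: MatingTable,
) -> int:
    """Observed homozygote count among at-risk progeny."""
    cs = haplotype.copies[matings.sire_idx]
    cd = haplotype.copies[matings.dam_idx]
    at_risk = (cs > 0) & (cd > 0)
    total = 0
    for m in np.flatnonzero(at_risk):
        off = matings.offspring_of(m)
        total += int((haplotype.copies[off] == 2).sum())
    return total


def binomial_deficit_test(
    observed: int,
    n_at_risk: int,
    expected: float,
    alpha: float = 0.005,
) -> tuple[float, bool]:
    """One-sided lower-tail exact binomial test of a homozygote deficit.

    ``P(X <= observed)`` with ``X ~ Binomial(n_at_risk, expected/n_at_risk)``;
    the haplotype is flagged when ``p < alpha``.  ``observed == 0`` uses the
    closed form ``(1 - E/n)^n``.  Raises on ``n_at_risk == 0`` (untestable).
    """
    if n_at_risk < 1:
        raise ValueError("n_at_risk must be >= 1; the haplotype is untestable")
    if not 0 <= expected <= n_at_risk:
        raise ValueError("expected must lie in [0, n_at_risk]")
    if observed < 0 or observed > n_at_risk:
        raise ValueError("observed must lie in [0, n_at_risk]")
    rate = expected / n_at_risk
    if observed == 0:
        p = (1.0 - rate) ** n_at_risk
    else:
        p = float(stats.binom.cdf(observed, n_at_risk, rate))
    return p, p < alpha


def het_progeny_fraction(
    haplotype: HaplotypeAllele,
    population: PhasedPopulation,
    matings: Optional[MatingTable] = None,
) -> tuple[float, int]:
    """Percent heterozygous progeny of carrier-by-carrier matings.

    Under Mendelian segregation this is 50%; when homozygotes die before
    genotyping the surviving progeny are 2:1 het : non-carrier, i.e. ~66.7%.
    Returns ``(percent, n_progeny)``; raises when no C x C progeny exist.
    """
    if matings is None:
        matings = build_mating_table(population)
    cs = haplotype.copies[matings.sire_idx]
    cd = haplotype.copies[matings.dam_idx]
    cxc = (cs > 0) & (cd > 0)
    n_het = 0
    n_tot = 0
    for m in np.flatnonzero(cxc):
        off = matings.offspring_of(m)
        c = haplotype.copies[off]
        c = c[c >= 0]
        n_tot += c.size
        n_het += int((c == 1).sum())
    if n_tot == 0:
        raise ValueError("no genotyped progeny from carrier-by-carrier matings")
    return 100.0 * n_het / n_tot, n_tot


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------


@dataclass
class DeficitTestResult:
    """One haplotype x window row of the scan output."""

    chrom: str
    start: int
    end: int
    window_size: int
    n_snps: int
    haplotype: str
    frequency: float
    expected_hom: float
    observed_hom: int
    n_at_risk_progeny: int
    p_value: float
    significant: bool
    pct_het_carrier_progeny: float
    n_carrier_matings_genotyped: int
    n_carrier_matings_pedigree: int
    n_carrier_progeny: int
    n_haplotypes_in_window: int


def scan(
    population: PhasedPopulation,
    windows: Optional[Sequence[Window]] = None,
    window_sizes: Iterable[int] = DEFAULT_WINDOW_SIZES,
    step_factor: float = 0.5,
    freq_min: float = 0.005,
    alpha: float = 0.005,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Scan all windows for haplotypes with a homozygote deficit.

    Returns one row per retained haplotype per window (columns of
    :class:`DeficitTestResult`); untestable haplotypes (no at-risk progeny)
    carry ``p_value = NaN``.  Reported coordinates are 1-based inclusive.
    """
    if windows is None:
        windows = enumerate_windows(
            population.snp_map, window_sizes, step_factor, chrom_lengths
        )
    matings = build_mating_table(population)
    rows = []
    for window in windows:
        haplotypes, n_haps = extract_haplotypes(population, window, freq_min)
        for hap in haplotypes:
            E, n_at_risk = expected_homozygotes(hap, population, matings)
            cs = hap.copies[matings.sire_idx]
            cd = hap.copies[matings.dam_idx]
            cxc = (cs > 0) & (cd > 0)
            n_matings_gt = int((cxc & (matings.n_offspring > 0)).sum())
            n_matings_ped = int(cxc.sum())
            n_carrier_progeny = int(matings.n_offspring[cxc].sum())
            obs = observed_homozygotes(hap, matings)
            if n_at_risk >= 1:
                p, sig = binomial_deficit_test(obs, n_at_risk, E, alpha)
            else:
                p, sig = np.nan, False
            try:
                pct_het, _ = het_progeny_fraction(hap, population, matings)
            except ValueError:
                pct_het = np.nan
            rows.append(
                DeficitTestResult(
                    chrom=window.chrom,
                    start=window.start + 1,
                    end=window.end,
                    window_size=window.size,
                    n_snps=len(window.snp_indices),
                    haplotype=hap.alleles,
                    frequency=hap.frequency,
                    expected_hom=E,
                    observed_hom=obs,
                    n_at_risk_progeny=n_at_risk,
                    p_value=p,
                    significant=bool(sig),
                    pct_het_carrier_progeny=pct_het,
                    n_carrier_matings_genotyped=n_matings_gt,
                    n_carrier_matings_pedigree=n_matings_ped,
                    n_carrier_progeny=n_carrier_progeny,
                    n_haplotypes_in_window=n_haps,
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=[f.name for f in DeficitTestResult.__dataclass_fields__.values()]
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def merge_significant_loci(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping significant windows into unique loci.

    Significant haplotypes whose windows overlap on the same chromosome count
    as one locus; the number of loci can therefore never exceed the number of
    significant windows.
    """
    sig = results[results["significant"] == True]  # noqa: E712
    loci = []
    for chrom, grp in sig.groupby("chrom"):
        intervals = sorted(
            {(int(s), int(e)) for s, e in zip(grp["start"], grp["end"])}
        )
        cur_s, cur_e = None, None
        for s, e in intervals:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # 1-based inclusive: touching = overlapping
                cur_e = max(cur_e, e)
            else:
                loci.append({"chrom": chrom, "start": cur_s, "end": cur_e})
                cur_s, cur_e = s, e
        if cur_s is not None:
            loci.append({"chrom": chrom, "start": cur_s, "end": cur_e})
    return pd.DataFrame(loci, columns=["chrom", "start", "end"])


def summarize_scan(results: pd.DataFrame, population: PhasedPopulation) -> dict:
    """Per-population summary of the significant haplotypes (table-style).

    Averages are taken over significant haplotype x window rows; the locus
    count merges overlapping significant windows.
    """
    matings = build_mating_table(population)
    sig = results[results["significant"] == True]  # noqa: E712
    loci = merge_significant_loci(results)
    summary = {
        "samples": int(population.individuals["genotyped"].sum()),
        "trios": int(matings.n_offspring.sum()),
        "n_haplotypes": int(len(sig)),
        "n_loci": int(len(loci)),
        "avg_haplotype_length_snps": float(sig["n_snps"].mean()) if len(sig) else np.nan,
        "avg_haplotypes_per_window": float(
            results.drop_duplicates(["chrom", "start", "end"])[
                "n_haplotypes_in_window"
            ].mean()
        )
        if len(results)
        else np.nan,
        "avg_haplotype_frequency": float(sig["frequency"].mean()) if len(sig) else np.nan,
        "avg_expected_hom": float(sig["expected_hom"].mean()) if len(sig) else np.nan,
        "avg_carrier_matings_genotyped": float(
            sig["n_carrier_matings_genotyped"].mean()
        )
        if len(sig)
        else np.nan,
        "avg_carrier_matings_pedigree": float(
            sig["n_carrier_matings_pedigree"].mean()
        )
        if len(sig)
        else np.nan,
        "avg_carrier_progeny": float(sig["n_carrier_progeny"].mean()) if len(sig) else np.nan,
        "pct_het_carrier_progeny": float(
            sig["pct_het_carrier_progeny"].mean()
        )
        if len(sig)
        else np.nan,
    }
    return summary


def scan_by_line(
    population: PhasedPopulation,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`scan` within each line; returns (results, line summary)."""
    frames = []
    summaries = []
    for line in pd.unique(population.individuals["line"]):
        sub = population.line_subset(line)
        res = scan(sub, **kwargs)
        res.insert(0, "line", line)
        frames.append(res)
        summary = summarize_scan(res, sub)
        summary["line"] = line
        summaries.append(summary)
    results = pd.concat(frames, ignore_index=True)
    return results, pd.DataFrame(summaries).set_index("line")
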