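"""Synthetic pedigreed populations, variant catalogues and hatchability records.

The generator emulates the data a layer-breeding program produces: a
multi-generation pedigree genotyped on a medium-density SNP chip with an
embedded recessive lethal haplotype, a whole-genome-sequencing variant
catalogue with class-dependent allele-frequency spectra, a linkage map, and
per-mating hatchability records.

The lethal is modelled as a point mutation at the midpoint SNP of the
configured window, carried by "tagged" founder chromosomes.  Any conceptus
(or founder draw) homozygous for the tag dies before genotyping with
probability ``penetrance``, which is exactly the "missing homozygosity"
signature the chip-level scan looks for.  Because the scan works on
allele-string identity, untagged chromosomes that are identical by state over
the window legitimately count as carriers of the same haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import LOF_CLASSES, SimulationConfig
from .population import PhasedPopulation, build_mating_table

__all__ = [
    "VariantCatalog",
    "simulate_population",
    "simulate_genetic_map",
    "simulate_variant_catalog",
    "simulate_hatchability",
    "draw_founder_tags",
]

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Classes whose simulated variants sit in coding sequence.
_CODING_CLASSES = (
    "synonymous",
    "missense_tolerated",
    "missense_deleterious",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "inframe_insertion",
    "inframe_deletion",
    "splice_acceptor",
    "splice_donor",
)

#: truth classes eligible to be embryonic-lethal truth variants
_EL_ELIGIBLE = (
    "frameshift",
    "stop_gained",
    "splice_acceptor",
    "splice_donor",
    "inframe_insertion",
    "inframe_deletion",
    "missense_deleterious",
)


# ---------------------------------------------------------------------------
# genome layout helpers
# ---------------------------------------------------------------------------


class _Genome:
    """Chromosome bookkeeping shared by the meiosis sampler."""

    def __init__(self, config: SimulationConfig, snp_map: pd.DataFrame):
        self.chroms = list(config.chrom_lengths)
        self.lengths = np.array([config.chrom_lengths[c] for c in self.chroms], float)
        self.morgans = self.lengths / 1e6 * config.genetic_map_rate / 100.0
        chrom_arr = snp_map["chrom"].to_numpy()
        self.bounds = []
        for c in self.chroms:
            idx = np.flatnonzero(chrom_arr == c)
            lo = idx[0] if idx.size else 0
            hi = idx[-1] + 1 if idx.size else 0
            self.bounds.append((lo, hi))
        self.bp = snp_map["bp"].to_numpy()


def _make_snp_map(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], float)
    weights = lengths / lengths.sum()
    counts = np.floor(weights * config.n_snps).astype(int)
    counts[: config.n_snps - counts.sum()] += 1  # largest-chromosome top-up
    rows = []
    for chrom, length, n in zip(chroms, lengths, counts):
        if n == 0:
            continue
        pos = np.unique(rng.integers(0, int(length), int(n)))
        while pos.size < n:  # replace collisions, rare at chip density
            extra = rng.integers(0, int(length), int(n) - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        rows.append(pd.DataFrame({"chrom": chrom, "bp": np.sort(pos)}))
    snp_map = pd.concat(rows, ignore_index=True)
    snp_map["marker"] = [f"snp{i:06d}" for i in range(len(snp_map))]
    return snp_map[["marker", "chrom", "bp"]]


def draw_founder_tags(
    rng: np.random.Generator, n_chromosomes: int, freq: float
) -> np.ndarray:
    """One Bernoulli(``freq``) lethal tag per founder chromosome."""
    return rng.random(n_chromosomes) < freq


def _gamete(
    hap: np.ndarray,
    tags: np.ndarray,
    genome: _Genome,
    rng: np.random.Generator,
    locus: Optional[tuple[int, float]],
) -> tuple[np.ndarray, bool]:
    """One recombinant gamete from a parent's two chromosomes.

    Crossover counts are Poisson with mean equal to the chromosome map length
    in Morgans and positions are uniform in bp (Haldane, no interference,
    constant cM/Mb).  ``locus`` = (chromosome index, bp) of the lethal
    mutation; the returned tag follows the source chromosome at that point.
    """
    gam = np.empty(hap.shape[1], dtype=np.uint8)
    tag = False
    for ci, ((lo, hi), morgans) in enumerate(zip(genome.bounds, genome.morgans)):
        if hi <= lo and (locus is None or locus[0] != ci):
            continue
        k = rng.poisson(morgans)
        s = int(rng.integers(2))
        if k == 0:
            gam[lo:hi] = hap[s, lo:hi]
            if locus is not None and locus[0] == ci:
                tag = bool(tags[s])
        else:
            cuts = np.sort(rng.uniform(0.0, genome.lengths[ci], k))
            seg = np.searchsorted(cuts, genome.bp[lo:hi])
            src = (s + seg) % 2
            idx = np.arange(lo, hi)
            gam[lo:hi] = hap[src, idx]
            if locus is not None and locus[0] == ci:
                s_at = (s + int(np.searchsorted(cuts, locus[1]))) % 2
                tag = bool(tags[s_at])
    return gam, tag


def _apply_switch_errors(
    haps: np.ndarray, rng: np.random.Generator, rate: float
) -> np.ndarray:
    """Inject phase switch errors at heterozygous sites (off by default)."""
    if rate <= 0:
        return haps
    out = haps.copy()
    het = out[0] != out[1]
    switches = het & (rng.random(out.shape[1]) < rate)
    flip = np.cumsum(switches) % 2 == 1
    out[0, flip], out[1, flip] = haps[1, flip], haps[0, flip]
    return out


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def simulate_population(config: SimulationConfig) -> PhasedPopulation:
    """Simulate a multi-line pedigreed population with truth phase.

    Founder haplotypes are drawn site-wise from per-SNP allele frequencies;
    meioses follow the Haldane model on the configured cM/Mb map.  If
    ``config.lethal_window`` is set, founder chromosomes of the lethal line
    are tagged with probability ``lethal_target_freq``, tagged chromosomes
    share one window allele string, and tag homozygotes are removed before
    genotyping with probability ``penetrance``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    # separate stream so enabling the hook does not perturb the meioses
    switch_rng = np.random.default_rng([config.seed, 3])
    snp_map = _make_snp_map(rng, config)
    genome = _Genome(config, snp_map)
    lo_af, hi_af = config.founder_af_range
    founder_af = rng.uniform(lo_af, hi_af, len(snp_map))

    lethal_idx = None
    lethal_string = None
    locus = None
    lethal_line = None
    if config.lethal_window is not None:
        chrom, start, end = config.lethal_window
        mask = (
            (snp_map["chrom"].to_numpy() == chrom)
            & (snp_map["bp"].to_numpy() >= start)
            & (snp_map["bp"].to_numpy() < end)
        )
        lethal_idx = np.flatnonzero(mask)
        if lethal_idx.size < 2:
            raise ValueError(
                f"lethal_window {config.lethal_window} contains "
                f"{lethal_idx.size} SNPs; at least 2 are required"
            )
        if 2 * config.n_founders_per_line * config.lethal_target_freq < 1.0:
            raise ValueError(
                "lethal_target_freq unreachable: expected tagged founder "
                "chromosomes < 1 at the configured n_founders_per_line"
            )
        # the lethal arises on one founder background; keep its window string
        # distinctive (low identical-by-state frequency among untagged
        # chromosomes), the case the missing-homozygosity method can detect
        af_win = founder_af[lethal_idx]
        cap = config.lethal_max_ibs_fraction * config.lethal_target_freq
        best_string, best_prob = None, np.inf
        for _ in range(10_000):
            cand = (rng.random(lethal_idx.size) < af_win).astype(np.uint8)
            prob = float(np.prod(np.where(cand == 1, af_win, 1.0 - af_win)))
            if prob < best_prob:
                best_string, best_prob = cand, prob
            if prob <= cap:
                break
        lethal_string = best_string
        mid = lethal_idx[lethal_idx.size // 2]
        ci = genome.chroms.index(chrom)
        locus = (ci, float(snp_map["bp"].iloc[mid]))
        lethal_line = config.lethal_line or config.lines[0]

    hap_list: list[np.ndarray] = []
    tag_list: list[np.ndarray] = []
    records: list[dict] = []

    def _add(line, gen, sire_idx, dam_idx, sex, haps, tags):
        row = len(records)
        records.append(
            {
                "id": f"{line}_G{gen}_{row}",
                "line": line,
                "sire_idx": sire_idx,
                "dam_idx": dam_idx,
                "sex": sex,
                "generation": gen,
                "genotyped": True,
            }
        )
        hap_list.append(haps)
        tag_list.append(tags)
        return row

    # --- founders -----------------------------------------------------------
    prev_rows: dict[str, list[int]] = {}
    for line in config.lines:
        rows: list[int] = []
        while len(rows) < config.n_founders_per_line:
            haps = (rng.random((2, len(snp_map))) < founder_af).astype(np.uint8)
            tags = np.zeros(2, dtype=bool)
            if lethal_idx is not None and line == lethal_line:
                tags = draw_founder_tags(rng, 2, config.lethal_target_freq)
                haps[:, lethal_idx] = np.where(
                    tags[:, None], lethal_string[None, :], haps[:, lethal_idx]
                )
                if tags.all() and rng.random() < config.penetrance:
                    continue  # tag homozygote dies before genotyping
            sex = "M" if rng.integers(2) == 0 else "F"
            rows.append(_add(line, 0, -1, -1, sex, haps, tags))
        prev_rows[line] = rows

    # --- later generations --------------------------------------------------
    for gen in range(1, config.n_generations):
        new_rows: dict[str, list[int]] = {}
        for line in config.lines:
            parents = prev_rows[line]
            sexes = np.array([records[r]["sex"] for r in parents])
            males = np.array(parents)[sexes == "M"]
            females = np.array(parents)[sexes == "F"]
            if males.size == 0 or females.size == 0:
                raise ValueError(
                    f"line {line} has no breeding {'sires' if males.size == 0 else 'dams'} "
                    f"in generation {gen - 1}"
                )
            n_matings = config.n_matings_per_line or females.size
            if n_matings <= females.size:
                dams = rng.permutation(females)[:n_matings]
            else:
                dams = rng.choice(females, n_matings, replace=True)
            sires = rng.choice(males, n_matings, replace=True)
            rows = []
            for sire, dam in zip(sires, dams):
                born = 0
                attempts = 0
                max_attempts = 40 * config.offspring_per_mating + 100
                while born < config.offspring_per_mating and attempts < max_attempts:
                    attempts += 1
                    g1, t1 = _gamete(hap_list[sire], tag_list[sire], genome, rng, locus)
                    g2, t2 = _gamete(hap_list[dam], tag_list[dam], genome, rng, locus)
                    if t1 and t2 and rng.random() < config.penetrance:
                        continue  # lethal homozygote, dies before genotyping
                    haps = np.stack([g1, g2])
                    if config.switch_error_rate > 0:
                        haps = _apply_switch_errors(haps, switch_rng, config.switch_error_rate)
                    sex = "M" if rng.integers(2) == 0 else "F"
                    rows.append(
                        _add(line, gen, int(sire), int(dam), sex,
                             haps, np.array([t1, t2]))
                    )
                    born += 1
            new_rows[line] = rows
        prev_rows = new_rows

    individuals = pd.DataFrame(records)
    individuals["sire"] = [
        records[i]["id"] if i >= 0 else None for i in individuals["sire_idx"]
    ]
    individuals["dam"] = [
        records[i]["id"] if i >= 0 else None for i in individuals["dam_idx"]
    ]
    individuals = individuals[
        ["id", "line", "sire", "dam", "sex", "generation", "genotyped",
         "sire_idx", "dam_idx"]
    ]
    return PhasedPopulation(
        snp_map=snp_map.reset_index(drop=True),
        individuals=individuals,
        haplotypes=np.stack(hap_list),
        lethal_tags=np.stack(tag_list),
    )


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def simulate_genetic_map(config: SimulationConfig) -> pd.DataFrame:
    """Linkage map with log-normally varying local rate around the baseline.

    Markers sit every ``map_marker_spacing`` bp plus one terminal marker per
    chromosome; cumulative cM grow monotonically by construction.
    """
    rng = np.random.default_rng([config.seed, 7])
    sigma = config.map_rate_sigma
    mu = np.log(config.genetic_map_rate) - sigma**2 / 2.0
    rows = []
    for chrom, length in config.chrom_lengths.items():
        bp = np.arange(0, length, config.map_marker_spacing, dtype=int)
        if bp[-1] != length:
            bp = np.append(bp, length)
        rates = rng.lognormal(mu, sigma, bp.size - 1)
        cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(bp) / 1e6)])
        rows.append(
            pd.DataFrame(
                {
                    "marker": [f"map_{chrom}_{i}" for i in range(bp.size)],
                    "chrom": chrom,
                    "bp": bp,
                    "cm": cm,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _bin_rates(gmap: pd.DataFrame, chrom: np.ndarray, pos: np.ndarray,
               bin_bp: int = 750_000) -> np.ndarray:
    """cM/Mb of the fixed ``bin_bp`` bin containing each position."""
    rates = np.zeros(len(pos))
    for c in np.unique(chrom):
        sub = gmap[gmap["chrom"] == c]
        mask = chrom == c
        if sub.empty:
            continue
        lo = (pos[mask] // bin_bp) * bin_bp
        hi = lo + bin_bp
        cm_lo = np.interp(lo.astype(float), sub["bp"], sub["cm"])
        cm_hi = np.interp(hi.astype(float), sub["bp"], sub["cm"])
        rates[mask] = (cm_hi - cm_lo) / (bin_bp / 1e6)
    return rates


# ---------------------------------------------------------------------------
# variant catalogue simulation
# ---------------------------------------------------------------------------


@dataclass
class VariantCatalog:
    """A simulated (or loaded) population variant catalogue.

    ``variants`` carries one row per biallelic record with QC, annotation and
    per-line count columns (``ac_<line>``, ``an_<line>``, ``nhom_<line>``);
    ``genotypes`` holds alt-allele dosage per sample (``-1`` missing) aligned
    with ``samples``; ``depths`` the matching per-genotype read depths.
    """

    variants: pd.DataFrame
    lines: tuple[str, ...]
    samples: pd.DataFrame
    genotypes: Optional[np.ndarray] = None
    depths: Optional[np.ndarray] = None
    genes: Optional[pd.DataFrame] = None

    def count_columns(self) -> list[str]:
        return [f"ac_{line}" for line in self.lines]


def _class_af_params(config: SimulationConfig, truth_class: str) -> tuple[float, float]:
    params = config.variant_class_af_params
    if truth_class in params:
        return params[truth_class]
    if truth_class in LOF_CLASSES:
        return params["missense_deleterious"]
    return params["synonymous"]


def _draw_substitution(rng: np.random.Generator, n: int, ts_tv: float):
    ref = _BASES[rng.integers(0, 4, n)]
    p_ts = ts_tv / (ts_tv + 1.0)
    is_ts = rng.random(n) < p_ts
    alt = np.empty(n, dtype=object)
    for i in range(n):
        if is_ts[i]:
            alt[i] = _TRANSITION[ref[i]]
        else:
            choices = [b for b in "ACGT" if b != ref[i] and b != _TRANSITION[ref[i]]]
            alt[i] = choices[int(rng.integers(2))]
    return ref.astype(object), alt


def simulate_variant_catalog(
    config: SimulationConfig,
    population_sizes: dict[str, int],
    genetic_map: Optional[pd.DataFrame] = None,
) -> VariantCatalog:
    """Simulate an annotated WGS variant catalogue for the configured lines.

    Per-variant allele frequencies are Beta draws per functional class;
    genotypes are Hardy-Weinberg binomial samples per line, except EL-truth
    variants whose hom-alt draws are resampled to het/ref.  Deleterious
    missense variants are placed preferentially in low-recombination regions
    when ``purging_gradient_slope`` is negative.
    """
    config.validate()
    for line in population_sizes:
        if line not in config.lines:
            raise ValueError(f"unknown line {line!r} in population_sizes")
    rng = np.random.default_rng([config.seed, 11])
    if genetic_map is None:
        genetic_map = simulate_genetic_map(config)

    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], float)
    weights = lengths / lengths.sum()

    # --- genes --------------------------------------------------------------
    n_genes = config.n_genes
    gene_chrom_i = rng.choice(len(chroms), n_genes, p=weights)
    gene_chrom = np.array(chroms, dtype=object)[gene_chrom_i]
    gene_pos = (rng.random(n_genes) * lengths[gene_chrom_i]).astype(int)
    genes = pd.DataFrame(
        {
            "gene_id": [f"GENE{g:05d}" for g in range(n_genes)],
            "chrom": gene_chrom,
            "pos": gene_pos,
            "aa_len": np.clip(
                rng.lognormal(5.7, 0.6, n_genes).astype(int), 50, 5000
            ),
            "lethal_flag": rng.random(n_genes) < config.lethal_gene_fraction,
            "ortho11": rng.random(n_genes) < 0.8,
            "rnacov": rng.lognormal(np.log(500.0), 1.0, n_genes).astype(int),
        }
    )
    # the gradient is defined per ~750-kb genomic bin, so each gene takes the
    # recombination rate of the bin that contains it
    gene_rate = _bin_rates(genetic_map, gene_chrom, gene_pos, bin_bp=750_000)

    # deleterious-missense placement weights implementing the purging gradient
    n_del = config.variant_counts.get("missense_deleterious", 0)
    n_neutral = config.variant_counts.get("synonymous", 0) + config.variant_counts.get(
        "missense_tolerated", 0
    )
    slope = config.purging_gradient_slope
    if n_neutral > 0 and n_del > 0:
        base_ratio = n_del / n_neutral
        target = base_ratio + slope * (gene_rate - gene_rate.mean())
        if target.min() < 0:
            raise ValueError(
                "purging_gradient_slope magnitude exceeds the achievable "
                "deleterious/tolerated ratio range (negative target ratio)"
            )
        del_weights = target / target.sum()
    else:
        del_weights = np.full(n_genes, 1.0 / n_genes)

    # --- per-class variant records -----------------------------------------
    frames = []
    for truth_class, n in config.variant_counts.items():
        if n <= 0:
            continue
        rec: dict[str, object] = {"truth_class": truth_class}
        if truth_class in _CODING_CLASSES:
            if truth_class == "missense_deleterious":
                g = rng.choice(n_genes, n, p=del_weights)
            else:
                g = rng.choice(n_genes, n)
            rec["gene_id"] = genes["gene_id"].to_numpy()[g]
            rec["chrom"] = genes["chrom"].to_numpy()[g]
            rec["pos"] = genes["pos"].to_numpy()[g] + rng.integers(1, 5000, n)
            rec["aa_len"] = genes["aa_len"].to_numpy()[g].astype(float)
            rec["ortho11"] = genes["ortho11"].to_numpy()[g]
            rec["rnacov"] = genes["rnacov"].to_numpy()[g].astype(float)
        else:
            ci = rng.choice(len(chroms), n, p=weights)
            rec["gene_id"] = np.array([""] * n, dtype=object)
            rec["chrom"] = np.array(chroms, dtype=object)[ci]
            rec["pos"] = (rng.random(n) * lengths[ci]).astype(int) + 1
            rec["aa_len"] = np.full(n, np.nan)
            rec["ortho11"] = np.zeros(n, dtype=bool)
            rec["rnacov"] = np.zeros(n)
        frames.append(pd.DataFrame(rec))
    variants = pd.concat(frames, ignore_index=True)
    n_var = len(variants)
    truth = variants["truth_class"].to_numpy()

    # consequence as an annotation tool would report it
    consequence = truth.copy()
    consequence[np.isin(truth, ["missense_tolerated", "missense_deleterious"])] = (
        "missense"
    )
    variants["consequence"] = consequence

    # amino-acid positions; frameshift and stop-gained optionally inflated at
    # the protein termini
    aa_len = variants["aa_len"].to_numpy()
    aa_pos = np.full(n_var, np.nan)
    coding_aa = np.isin(
        truth,
        [
            "synonymous",
            "missense_tolerated",
            "missense_deleterious",
            "stop_gained",
            "stop_lost",
            "start_lost",
            "frameshift",
            "inframe_insertion",
            "inframe_deletion",
        ],
    )
    ok = coding_aa & np.isfinite(aa_len)
    aa_pos[ok] = rng.integers(1, aa_len[ok].astype(int) + 1)
    terminal = (
        np.isin(truth, ["frameshift", "stop_gained"])
        & ok
        & (rng.random(n_var) < config.terminal_inflation)
    )
    if terminal.any():
        L = aa_len[terminal].astype(int)
        first_bin = rng.random(terminal.sum()) < 0.5
        width = np.maximum(L // 10, 1)
        offset = (rng.random(terminal.sum()) * width).astype(int)
        aa_pos[terminal] = np.where(first_bin, 1 + offset, L - offset)
    variants["aa_pos"] = aa_pos

    # SIFT / PROVEAN scores consistent with the truth class
    sift = np.full(n_var, np.nan)
    m_del = truth == "missense_deleterious"
    m_tol = truth == "missense_tolerated"
    sift[m_del] = rng.uniform(0.0, 0.05, m_del.sum())
    sift[m_tol] = rng.uniform(0.0500001, 1.0, m_tol.sum())
    unscored = m_tol & (rng.random(n_var) < 0.02)
    sift[unscored] = np.nan
    variants["sift"] = sift

    provean = np.full(n_var, np.nan)
    damaging = m_del | np.isin(truth, list(LOF_CLASSES))
    provean[damaging] = rng.normal(-4.5, 1.8, damaging.sum())
    provean[m_tol] = rng.normal(-0.5, 1.5, m_tol.sum())
    variants["provean"] = provean

    # alleles and indel lengths
    is_indel = np.isin(
        truth, ["frameshift", "inframe_insertion", "inframe_deletion"]
    ) | ((truth == "other") & (rng.random(n_var) < 0.5))
    indel_len = np.zeros(n_var, dtype=int)
    fs = truth == "frameshift"
    non3 = np.array([L for L in range(1, 16) if L % 3 != 0])
    indel_len[fs] = rng.choice(non3, fs.sum()) * np.where(
        rng.random(fs.sum()) < 0.5, 1, -1
    )
    for cls, sign in (("inframe_insertion", 1), ("inframe_deletion", -1)):
        m = truth == cls
        short = rng.random(m.sum()) < config.coding_inframe_enrichment
        L = np.where(short, rng.choice([3, 6, 9], m.sum()), rng.choice([12, 15], m.sum()))
        indel_len[m] = sign * L
    m_nc = (truth == "other") & is_indel
    indel_len[m_nc] = rng.integers(1, 16, m_nc.sum()) * np.where(
        rng.random(m_nc.sum()) < 0.5, 1, -1
    )
    ref, alt = _draw_substitution(rng, n_var, config.ts_tv)
    for i in np.flatnonzero(is_indel):
        L = abs(int(indel_len[i]))
        seq = "".join(_BASES[rng.integers(0, 4, L)])
        if indel_len[i] > 0:
            alt[i] = str(ref[i]) + seq
        else:
            ref[i], alt[i] = str(ref[i]) + seq, str(ref[i])
    variants["ref"] = ref
    variants["alt"] = alt
    variants["is_indel"] = is_indel
    variants["indel_len"] = indel_len

    # site-level QC fields
    variants["qual"] = rng.gamma(4.0, 20.0, n_var)
    near = np.full(n_var, np.nan)
    snv = ~is_indel
    near[snv] = np.floor(rng.exponential(200.0, snv.sum()))
    variants["near_indel_bp"] = near

    # --- line-private and EL-truth labelling -------------------------------
    lines = tuple(population_sizes)
    private_line = np.array([""] * n_var, dtype=object)
    if len(lines) > 1 and config.line_private_fraction > 0:
        is_private = rng.random(n_var) < config.line_private_fraction
        private_line[is_private] = rng.choice(
            np.array(lines, dtype=object), is_private.sum()
        )
    variants["truth_private_line"] = private_line

    truth_el = np.zeros(n_var, dtype=bool)
    eligible = np.flatnonzero(np.isin(truth, _EL_ELIGIBLE))
    if config.n_el_truth > 0 and eligible.size:
        chosen = rng.choice(
            eligible, min(config.n_el_truth, eligible.size), replace=False
        )
        truth_el[chosen] = True
        # EL truth variants must survive the gene-level filters: reassign to a
        # flagged, orthologous, expressed gene
        good = genes[
            genes["lethal_flag"] & genes["ortho11"] & (genes["rnacov"] >= 200)
        ]
        if good.empty:
            raise ValueError(
                "no gene satisfies the EL gene-level filters; increase "
                "n_genes or lethal_gene_fraction"
            )
        gi = rng.choice(good.index.to_numpy(), chosen.size)
        for col_src, col_dst in (
            ("gene_id", "gene_id"),
            ("chrom", "chrom"),
            ("ortho11", "ortho11"),
        ):
            variants.loc[chosen, col_dst] = genes.loc[gi, col_src].to_numpy()
        variants.loc[chosen, "pos"] = genes.loc[gi, "pos"].to_numpy() + rng.integers(
            1, 5000, chosen.size
        )
        variants.loc[chosen, "rnacov"] = genes.loc[gi, "rnacov"].to_numpy().astype(float)
        variants.loc[chosen, "aa_len"] = genes.loc[gi, "aa_len"].to_numpy().astype(float)
        has_aa = np.isfinite(variants.loc[chosen, "aa_pos"].to_numpy())
        new_pos = np.minimum(
            variants.loc[chosen, "aa_pos"].to_numpy(),
            variants.loc[chosen, "aa_len"].to_numpy(),
        )
        variants.loc[chosen, "aa_pos"] = np.where(has_aa, new_pos, np.nan)
        # inframe EL indels are PROVEAN-deleterious by construction
        inframe_el = chosen[
            np.isin(truth[chosen], ["inframe_insertion", "inframe_deletion"])
        ]
        variants.loc[inframe_el, "provean"] = np.minimum(
            variants.loc[inframe_el, "provean"].to_numpy(), -3.0
        )
    variants["truth_el"] = truth_el

    # --- allele frequencies and genotypes ----------------------------------
    af = np.empty(n_var)
    for truth_class in np.unique(truth):
        m = truth == truth_class
        a, b = _class_af_params(config, str(truth_class))
        af[m] = rng.beta(a, b, m.sum())
    af = np.clip(af, 1e-4, 1.0 - 1e-4)
    variants["truth_af"] = af

    sample_names, sample_lines = [], []
    for line in lines:
        for i in range(population_sizes[line]):
            sample_names.append(f"{line}_s{i:03d}")
            sample_lines.append(line)
    samples = pd.DataFrame({"sample": sample_names, "line": sample_lines})
    n_samples = len(samples)
    line_of_sample = np.array(sample_lines, dtype=object)

    p_mat = np.repeat(af[:, None], n_samples, axis=1)
    for line in lines:
        others = line_of_sample != line
        mask = (private_line == line)[:, None] & others[None, :]
        p_mat[mask] = 0.0
    genotypes = rng.binomial(2, p_mat).astype(np.int8)

    # EL truth: reject hom-alt draws (resample to ref/het with HW weights)
    el_rows = np.flatnonzero(truth_el)
    for r in el_rows:
        hom = genotypes[r] == 2
        if hom.any():
            p = af[r]
            p_het = 2 * p * (1 - p) / ((1 - p) ** 2 + 2 * p * (1 - p))
            genotypes[r, hom] = rng.binomial(1, p_het, hom.sum()).astype(np.int8)

    # missingness and depths
    cr = np.clip(rng.beta(
        config.target_call_rate * 40, (1 - config.target_call_rate) * 40, n_var
    ), 0.3, 1.0)
    missing = rng.random((n_var, n_samples)) > cr[:, None]
    genotypes[missing] = -1
    mean_depth = rng.uniform(*config.mean_depth_range, n_samples)
    depths = rng.poisson(mean_depth[None, :], (n_var, n_samples)).astype(np.int16)
    depths[missing] = 0
    variants["call_rate"] = (genotypes >= 0).mean(axis=1)

    # per-line counts
    for line in lines:
        cols = line_of_sample == line
        g = genotypes[:, cols]
        called = g >= 0
        variants[f"an_{line}"] = 2 * called.sum(axis=1)
        variants[f"ac_{line}"] = np.where(g > 0, g, 0).sum(axis=1)
        variants[f"nhom_{line}"] = (g == 2).sum(axis=1)

    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    genotypes = genotypes[order]
    depths = depths[order]

    cols = [
        "chrom", "pos", "ref", "alt", "is_indel", "indel_len", "qual",
        "call_rate", "near_indel_bp", "consequence", "gene_id", "sift",
        "provean", "aa_pos", "aa_len", "ortho11", "rnacov",
        "truth_class", "truth_af", "truth_el", "truth_private_line",
    ] + [f"{p}_{line}" for line in lines for p in ("ac", "an", "nhom")]
    variants = variants[cols]
    return VariantCatalog(
        variants=variants,
        lines=lines,
        samples=samples,
        genotypes=genotypes,
        depths=depths,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# hatchability
# ---------------------------------------------------------------------------


def simulate_hatchability(
    population: PhasedPopulation,
    n_eggs_per_mating: int = 50,
    base_hatch: float = 0.9,
    penetrance: float = 1.0,
    seed: int = 0,
    carriers: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-mating egg counts with a hatch deficit in carrier-by-carrier matings.

    A quarter of C x C conceptuses are lethal homozygotes, so those matings
    hatch at ``base_hatch * (1 - penetrance / 4)``; every other mating hatches
    at ``base_hatch``.  ``carriers`` overrides the truth tags of the
    population (boolean per individual row).
    """
    if not 0.0 < base_hatch <= 1.0:
        raise ValueError("base_hatch must lie in (0, 1]")
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if carriers is None:
        if population.lethal_tags is None:
            carriers = np.zeros(population.n_individuals, dtype=bool)
        else:
            carriers = population.lethal_tags.any(axis=1)
    matings = build_mating_table(population)
    ids = population.individuals["id"].to_numpy()
    rows = []
    for m in range(matings.n_matings):
        s, d = matings.sire_idx[m], matings.dam_idx[m]
        n_carrier_parents = int(carriers[s]) + int(carriers[d])
        status = {2: "CxC", 1: "CxN", 0: "NxN"}[n_carrier_parents]
        rate = base_hatch * (1 - penetrance / 4.0) if status == "CxC" else base_hatch
        hatched = int(rng.binomial(n_eggs_per_mating, rate))
        rows.append(
            {
                "mating_id": f"M{m:05d}",
                "sire": ids[s],
                "dam": ids[d],
                "carrier_status": status,
                "eggs_set": n_eggs_per_mating,
                "hatched": hatched,
            }
        )
    return pd.DataFrame(rows)
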