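"""Configuration objects for the synthetic-data generator.

All randomness in the generator flows from ``SimulationConfig.seed`` through
:func:`numpy.random.default_rng`; an identical config (including the seed)
reproduces identical output arrays and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


#: Beta(a, b) allele-frequency parameters per functional class.  Deleterious
#: classes are skewed towards rare alleles (purifying selection keeps damaging
#: variants at low frequency); synonymous variants follow a symmetric U-shaped
#: spectrum typical of neutral segregating sites.
DEFAULT_CLASS_AF_PARAMS: dict[str, tuple[float, float]] = {
    "synonymous": (0.8, 0.8),
    "missense_tolerated": (0.5, 1.0),
    "missense_deleterious": (0.2, 2.0),
    "stop_gained": (0.15, 2.5),
}

#: Number of simulated variants per consequence class.  Proportions follow the
#: usual ordering of a coding catalogue (synonymous > tolerated missense >
#: deleterious missense > LoF classes) at a size that keeps per-bin counts
#: stable for the downstream spectra.
DEFAULT_VARIANT_COUNTS: dict[str, int] = {
    "synonymous": 4000,
    "missense_tolerated": 3000,
    "missense_deleterious": 800,
    "stop_gained": 150,
    "frameshift": 150,
    "inframe_insertion": 60,
    "inframe_deletion": 60,
    "splice_acceptor": 40,
    "splice_donor": 40,
    "stop_lost": 20,
    "start_lost": 20,
    "other": 2000,
}

#: Variant classes treated as potential loss of function.
LOF_CLASSES = frozenset(
    {
        "splice_acceptor",
        "splice_donor",
        "inframe_insertion",
        "inframe_deletion",
        "frameshift",
        "stop_lost",
        "stop_gained",
        "start_lost",
    }
)

#: Classes that alter the protein sequence (used for carrier-concordance
#: matching around deficit haplotypes).
PROTEIN_ALTERING_CLASSES = LOF_CLASSES | {"missense"}


def _default_chrom_lengths() -> dict[str, int]:
    # Five "macrochromosome-like" chromosomes; lengths scaled down from the
    # chicken genome but keeping 60K-chip marker density (~20 markers/Mb).
    return {
        "1": 10_000_000,
        "2": 8_000_000,
        "3": 6_000_000,
        "4": 5_000_000,
        "5": 4_000_000,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic pedigreed population and variant catalogue.

    Attributes
    ----------
    seed:
        Root seed; every stochastic stage derives its own stream from it.
    lines:
        Labels of the simulated breeding lines.
    n_founders_per_line:
        Founder animals per line (half sires, half dams on average).
    n_generations:
        Total generations including founders (``1`` = founders only).
    n_matings_per_line:
        Matings per line per generation; defaults to the number of dams.
    offspring_per_mating:
        Number of *genotyped surviving* offspring per mating.  Conceptuses
        homozygous for the lethal tag die before genotyping and are replaced,
        mirroring a hatchery that genotypes a planned number of hatched chicks.
    n_snps:
        Chip SNPs, distributed over chromosomes proportionally to length.
    chrom_lengths:
        Physical length in bp per chromosome label.
    genetic_map_rate:
        Baseline recombination rate in cM/Mb (chicken macrochromosomes
        average ~3 cM/Mb).
    map_rate_sigma:
        Log-normal spread of per-interval map rates around the baseline.
    map_marker_spacing:
        bp between genetic-map markers emitted by the map generator.
    founder_af_range:
        Uniform range of founder allele frequencies per SNP; chip SNPs are
        ascertained for intermediate frequency.
    lethal_window:
        ``(chrom, start_bp, end_bp)`` harbouring the recessive lethal, or
        ``None`` for a null population.
    lethal_line:
        Line segregating the lethal (default: first line).
    lethal_target_freq:
        Bernoulli tag probability per founder chromosome.
    lethal_max_ibs_fraction:
        Cap on the identical-by-state background frequency of the lethal
        window string, as a fraction of ``lethal_target_freq``.  A recessive
        lethal is only detectable by missing homozygosity when it segregates
        on a distinctive haplotype; lethals on common strings are the
        method's documented blind spot, so the generator embeds the
        detectable case.
    penetrance:
        Probability that a tag homozygote dies before genotyping.
    switch_error_rate:
        Per-heterozygous-site phase switch probability (phasing-error
        injection hook; ``0`` emits truth phase).
    variant_class_af_params:
        Beta(a, b) allele-frequency parameters per class; the four classes of
        :data:`DEFAULT_CLASS_AF_PARAMS` are required.
    variant_counts:
        Simulated variants per consequence class.
    n_genes:
        Genes in the synthetic annotation.
    lethal_gene_fraction:
        Fraction of genes flagged as early-lethal in null-mutant mice.
    n_el_truth:
        Variants constructed as true embryonic lethals (hom-alt genotypes
        resampled away, placed in flagged genes passing the gene filters).
    line_private_fraction:
        Fraction of variants private to a single line.
    purging_gradient_slope:
        Change of the expected deleterious/tolerated ratio per cM/Mb of local
        recombination rate (negative = purging is more effective where
        recombination is high).
    ts_tv:
        Target transition/transversion ratio of the substitution sampler.
    coding_inframe_enrichment:
        Probability that a coding in-frame-class indel length is drawn from
        {3, 6, 9} rather than uniformly.
    terminal_inflation:
        Probability mass moved into the terminal 10% protein-position bins for
        frameshift and stop-gained variants (0 = uniform positions).
    mean_depth_range:
        Uniform range of per-sample mean sequencing depth.
    target_call_rate:
        Mean genotype call rate of the simulated catalogue.
    """

    seed: int = 0
    lines: tuple[str, ...] = ("WA", "WD", "W1")
    n_founders_per_line: int = 120
    n_generations: int = 3
    n_matings_per_line: Optional[int] = None
    offspring_per_mating: int = 3
    n_snps: int = 600
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    genetic_map_rate: float = 3.0
    map_rate_sigma: float = 0.4
    map_marker_spacing: int = 250_000
    founder_af_range: tuple[float, float] = (0.1, 0.9)
    lethal_window: Optional[tuple[str, int, int]] = None
    lethal_line: Optional[str] = None
    lethal_target_freq: float = 0.05
    lethal_max_ibs_fraction: float = 0.02
    penetrance: float = 1.0
    switch_error_rate: float = 0.0
    variant_class_af_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_AF_PARAMS)
    )
    variant_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_COUNTS)
    )
    n_genes: int = 400
    lethal_gene_fraction: float = 0.25
    n_el_truth: int = 25
    line_private_fraction: float = 0.05
    purging_gradient_slope: float = 0.0
    ts_tv: float = 2.5
    coding_inframe_enrichment: float = 0.6
    terminal_inflation: float = 0.3
    mean_depth_range: tuple[float, float] = (8.0, 23.0)
    target_call_rate: float = 0.95

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_founders_per_line": self.n_founders_per_line,
            "n_generations": self.n_generations,
            "offspring_per_mating": self.offspring_per_mating,
            "n_snps": self.n_snps,
            "n_genes": self.n_genes,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if not self.lines:
            raise ValueError("at least one line label is required")
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("line labels must be unique")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if not 0.0 < self.lethal_target_freq < 1.0:
            raise ValueError("lethal_target_freq must lie in (0, 1)")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        lo, hi = self.founder_af_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("founder_af_range must satisfy 0 < lo <= hi < 1")
        missing = set(DEFAULT_CLASS_AF_PARAMS) - set(self.variant_class_af_params)
        if missing:
            raise ValueError(
                "variant_class_af_params must define at least "
                f"{sorted(DEFAULT_CLASS_AF_PARAMS)}; missing {sorted(missing)}"
            )
        for cls, (a, b) in self.variant_class_af_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {cls} must be positive")
        if self.lethal_window is not None:
            chrom, start, end = self.lethal_window
            if chrom not in self.chrom_lengths:
                raise ValueError(f"lethal_window chromosome {chrom!r} not in chrom_lengths")
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise ValueError("lethal_window must satisfy 0 <= start < end <= chrom length")
        if self.lethal_line is not None and self.lethal_line not in self.lines:
            raise ValueError(f"lethal_line {self.lethal_line!r} not among lines")
        if not 0.0 <= self.switch_error_rate < 1.0:
            raise ValueError("switch_error_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        data = dict(payload)
        if "lines" in data:
            data["lines"] = tuple(data["lines"])
        if data.get("lethal_window") is not None:
            data["lethal_window"] = tuple(data["lethal_window"])
        for key in ("founder_af_range", "mean_depth_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "variant_class_af_params" in data:
            data["variant_class_af_params"] = {
                k: tuple(v) for k, v in data["variant_class_af_params"].items()
            }
        return cls(**data)
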