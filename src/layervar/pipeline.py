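"""End-to-end orchestration of the analysis stages from one config.

Stages run in dependency order (``simulate`` feeds every downstream stage);
all thresholds default to the study's printed values, every random stream is
derived from one root seed, and a machine-readable manifest records inputs,
thresholds and per-stage outputs so any output is reproducible from the
manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import add_per_line_af, classify_variants, filter_sites, ts_tv
from .config import SimulationConfig
from .deficit import scan_by_line
from .io import (
    ensure_dir,
    write_catalog_tsv,
    write_genetic_map,
    write_pedigree,
    write_phased_vcf,
)
from .lethal import el_filter, hatchability_test
from .purging import bin_variant_classes, purging_correlation, recombination_bins
from .selection import afs_by_class, fixed_intolerant, zhp_scan
from .simulate import (
    simulate_genetic_map,
    simulate_hatchability,
    simulate_population,
    simulate_variant_catalog,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "scan", "catalog", "afs", "sweep", "recomb", "el")

_STAGE_DEPS = {
    "scan": ("simulate",),
    "catalog": ("simulate",),
    "afs": ("catalog",),
    "sweep": ("catalog",),
    "recomb": ("catalog",),
    "el": ("catalog",),
}


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, defaulting to the study's values."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = ALL_STAGES
    outdir: str = "layervar_out"
    seed: int = 0
    # haplotype scan
    window_sizes: tuple[int, ...] = (250_000, 500_000, 1_000_000)
    step_factor: float = 0.5
    freq_min: float = 0.005
    alpha: float = 0.005
    # catalogue QC
    qual_min: float = 20.0
    callrate_min: float = 0.7
    indel_exclusion_bp: int = 3
    depth_min: int = 4
    depth_max_factor: float = 2.5
    # classification
    sift_deleterious: float = 0.05
    sift_load: float = 0.01
    rnacov_min: float = 200.0
    # selection signatures
    af_fixed: float = 0.9
    af_line_specific: float = 0.7
    sweep_window_bp: int = 20_000
    sweep_min_variants: int = 20
    zhp_threshold: float = -2.7
    # purging
    recomb_bin_bp: int = 750_000
    recomb_chroms: tuple[str, ...] = ("1", "2", "3", "4", "5")
    # sequenced samples per line for the simulated catalogue
    samples_per_line: dict = field(
        default_factory=lambda: {"WA": 71, "WD": 78, "W1": 101}
    )

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            for dep in _STAGE_DEPS.get(stage, ()):
                if dep not in self.stages:
                    raise ValueError(
                        f"stage '{stage}' requires stage '{dep}' which is disabled"
                    )

    def to_yaml(self, path: str) -> None:
        payload = asdict(self)
        payload["simulation"] = self.simulation.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        data = dict(payload)
        if "simulation" in data:
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        for key in ("stages", "window_sizes", "recomb_chroms"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict."""
    outdir = ensure_dir(config.outdir)
    sim = config.simulation
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("simulation", "stages", "outdir", "samples_per_line")
        },
        "simulation": sim.to_dict(),
        "outputs": {},
    }
    population = catalog = None
    summary_lines = []

    def _out(stage: str, name: str, path: str):
        manifest["outputs"].setdefault(stage, {})[name] = path

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                population = simulate_population(sim)
                gmap = simulate_genetic_map(sim)
                write_phased_vcf(population, f"{outdir}/population.vcf")
                write_pedigree(population, f"{outdir}/pedigree.tsv")
                write_genetic_map(gmap, f"{outdir}/genetic_map.tsv")
                _out(stage, "phased_vcf", f"{outdir}/population.vcf")
                _out(stage, "pedigree", f"{outdir}/pedigree.tsv")
                _out(stage, "genetic_map", f"{outdir}/genetic_map.tsv")
                summary_lines.append(
                    f"simulate: {population.n_individuals} animals, "
                    f"{population.n_snps} SNPs"
                )
            elif stage == "scan":
                results, line_summary = scan_by_line(
                    population,
                    window_sizes=config.window_sizes,
                    step_factor=config.step_factor,
                    freq_min=config.freq_min,
                    alpha=config.alpha,
                    chrom_lengths=sim.chrom_lengths,
                )
                results.to_csv(f"{outdir}/deficit_scan.tsv", sep="\t", index=False)
                line_summary.to_csv(f"{outdir}/deficit_summary.tsv", sep="\t")
                _out(stage, "deficit_table", f"{outdir}/deficit_scan.tsv")
                _out(stage, "line_summary", f"{outdir}/deficit_summary.tsv")
                summary_lines.append(
                    f"scan: {int(results['significant'].sum())} significant "
                    f"haplotypes over {len(results)} tests"
                )
            elif stage == "catalog":
                catalog = simulate_variant_catalog(sim, config.samples_per_line)
                filtered, report = filter_sites(
                    catalog.variants,
                    config.qual_min,
                    config.callrate_min,
                    config.indel_exclusion_bp,
                )
                catalog.variants = classify_variants(
                    filtered, config.sift_deleterious, config.rnacov_min
                )
                catalog.variants = add_per_line_af(catalog.variants, catalog.lines)
                write_catalog_tsv(catalog.variants, f"{outdir}/catalog.tsv")
                _out(stage, "catalog", f"{outdir}/catalog.tsv")
                manifest["outputs"]["catalog"]["filter_report"] = report
                summary_lines.append(
                    f"catalog: {len(catalog.variants)} variants post-QC "
                    f"(TS/TV {ts_tv(catalog.variants):.2f})"
                )
            elif stage == "afs":
                spectra = afs_by_class(
                    catalog.variants,
                    ["synonymous", "missense_tolerated", "missense_deleterious", "lof"],
                    lines=catalog.lines,
                )
                rows = []
                for cls, hist in spectra.items():
                    for b in range(20):
                        rows.append(
                            {
                                "class": cls,
                                "bin_low": hist.bin_edges[b],
                                "bin_high": hist.bin_edges[b + 1],
                                "count": int(hist.counts[b]),
                                "proportion": hist.proportions[b],
                            }
                        )
                pd.DataFrame(rows).to_csv(f"{outdir}/afs.tsv", sep="\t", index=False)
                _out(stage, "afs", f"{outdir}/afs.tsv")
                summary_lines.append("afs: spectra for 4 classes")
            elif stage == "sweep":
                frames = []
                for line in catalog.lines:
                    frames.append(
                        zhp_scan(
                            catalog.variants,
                            line,
                            config.sweep_window_bp,
                            config.sweep_min_variants,
                            config.zhp_threshold,
                        )
                    )
                sweeps = pd.concat(frames, ignore_index=True)
                bed = sweeps[sweeps["scored"]][
                    ["chrom", "start", "end", "Hp", "zHp", "sweep_flag", "line"]
                ]
                bed.to_csv(f"{outdir}/sweeps.bed", sep="\t", index=False, header=False)
                fixed = fixed_intolerant(catalog.variants, catalog.lines, config.af_fixed)
                fixed.to_csv(f"{outdir}/fixed_intolerant.tsv", sep="\t", index=False)
                _out(stage, "sweep_bed", f"{outdir}/sweeps.bed")
                _out(stage, "fixed_intolerant", f"{outdir}/fixed_intolerant.tsv")
                summary_lines.append(
                    f"sweep: {int(sweeps['sweep_flag'].sum())} flagged windows, "
                    f"{len(fixed)} fixed/nearly fixed intolerant variants"
                )
            elif stage == "recomb":
                gmap = simulate_genetic_map(sim)
                bins = recombination_bins(
                    gmap, config.recomb_bin_bp, config.recomb_chroms, sim.chrom_lengths
                )
                bins = bin_variant_classes(bins, catalog.variants)
                corr = purging_correlation(bins, seed=config.seed)
                bins.to_csv(f"{outdir}/recomb_bins.tsv", sep="\t", index=False)
                with open(f"{outdir}/purging_correlation.json", "w") as fh:
                    json.dump(
                        {k: v for k, v in corr.items() if k != "table"}, fh, indent=2
                    )
                _out(stage, "bins", f"{outdir}/recomb_bins.tsv")
                _out(stage, "correlation", f"{outdir}/purging_correlation.json")
                summary_lines.append(
                    f"recomb: r = {corr['pearson_r']:.3f} over {corr['n_bins']} bins"
                )
            elif stage == "el":
                lethal_genes = set(
                    catalog.genes.loc[catalog.genes["lethal_flag"], "gene_id"]
                )
                candidates = el_filter(catalog.variants, lethal_genes, catalog.lines)
                candidates.to_csv(f"{outdir}/el_candidates.tsv", sep="\t", index=False)
                _out(stage, "el_candidates", f"{outdir}/el_candidates.tsv")
                ht = None
                if population is not None and population.lethal_tags is not None:
                    hatch = simulate_hatchability(
                        population,
                        penetrance=sim.penetrance,
                        seed=config.seed,
                    )
                    hatch.to_csv(f"{outdir}/hatchability.tsv", sep="\t", index=False)
                    _out(stage, "hatchability", f"{outdir}/hatchability.tsv")
                    counts = hatch["carrier_status"].value_counts()
                    if counts.get("CxC", 0) >= 2 and counts.get("CxN", 0) >= 2:
                        ht = hatchability_test(hatch)
                        manifest["outputs"]["el"]["hatchability_test"] = ht
                summary_lines.append(f"el: {len(candidates)} candidates")
        except Exception as exc:  # noqa: BLE001 - halt with the stage's diagnostic
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            _write_manifest(manifest, outdir, partial=True)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    manifest["summary"] = summary_lines
    _write_manifest(manifest, outdir, partial=False)
    return manifest


def _write_manifest(manifest: dict, outdir: str, partial: bool) -> None:
    manifest["partial"] = partial
    with open(f"{outdir}/manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
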