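"""Shared fixtures: hand-built populations and packaged toy files."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pytest

from layervar import SimulationConfig, simulate_population
from layervar.population import PhasedPopulation

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


def build_population(snp_bp, individuals, chrom="1", lethal_tags=None):
    """Construct a PhasedPopulation from explicit haplotype strings.

    ``individuals`` is a list of (id, line, sire_id, dam_id, sex, generation,
    (hap_a, hap_b)) with haplotypes as "0"/"1" strings ("." = missing).
    """
    snp_map = pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(len(snp_bp))],
            "chrom": chrom,
            "bp": list(snp_bp),
        }
    )
    ids = [rec[0] for rec in individuals]
    pos = {iid: i for i, iid in enumerate(ids)}
    rows = []
    haps = np.zeros((len(individuals), 2, len(snp_bp)), dtype=np.uint8)
    for i, (iid, line, sire, dam, sex, gen, (ha, hb)) in enumerate(individuals):
        rows.append(
            {
                "id": iid,
                "line": line,
                "sire": sire,
                "dam": dam,
                "sex": sex,
                "generation": gen,
                "genotyped": True,
                "sire_idx": pos.get(sire, -1) if sire else -1,
                "dam_idx": pos.get(dam, -1) if dam else -1,
            }
        )
        for k, h in enumerate((ha, hb)):
            haps[i, k] = [255 if c == "." else int(c) for c in h]
    return PhasedPopulation(
        snp_map=snp_map,
        individuals=pd.DataFrame(rows),
        haplotypes=haps,
        lethal_tags=lethal_tags,
    )


def het_by_het_population(n_offspring=20, target="1111", other="0000"):
    """One carrier-by-carrier mating: both parents carry one target copy."""
    snp_bp = [1000 * (i + 1) for i in range(len(target))]
    inds = [
        ("S", "L", None, None, "M", 0, (target, other)),
        ("D", "L", None, None, "F", 0, (other, target)),
    ]
    third = "01" * (len(target) // 2) or "01"
    third = (third * len(target))[: len(target)]
    for i in range(n_offspring):
        inds.append((f"O{i}", "L", "S", "D", "M", 1, (other, third)))
    return build_population(snp_bp, inds)


@pytest.fixture(scope="session")
def lethal_config():
    """Small population segregating a fully penetrant lethal at 5%."""
    return SimulationConfig(
        seed=11,
        lines=("WA",),
        n_founders_per_line=600,
        n_generations=2,
        offspring_per_mating=2,
        n_matings_per_line=300,
        n_snps=84,
        chrom_lengths={"1": 4_000_000},
        lethal_window=("1", 1_500_000, 2_000_000),
        lethal_target_freq=0.05,
        penetrance=1.0,
    )


@pytest.fixture(scope="session")
def lethal_population(lethal_config):
    return simulate_population(lethal_config)


@pytest.fixture(scope="session")
def catalog_config():
    """Default-condition catalogue at a size that keeps tests fast."""
    return SimulationConfig(
        seed=5,
        lines=("WA", "WD", "W1"),
        variant_counts={
            "synonymous": 1500,
            "missense_tolerated": 1000,
            "missense_deleterious": 400,
            "stop_gained": 80,
            "frameshift": 100,
            "inframe_insertion": 60,
            "inframe_deletion": 60,
            "splice_acceptor": 25,
            "splice_donor": 25,
            "stop_lost": 10,
            "start_lost": 10,
            "other": 800,
        },
        n_genes=300,
        n_el_truth=20,
    )


@pytest.fixture(scope="session")
def sim_catalog(catalog_config):
    from layervar import simulate_variant_catalog

    return simulate_variant_catalog(
        catalog_config, {"WA": 40, "WD": 40, "W1": 40}
    )


@pytest.fixture()
def toy_sites_vcf():
    return os.path.join(DATA_DIR, "toy_sites.vcf")


@pytest.fixture()
def el_fixture_path():
    return os.path.join(DATA_DIR, "el_variants.tsv")


@pytest.fixture()
def lethal_genes_path():
    return os.path.join(DATA_DIR, "lethal_genes.tsv")
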