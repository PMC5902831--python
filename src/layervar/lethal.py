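"""Candidate embryonic-lethal variant filtering, carrier-concordance matching
and the carrier-mating hatchability comparison.

An embryonic-lethal (EL) candidate is a putative loss-of-function or
deleterious missense variant that (1) is never observed homozygous for the
alternate allele and (2) sits in a gene whose null-mutant mouse phenotype is
early lethality.  In-frame indels additionally require a deleterious PROVEAN
score.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import PROTEIN_ALTERING_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "el_filter",
    "haplotype_concordance",
    "hatchability_test",
]

_INFRAME = ("inframe_insertion", "inframe_deletion")


def el_filter(
    variants: pd.DataFrame,
    lethal_gene_set: Iterable[str],
    lines: Optional[Iterable[str]] = None,
    provean_inframe_max: float = -2.5,
    exclusion_list: Optional[Iterable[tuple]] = None,
) -> pd.DataFrame:
    """Select candidate embryonic-lethal variants.

    A candidate must be classified LoF or deleterious missense (in-frame
    indels only when PROVEAN <= ``provean_inframe_max``), have zero hom-alt
    genotypes across all samples, and lie in a gene from ``lethal_gene_set``.
    ``exclusion_list`` holds (chrom, pos, ref, alt) tuples of manually
    excluded records (machine-readable stand-in for visual curation).

    The output carries ``line_specific_to`` ("shared" when carried in more
    than one line), ``carrier_count`` and an ordered ``reason_trail`` of
    (criterion, passed) pairs replaying the accept decision.
    """
    lethal_genes = set(lethal_gene_set)
    if not lethal_genes:
        raise ValueError("empty lethal gene set: lethality criterion untestable")
    if "label" not in variants.columns:
        raise ValueError("variants must be classified first (classify_variants)")
    if lines is None:
        lines = sorted(
            c.split("_", 1)[1] for c in variants.columns if c.startswith("nhom_")
        )
    lines = list(lines)
    excluded = set(map(tuple, exclusion_list)) if exclusion_list else set()

    label = variants["label"].to_numpy()
    cons = variants["consequence"].to_numpy()
    provean = variants["provean"].to_numpy(dtype=float)
    damaging = (label == "lof") | (label == "missense_deleterious")
    inframe = np.isin(cons, _INFRAME)
    damaging &= ~inframe | (np.nan_to_num(provean, nan=0.0) <= provean_inframe_max)

    nhom = sum(variants[f"nhom_{line}"].to_numpy() for line in lines)
    no_hom = nhom == 0
    in_gene = variants["gene_id"].isin(lethal_genes).to_numpy()

    rows = []
    for i in np.flatnonzero(damaging & no_hom & in_gene):
        key = (
            variants["chrom"].iat[i],
            int(variants["pos"].iat[i]),
            variants["ref"].iat[i],
            variants["alt"].iat[i],
        )
        manually_ok = key not in excluded
        trail = [
            ("damaging_class", True),
            ("no_homozygotes", True),
            ("lethal_gene", True),
            ("not_manually_excluded", manually_ok),
        ]
        if not manually_ok:
            logger.info("EL candidate at %s:%d excluded by curation list", key[0], key[1])
            continue
        carried = [line for line in lines if variants[f"ac_{line}"].iat[i] > 0]
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "gene_id": variants["gene_id"].iat[i],
                "consequence": cons[i],
                "label": label[i],
                "line_specific_to": carried[0] if len(carried) == 1 else "shared",
                "carrier_count": int(
                    sum(variants[f"ac_{line}"].iat[i] for line in lines)
                ),
                "reason_trail": trail,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "consequence", "label",
            "line_specific_to", "carrier_count", "reason_trail",
        ],
    )


def haplotype_concordance(
    carrier_ids: Iterable[str],
    chrom: str,
    start: int,
    end: int,
    catalog,
    sample_to_individual: Mapping[str, str],
    flank: int = 0,
    strict: bool = True,
    min_concordance: float = 0.8,
) -> pd.DataFrame:
    """Protein-altering variants carried uniquely by haplotype carriers.

    Sequenced samples are mapped to chip individuals via
    ``sample_to_individual``.  In strict mode a variant is reported when its
    sequenced alt-carriers coincide exactly with the sequenced haplotype
    carriers and no hom-alt genotype exists; in relaxed mode the Jaccard
    concordance between the two sets is reported and variants at or above
    ``min_concordance`` are kept.  Returns an empty, ``untestable``-flagged
    frame when no sequenced carriers exist.
    """
    if catalog.genotypes is None:
        raise ValueError("catalog must carry per-sample genotypes")
    carriers = set(carrier_ids)
    samples = catalog.samples["sample"].to_numpy()
    mapped = np.array([s in sample_to_individual for s in samples])
    seq_carrier = np.array(
        [mapped[j] and sample_to_individual[samples[j]] in carriers
         for j in range(len(samples))]
    )
    cols = [
        "variant_index", "chrom", "pos", "ref", "alt", "gene_id",
        "consequence", "concordance", "n_alt_carriers", "n_hap_carriers",
    ]
    if not seq_carrier.any():
        logger.warning("no sequenced haplotype carriers: concordance untestable")
        out = pd.DataFrame(columns=cols)
        out.attrs["untestable"] = True
        return out

    v = catalog.variants
    region = (
        (v["chrom"].to_numpy() == chrom)
        & (v["pos"].to_numpy() >= start - flank)
        & (v["pos"].to_numpy() < end + flank)
        & v["consequence"].isin(PROTEIN_ALTERING_CLASSES).to_numpy()
    )
    rows = []
    hap_set = seq_carrier & mapped
    for i in np.flatnonzero(region):
        g = catalog.genotypes[i]
        if np.any((g == 2) & mapped):
            continue
        alt_set = (g >= 1) & mapped
        union = (alt_set | hap_set).sum()
        inter = (alt_set & hap_set).sum()
        conc = inter / union if union else 0.0
        keep = conc == 1.0 if strict else conc >= min_concordance
        if keep and alt_set.any():
            rows.append(
                {
                    "variant_index": int(i),
                    "chrom": v["chrom"].iat[i],
                    "pos": int(v["pos"].iat[i]),
                    "ref": v["ref"].iat[i],
                    "alt": v["alt"].iat[i],
                    "gene_id": v["gene_id"].iat[i],
                    "consequence": v["consequence"].iat[i],
                    "concordance": float(conc),
                    "n_alt_carriers": int(alt_set.sum()),
                    "n_hap_carriers": int(hap_set.sum()),
                }
            )
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["untestable"] = False
    return out


def hatchability_test(
    hatch_records: pd.DataFrame,
    group_a: str = "CxC",
    group_b: str = "CxN",
) -> dict:
    """Equal-variance two-sample t-test of hatch fraction between mating types.

    Compares carrier-by-carrier against carrier-by-non-carrier matings on
    per-mating hatch fractions (hatched / eggs set), two-sided.  Raises when
    either group has fewer than 2 matings.
    """
    frac = hatch_records["hatched"] / hatch_records["eggs_set"]
    status = hatch_records["carrier_status"]
    a = frac[status == group_a].to_numpy(dtype=float)
    b = frac[status == group_b].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need >= 2 matings per group; got {a.size} {group_a} and {b.size} {group_b}"
        )
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate pooled variance: identical values give t = 0, p = 1
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(t),
        "df": int(a.size + b.size - 2),
        "p_value": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
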