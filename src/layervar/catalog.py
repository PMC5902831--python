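"""Site/genotype QC and functional classification of the variant catalogue.

Works on a :class:`pandas.DataFrame` of biallelic records carrying QC fields
(``qual``, ``call_rate``, ``near_indel_bp``), annotation fields
(``consequence``, ``gene_id``, ``sift``, ``provean``, ``aa_pos``, ``aa_len``,
``ortho11``, ``rnacov``) and per-line allele counts ``ac_<line>`` /
``an_<line>`` / ``nhom_<line>``.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import LOF_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "filter_sites",
    "filter_genotypes",
    "classify_variants",
    "classify",
    "per_line_af",
    "add_per_line_af",
    "ts_tv",
    "mutation_load",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _nearest_indel_distance(df: pd.DataFrame) -> np.ndarray:
    """bp distance from each SNV to the nearest indel on the same chromosome."""
    dist = np.full(len(df), np.inf)
    pos = df["pos"].to_numpy()
    is_indel = df["is_indel"].to_numpy(dtype=bool)
    chrom = df["chrom"].to_numpy()
    for c in pd.unique(chrom):
        m = chrom == c
        ind_pos = np.sort(pos[m & is_indel])
        snv = m & ~is_indel
        if ind_pos.size == 0 or not snv.any():
            continue
        p = pos[snv]
        i = np.searchsorted(ind_pos, p)
        left = np.where(i > 0, p - ind_pos[np.maximum(i - 1, 0)], np.inf)
        right = np.where(i < ind_pos.size, ind_pos[np.minimum(i, ind_pos.size - 1)] - p,
                         np.inf)
        dist[snv] = np.minimum(left, right)
    return dist


def filter_sites(
    variants: pd.DataFrame,
    qual_min: float = 20.0,
    callrate_min: float = 0.7,
    indel_exclusion_bp: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Post-calling site filters.

    Removes SNVs within ``indel_exclusion_bp`` of an indel (distance <=
    threshold, an inclusive reading of "within"), then sites with phred
    quality below ``qual_min`` or call rate below ``callrate_min`` (strict
    "below", so a site at exactly the threshold survives).  Idempotent.

    Returns the surviving records and a stage-wise report.
    """
    for fieldname in ("qual", "call_rate"):
        if fieldname not in variants.columns:
            raise ValueError(f"missing QC field {fieldname!r}")
    report = {"input": len(variants)}
    if "near_indel_bp" in variants.columns:
        dist = variants["near_indel_bp"].to_numpy(dtype=float)
        computed = _nearest_indel_distance(variants) if "is_indel" in variants else None
        if computed is not None:
            dist = np.where(np.isnan(dist), computed, dist)
    elif {"is_indel", "pos", "chrom"} <= set(variants.columns):
        dist = _nearest_indel_distance(variants)
    else:
        raise ValueError("missing QC field 'near_indel_bp' (and no positions to derive it)")
    dist = np.where(np.isnan(dist), np.inf, dist)
    is_indel = (
        variants["is_indel"].to_numpy(dtype=bool)
        if "is_indel" in variants.columns
        else np.zeros(len(variants), dtype=bool)
    )
    near = ~is_indel & (dist <= indel_exclusion_bp)
    report["removed_near_indel"] = int(near.sum())
    keep = ~near
    low_qual = keep & (variants["qual"].to_numpy() < qual_min)
    report["removed_quality"] = int(low_qual.sum())
    keep &= ~low_qual
    low_cr = keep & (variants["call_rate"].to_numpy() < callrate_min)
    report["removed_callrate"] = int(low_cr.sum())
    keep &= ~low_cr
    report["output"] = int(keep.sum())
    return variants[keep].reset_index(drop=True), report


def filter_genotypes(
    genotypes: np.ndarray,
    depths: np.ndarray,
    depth_min: int = 4,
    depth_max_factor: float = 2.5,
    sample_mean_depth: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype depth filter: keep depths in ``[min, mean * factor]``.

    Both bounds are inclusive; failing genotype calls become missing (-1).
    ``sample_mean_depth`` defaults to each sample's mean depth over called
    genotypes.  Returns the filtered genotype matrix and the recomputed
    per-variant call rate.
    """
    genotypes = np.asarray(genotypes)
    depths = np.asarray(depths)
    if genotypes.shape != depths.shape:
        raise ValueError("genotypes and depths must have the same shape")
    if sample_mean_depth is None:
        called = genotypes >= 0
        with np.errstate(invalid="ignore"):
            sample_mean_depth = np.where(
                called.sum(axis=0) > 0,
                np.where(called, depths, 0).sum(axis=0)
                / np.maximum(called.sum(axis=0), 1),
                0.0,
            )
    sample_mean_depth = np.asarray(sample_mean_depth, dtype=float)
    if np.any(sample_mean_depth <= 0):
        raise ValueError("average sample depth must be positive")
    ceiling = sample_mean_depth * depth_max_factor
    bad = (depths < depth_min) | (depths > ceiling[None, :])
    out = genotypes.copy()
    out[bad & (out >= 0)] = -1
    call_rate = (out >= 0).mean(axis=1)
    return out, call_rate


def classify(
    consequence: str,
    sift: Optional[float],
    ortho11: bool,
    rnacov: float,
    sift_deleterious: float = 0.05,
    rnacov_min: float = 200.0,
) -> tuple[str, bool]:
    """Classify one variant record.

    Returns ``(label, deleterious_final)`` where label is one of
    ``synonymous``, ``missense_tolerated``, ``missense_deleterious``,
    ``missense_unscored``, ``lof`` or ``other``, and ``deleterious_final``
    marks membership in the final deleterious set: (LoF or deleterious
    missense) in a 1:1-orthologous gene with RNA-seq coverage of at least
    ``rnacov_min``.
    """
    if consequence in LOF_CLASSES:
        label = "lof"
    elif consequence == "missense":
        if sift is None or (isinstance(sift, float) and np.isnan(sift)):
            label = "missense_unscored"
            logger.info("missense variant without SIFT score: excluded from class comparisons")
        elif sift <= sift_deleterious:
            label = "missense_deleterious"
        else:
            label = "missense_tolerated"
    elif consequence == "synonymous":
        label = "synonymous"
    else:
        label = "other"
    damaging = label == "lof" or label == "missense_deleterious"
    final = bool(damaging and ortho11 and rnacov >= rnacov_min)
    return label, final


def classify_variants(
    variants: pd.DataFrame,
    sift_deleterious: float = 0.05,
    rnacov_min: float = 200.0,
) -> pd.DataFrame:
    """Vectorised :func:`classify` over a catalogue; adds ``label`` and
    ``deleterious_final`` columns (pure function of each row's fields)."""
    cons = variants["consequence"].to_numpy()
    sift = variants["sift"].to_numpy(dtype=float)
    label = np.full(len(variants), "other", dtype=object)
    label[np.isin(cons, list(LOF_CLASSES))] = "lof"
    m = cons == "missense"
    label[m & np.isnan(sift)] = "missense_unscored"
    label[m & (sift <= sift_deleterious)] = "missense_deleterious"
    label[m & (sift > sift_deleterious)] = "missense_tolerated"
    label[cons == "synonymous"] = "synonymous"
    n_unscored = int((label == "missense_unscored").sum())
    if n_unscored:
        logger.info("%d missense variants lack a SIFT score and are unscored", n_unscored)
    damaging = (label == "lof") | (label == "missense_deleterious")
    final = (
        damaging
        & variants["ortho11"].to_numpy(dtype=bool)
        & (variants["rnacov"].to_numpy(dtype=float) >= rnacov_min)
    )
    out = variants.copy()
    out["label"] = label
    out["deleterious_final"] = final
    return out


def per_line_af(variants: pd.DataFrame, line: str) -> np.ndarray:
    """Alternate-allele frequency within one line (missing excluded).

    Lines with zero called alleles yield ``NaN`` (flagged undefined).
    """
    ac = variants[f"ac_{line}"].to_numpy(dtype=float)
    an = variants[f"an_{line}"].to_numpy(dtype=float)
    af = np.divide(ac, an, out=np.full(len(variants), np.nan), where=an > 0)
    n_undef = int((an == 0).sum())
    if n_undef:
        logger.info("line %s: %d variants with no called alleles (AF undefined)",
                    line, n_undef)
    return af


def add_per_line_af(variants: pd.DataFrame, lines: Sequence[str]) -> pd.DataFrame:
    out = variants.copy()
    for line in lines:
        out[f"af_{line}"] = per_line_af(variants, line)
    return out


def ts_tv(variants: pd.DataFrame) -> float:
    """Transition/transversion ratio over biallelic SNVs.

    Transitions are A<->G and C<->T.  Returns ``inf`` with a warning when no
    transversions are present.
    """
    if "is_indel" in variants.columns:
        snv = variants[~variants["is_indel"].astype(bool)]
    else:
        snv = variants
    snv = snv[(snv["ref"].str.len() == 1) & (snv["alt"].str.len() == 1)]
    pairs = list(zip(snv["ref"], snv["alt"]))
    n_ts = sum(p in _TRANSITIONS for p in pairs)
    n_tv = len(pairs) - n_ts
    if n_tv == 0:
        warnings.warn("no transversions observed; TS/TV is infinite")
        return float("inf")
    return n_ts / n_tv


def mutation_load(
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    sample_names: Sequence[str],
    sift_load: float = 0.01,
) -> pd.DataFrame:
    """Per-individual deleterious burden and mutation load.

    Counts heterozygous and homozygous genotypes at deleterious variants
    (SIFT strictly below ``sift_load``, the load threshold, which is tighter
    than the class threshold) and synonymous variants, and reports
    ``load_ratio`` = deleterious / synonymous carried-variant counts per
    individual (``NaN``, flagged, when no synonymous variants are carried).
    """
    if "label" not in variants.columns:
        raise ValueError("variants must be classified first (classify_variants)")
    sift = variants["sift"].to_numpy(dtype=float)
    deleterious = (
        (variants["label"].to_numpy() == "missense_deleterious")
        & np.isfinite(sift)
        & (sift < sift_load)
    )
    synonymous = variants["label"].to_numpy() == "synonymous"
    g = np.asarray(genotypes)
    het_del = ((g == 1) & deleterious[:, None]).sum(axis=0)
    hom_del = ((g == 2) & deleterious[:, None]).sum(axis=0)
    syn_carried = ((g > 0) & synonymous[:, None]).sum(axis=0)
    del_carried = het_del + hom_del
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(syn_carried > 0, del_carried / np.maximum(syn_carried, 1),
                         np.nan)
    n_undef = int((syn_carried == 0).sum())
    if n_undef:
        logger.info("%d individuals carry no synonymous variants; load undefined",
                    n_undef)
    return pd.DataFrame(
        {
            "sample": list(sample_names),
            "n_het_deleterious": het_del,
            "n_hom_deleterious": hom_del,
            "n_deleterious": del_carried,
            "n_synonymous": syn_carried,
            "load_ratio": ratio,
        }
    )
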