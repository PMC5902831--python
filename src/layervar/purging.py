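"""Recombination-rate vs deleterious/tolerated ratio, protein-position
profiles and indel-length spectra.

Purifying selection removes deleterious alleles more efficiently where
recombination decouples them from linked favoured variants, so the ratio of
deleterious missense to (synonymous + tolerated missense) variants is
expected to decline with local cM/Mb.  The ratio is computed in ~750-kb bins
on the macrochromosomes and correlated with the bin recombination rate.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

__all__ = [
    "recombination_bins",
    "bin_variant_classes",
    "purging_correlation",
    "relative_position",
    "position_profiles",
    "indel_length_spectrum",
]


def recombination_bins(
    genetic_map: pd.DataFrame,
    bin_bp: int = 750_000,
    chroms: Sequence[str] = ("1", "2", "3", "4", "5"),
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Recombination rate (cM/Mb) in fixed physical bins on macrochromosomes.

    The cM length of a bin is obtained by linear interpolation of the map at
    the bin edges; beyond the terminal markers the cM value is held constant,
    so unmapped terminal bins get rate 0 (flagged via ``beyond_map``).
    Terminal bins shorter than half a bin are dropped.
    """
    rows = []
    for chrom in chroms:
        sub = genetic_map[genetic_map["chrom"].astype(str) == str(chrom)]
        if sub.empty:
            continue
        sub = sub.sort_values("bp")
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(cm) < 0)
        if bad.size:
            markers = sub["marker"].to_numpy()[bad + 1] if "marker" in sub else bad + 1
            raise ValueError(
                f"genetic map not monotone in cM on chromosome {chrom}: "
                f"offending markers {list(markers)[:10]}"
            )
        end = int(chrom_lengths[str(chrom)]) if chrom_lengths else int(bp[-1])
        edges = list(range(0, end, bin_bp))
        if end - edges[-1] >= bin_bp // 2 and edges[-1] != end:
            edges.append(end)
        for start, stop in zip(edges[:-1], edges[1:]):
            cm_lo = float(np.interp(start, bp, cm))
            cm_hi = float(np.interp(stop, bp, cm))
            length_mb = (stop - start) / 1e6
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": start,
                    "end": stop,
                    "cm_length": cm_hi - cm_lo,
                    "rate": (cm_hi - cm_lo) / length_mb,
                    "beyond_map": start >= bp[-1] or stop <= bp[0],
                }
            )
    return pd.DataFrame(rows)


def bin_variant_classes(bins: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Count deleterious missense, synonymous and tolerated missense per bin.

    Adds ``del_tol_ratio`` = deleterious / (synonymous + tolerated), ``NaN``
    when the denominator is zero.
    """
    if "label" not in variants.columns:
        raise ValueError("variants must be classified first")
    out = bins.copy()
    n_del = np.zeros(len(bins), dtype=int)
    n_syn = np.zeros(len(bins), dtype=int)
    n_tol = np.zeros(len(bins), dtype=int)
    label = variants["label"].to_numpy()
    chrom = variants["chrom"].astype(str).to_numpy()
    pos = variants["pos"].to_numpy(dtype=float)
    for i, row in enumerate(bins.itertuples()):
        m = (chrom == str(row.chrom)) & (pos >= row.start) & (pos < row.end)
        n_del[i] = int((m & (label == "missense_deleterious")).sum())
        n_syn[i] = int((m & (label == "synonymous")).sum())
        n_tol[i] = int((m & (label == "missense_tolerated")).sum())
    out["n_deleterious_missense"] = n_del
    out["n_synonymous"] = n_syn
    out["n_tolerated_missense"] = n_tol
    denom = n_syn + n_tol
    out["del_tol_ratio"] = np.divide(
        n_del, denom, out=np.full(len(bins), np.nan), where=denom > 0
    )
    return out


def purging_correlation(
    bins: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
    rate_cut: float = 2.0,
) -> dict:
    """Pearson correlation of recombination rate vs deleterious/tolerated ratio.

    Only bins with a defined ratio enter.  Reports the t-distribution p-value
    and a permutation p-value (bins are spatially autocorrelated, so the
    permutation p is the safer reference), plus a two-class summary of the
    mean ratio in low (rate <= ``rate_cut``) vs high recombination bins.
    """
    ok = bins["del_tol_ratio"].notna().to_numpy()
    if ok.sum() == 0:
        raise ValueError("all bins have undefined deleterious/tolerated ratios")
    if ok.sum() < 3:
        raise ValueError("need at least 3 bins with defined ratios")
    rate = bins.loc[ok, "rate"].to_numpy(dtype=float)
    ratio = bins.loc[ok, "del_tol_ratio"].to_numpy(dtype=float)
    r, p_t = stats.pearsonr(rate, ratio)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = np.corrcoef(rate, rng.permutation(ratio))[0, 1]
    p_perm = (1 + np.sum(np.abs(perm) >= abs(r))) / (n_permutations + 1)
    low = rate <= rate_cut
    return {
        "pearson_r": float(r),
        "p_value": float(p_t),
        "p_permutation": float(p_perm),
        "permutation_null_abs_r_95": float(np.quantile(np.abs(perm), 0.95)),
        "n_bins": int(ok.sum()),
        "mean_ratio_low_recomb": float(ratio[low].mean()) if low.any() else math.nan,
        "mean_ratio_high_recomb": float(ratio[~low].mean()) if (~low).any() else math.nan,
        "table": bins.loc[ok].reset_index(drop=True),
    }


def relative_position(aa_pos: int, aa_len: int) -> tuple[float, int]:
    """Relative protein position in (0, 1] and its decile bin (1..10).

    ``bin = ceil(10 * aa_pos / aa_len)``; the mapping is invariant to integer
    scaling of (aa_pos, aa_len).  Rejects records with ``aa_pos > aa_len``.
    """
    if aa_pos < 1 or aa_len < 1:
        raise ValueError("aa_pos and aa_len must be positive")
    if aa_pos > aa_len:
        raise ValueError(f"aa_pos {aa_pos} exceeds protein length {aa_len}")
    relpos = aa_pos / aa_len
    return relpos, int(math.ceil(10 * relpos))


def _position_bins(variants: pd.DataFrame) -> np.ndarray:
    """Decile bin per variant; NaN-position or inconsistent records get -1."""
    aa_pos = variants["aa_pos"].to_numpy(dtype=float)
    aa_len = variants["aa_len"].to_numpy(dtype=float)
    ok = np.isfinite(aa_pos) & np.isfinite(aa_len) & (aa_pos >= 1) & (aa_pos <= aa_len)
    n_bad = int((np.isfinite(aa_pos) & np.isfinite(aa_len) & (aa_pos > aa_len)).sum())
    if n_bad:
        logger.warning("%d records with aa_pos > aa_len rejected", n_bad)
    bins = np.full(len(variants), -1, dtype=int)
    bins[ok] = np.ceil(10 * aa_pos[ok] / aa_len[ok]).astype(int)
    return bins


def position_profiles(
    variants: pd.DataFrame,
    classes: Sequence[str],
    reference: str = "synonymous",
    n_permutations: int = 999,
    seed: int = 0,
    class_column: str = "consequence",
) -> dict:
    """10-bin protein-position histograms plus a terminal-enrichment statistic.

    For each class the enrichment is the proportion of variants in the first
    and last decile relative to the same proportion in the reference class;
    a label-permutation p-value (one-sided, enrichment > 1) accompanies it.
    """
    bins = _position_bins(variants)
    labels = variants[class_column].to_numpy()
    rng = np.random.default_rng(seed)
    ref_bins = bins[(labels == reference) & (bins > 0)]
    if ref_bins.size == 0:
        raise ValueError(f"reference class {reference!r} has no positioned variants")
    ref_term = np.isin(ref_bins, (1, 10)).mean()
    out: dict[str, dict] = {}
    for cls in classes:
        cls_bins = bins[(labels == cls) & (bins > 0)]
        profile = np.bincount(cls_bins, minlength=11)[1:]
        if cls_bins.size == 0:
            logger.info("class %s has no positioned variants", cls)
            out[cls] = {
                "profile": profile,
                "n": 0,
                "terminal_enrichment": math.nan,
                "p_permutation": math.nan,
                "empty": True,
            }
            continue
        cls_term = np.isin(cls_bins, (1, 10)).mean()
        enrich = cls_term / ref_term if ref_term > 0 else math.inf
        pooled = np.concatenate([cls_bins, ref_bins])
        n_cls = cls_bins.size
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            pt = np.isin(pooled[:n_cls], (1, 10)).mean()
            pr = np.isin(pooled[n_cls:], (1, 10)).mean()
            stat = pt / pr if pr > 0 else np.inf
            if stat >= enrich:
                count += 1
        out[cls] = {
            "profile": profile,
            "n": int(n_cls),
            "terminal_enrichment": float(enrich),
            "p_permutation": (count + 1) / (n_permutations + 1),
            "empty": False,
        }
    return out


def indel_length_spectrum(
    variants: pd.DataFrame,
    max_len: int = 15,
) -> dict:
    """Length histograms of coding vs non-coding indels and in-frame fractions.

    Coding indels are frameshift/inframe consequence classes; lengths are
    signed (insertions positive).  The in-frame fraction (|length| % 3 == 0)
    is compared between coding and non-coding with a two-proportion z-test.
    """
    if "is_indel" not in variants.columns:
        raise ValueError("variants must carry an 'is_indel' column")
    indels = variants[variants["is_indel"].astype(bool)]
    if indels.empty:
        logger.info("no indels in catalogue")
        return {
            "coding_hist": np.zeros(max_len, dtype=int),
            "noncoding_hist": np.zeros(max_len, dtype=int),
            "inframe_fraction_coding": math.nan,
            "inframe_fraction_noncoding": math.nan,
            "z": math.nan,
            "p_value": math.nan,
            "empty": True,
        }
    coding_classes = ("frameshift", "inframe_insertion", "inframe_deletion")
    coding = indels["consequence"].isin(coding_classes).to_numpy()
    lengths = np.abs(indels["indel_len"].to_numpy(dtype=int))
    lengths = np.clip(lengths, 1, max_len)

    def _hist(mask):
        return np.bincount(lengths[mask], minlength=max_len + 1)[1:]

    inframe = lengths % 3 == 0
    n_cod, n_non = int(coding.sum()), int((~coding).sum())
    f_cod = inframe[coding].mean() if n_cod else math.nan
    f_non = inframe[~coding].mean() if n_non else math.nan
    if n_cod and n_non and 0 < inframe.sum() < inframe.size:
        z, p = proportions_ztest(
            [int(inframe[coding].sum()), int(inframe[~coding].sum())], [n_cod, n_non]
        )
    elif n_cod and n_non:
        z, p = math.nan, 1.0  # degenerate: identical proportions of 0 or 1
    else:
        z, p = math.nan, math.nan
    return {
        "coding_hist": _hist(coding),
        "noncoding_hist": _hist(~coding),
        "inframe_fraction_coding": float(f_cod),
        "inframe_fraction_noncoding": float(f_non),
        "z": float(z) if np.isfinite(z) else z,
        "p_value": float(p) if np.isfinite(p) else p,
        "empty": False,
    }
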