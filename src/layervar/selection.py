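"""Allele-frequency spectra, pooled-heterozygosity sweep scan and
high-frequency "evolutionary intolerant" variant sets.

The sweep statistic is the pooled heterozygosity of a genomic window,

    Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))^2,

where the sums run over per-SNP major and minor allele counts within the
window and line.  Hp lies in [0, 0.5]; its genome-wide Z-score (zHp)
standardises windows within a line, and strongly negative zHp marks
candidate selective sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import per_line_af

logger = logging.getLogger(__name__)

__all__ = [
    "AFSHistogram",
    "afs_histogram",
    "afs_by_class",
    "pooled_heterozygosity",
    "zhp_scan",
    "fixed_intolerant",
    "line_specific_high_freq",
    "sweep_overlap",
]

#: Allele-frequency bin edges: 20 bins of width 0.05 over [0, 1].
AFS_BIN_EDGES = np.round(np.arange(0, 21) * 0.05, 10)


@dataclass
class AFSHistogram:
    """Allele-frequency spectrum of one functional class."""

    class_label: str
    bin_edges: np.ndarray
    counts: np.ndarray
    proportions: np.ndarray
    empty: bool = False


def afs_histogram(afs: np.ndarray, class_label: str = "") -> AFSHistogram:
    """20-bin histogram of allele frequencies.

    Bins are half-open ``[k*0.05, (k+1)*0.05)`` except the last, which is
    closed so AF exactly 1.0 lands in the top bin and the bins partition the
    class.  Non-finite frequencies are ignored.
    """
    afs = np.asarray(afs, dtype=float)
    afs = afs[np.isfinite(afs)]
    if np.any((afs < 0) | (afs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    idx = np.minimum((afs / 0.05).astype(int), 19)
    counts = np.bincount(idx, minlength=20)
    total = counts.sum()
    empty = total == 0
    if empty:
        logger.info("class %s has no variants; all-zero spectrum", class_label)
        proportions = np.zeros(20)
    else:
        proportions = counts / total
    return AFSHistogram(
        class_label=class_label,
        bin_edges=AFS_BIN_EDGES.copy(),
        counts=counts,
        proportions=proportions,
        empty=empty,
    )


def afs_by_class(
    variants: pd.DataFrame,
    classes: Sequence[str],
    lines: Optional[Sequence[str]] = None,
    pooled: bool = True,
) -> dict[str, AFSHistogram]:
    """Spectra per functional class label, pooled across lines by default.

    Pooled frequencies are total alt counts over total called alleles; in
    per-line mode each line contributes its own frequency per variant.
    """
    if "label" not in variants.columns:
        raise ValueError("variants must carry a 'label' column (classify first)")
    if lines is None:
        lines = sorted(
            c.split("_", 1)[1] for c in variants.columns if c.startswith("ac_")
        )
    out = {}
    for cls in classes:
        sub = variants[variants["label"] == cls]
        if pooled:
            ac = sum(sub[f"ac_{line}"].to_numpy(dtype=float) for line in lines)
            an = sum(sub[f"an_{line}"].to_numpy(dtype=float) for line in lines)
            af = np.divide(ac, an, out=np.full(len(sub), np.nan), where=an > 0)
        else:
            af = np.concatenate([per_line_af(sub, line) for line in lines]) if len(sub) else np.array([])
        out[cls] = afs_histogram(af, cls)
    return out


def pooled_heterozygosity(n_major: np.ndarray, n_minor: np.ndarray) -> float:
    """Hp from per-SNP major and minor allele counts of one window."""
    smaj = float(np.sum(n_major))
    smin = float(np.sum(n_minor))
    tot = smaj + smin
    if tot <= 0:
        raise ValueError("window has no called alleles")
    return 2.0 * smaj * smin / tot**2


def zhp_scan(
    variants: pd.DataFrame,
    line: Optional[str] = None,
    window_bp: int = 20_000,
    min_variants: int = 20,
    z_threshold: float = -2.7,
    pooled_lines: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Genome-wide pooled-heterozygosity scan for one line.

    Windows are a non-overlapping ``window_bp`` grid anchored at position 0 of
    each chromosome.  Windows with fewer than ``min_variants`` variants are
    left unscored; zHp standardises Hp over all scored windows of the line and
    ``sweep_flag`` marks windows with ``zHp <= z_threshold``.

    Passing ``pooled_lines`` instead of ``line`` pools allele counts across
    those lines before computing Hp (pooled mode).
    """
    if (line is None) == (pooled_lines is None):
        raise ValueError("pass exactly one of line or pooled_lines")
    if pooled_lines is not None:
        ac = sum(variants[f"ac_{l}"].to_numpy(dtype=float) for l in pooled_lines)
        an = sum(variants[f"an_{l}"].to_numpy(dtype=float) for l in pooled_lines)
        line = "+".join(pooled_lines)
    else:
        ac = variants[f"ac_{line}"].to_numpy(dtype=float)
        an = variants[f"an_{line}"].to_numpy(dtype=float)
    called = an > 0
    n_major = np.maximum(ac, an - ac)
    n_minor = np.minimum(ac, an - ac)
    df = pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy(),
            "win": variants["pos"].to_numpy(dtype=int) // window_bp,
            "maj": np.where(called, n_major, 0.0),
            "min": np.where(called, n_minor, 0.0),
            "n": called.astype(int),
        }
    )
    grouped = df.groupby(["chrom", "win"], sort=True).sum().reset_index()
    grouped["start"] = grouped["win"] * window_bp
    grouped["end"] = grouped["start"] + window_bp
    scored = grouped["n"] >= min_variants
    if scored.sum() < 2:
        raise ValueError(
            f"only {int(scored.sum())} scored windows for line {line}; "
            "zHp needs at least 2 (sd undefined)"
        )
    tot = grouped["maj"] + grouped["min"]
    hp = np.where(
        scored & (tot > 0), 2.0 * grouped["maj"] * grouped["min"] / tot**2, np.nan
    )
    mean = np.nanmean(hp[scored])
    sd = np.nanstd(hp[scored], ddof=1)
    if sd == 0:
        raise ValueError("all scored windows have identical Hp; zHp undefined")
    z = (hp - mean) / sd
    out = pd.DataFrame(
        {
            "line": line,
            "chrom": grouped["chrom"],
            "start": grouped["start"].astype(int),
            "end": grouped["end"].astype(int),
            "n_variants": grouped["n"].astype(int),
            "Hp": hp,
            "zHp": z,
            "sweep_flag": scored.to_numpy() & (z <= z_threshold),
            "scored": scored.to_numpy(),
        }
    )
    return out


def fixed_intolerant(
    variants: pd.DataFrame,
    lines: Sequence[str],
    af_min: float = 0.9,
) -> pd.DataFrame:
    """Deleterious variants fixed or nearly fixed (AF > ``af_min``) in >= 1 line.

    Adds per-line boolean columns ``nearfixed_<line>`` and a ``fixed`` flag
    for variants at AF exactly 1.0 in every line with called alleles.
    """
    if "deleterious_final" not in variants.columns:
        raise ValueError("variants must be classified first")
    sub = variants[variants["deleterious_final"]].copy()
    any_high = np.zeros(len(sub), dtype=bool)
    all_fixed = np.ones(len(sub), dtype=bool)
    for line in lines:
        af = per_line_af(sub, line)
        high = np.nan_to_num(af, nan=0.0) > af_min
        sub[f"nearfixed_{line}"] = high
        any_high |= high
        defined = np.isfinite(af)
        all_fixed &= np.where(defined, af == 1.0, True)
    sub["fixed"] = all_fixed
    return sub[any_high].reset_index(drop=True)


def line_specific_high_freq(
    variants: pd.DataFrame,
    lines: Sequence[str],
    af_min: float = 0.7,
) -> dict[str, pd.DataFrame]:
    """High-frequency variants private to a single line.

    A variant qualifies for a line when its AF there exceeds ``af_min`` and
    its alt count is zero in every other line; the per-line sets are
    pairwise disjoint by construction.
    """
    if len(lines) < 2:
        raise ValueError("line-specific sets need at least 2 lines")
    afs = {line: np.nan_to_num(per_line_af(variants, line), nan=0.0) for line in lines}
    acs = {line: variants[f"ac_{line}"].to_numpy() for line in lines}
    out = {}
    for line in lines:
        absent_elsewhere = np.ones(len(variants), dtype=bool)
        for other in lines:
            if other != line:
                absent_elsewhere &= acs[other] == 0
        mask = (afs[line] > af_min) & absent_elsewhere
        out[line] = variants[mask].reset_index(drop=True)
    return out


def sweep_overlap(
    fixed_set: pd.DataFrame,
    sweep_windows: pd.DataFrame,
    af_min: float = 0.9,
) -> pd.DataFrame:
    """Fixed/nearly fixed intolerant variants inside flagged sweep windows.

    A variant is reported when its position falls in a ``sweep_flag`` window
    of a line in which its frequency exceeds ``af_min``.
    """
    flagged = sweep_windows[sweep_windows["sweep_flag"]]
    if flagged.empty or fixed_set.empty:
        return fixed_set.iloc[0:0].copy()
    rows = []
    for _, win in flagged.iterrows():
        line = win["line"]
        af = per_line_af(fixed_set, line)
        m = (
            (fixed_set["chrom"].to_numpy() == win["chrom"])
            & (fixed_set["pos"].to_numpy() >= win["start"])
            & (fixed_set["pos"].to_numpy() < win["end"])
            & (np.nan_to_num(af, nan=0.0) > af_min)
        )
        for i in np.flatnonzero(m):
            rows.append((i, line))
    if not rows:
        return fixed_set.iloc[0:0].copy()
    idx = sorted({i for i, _ in rows})
    out = fixed_set.iloc[idx].copy()
    line_map: dict[int, list[str]] = {}
    for i, line in rows:
        line_map.setdefault(i, []).append(line)
    out["sweep_lines"] = [",".join(sorted(set(line_map[i]))) for i in idx]
    return out.reset_index(drop=True)
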