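"""In-memory container for phased, pedigreed chip genotypes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Missing-allele code in haplotype arrays.
MISSING_ALLELE = 255


@dataclass
class PhasedPopulation:
    """Phased haplotypes over a SNP map plus pedigree links.

    Attributes
    ----------
    snp_map:
        One row per SNP with columns ``chrom`` and ``bp``, sorted by
        (chrom, bp); the row order indexes the last axis of ``haplotypes``.
    individuals:
        One row per animal with columns ``id``, ``line``, ``sire``, ``dam``
        (parent ids or ``None``), ``sex`` ("M"/"F"), ``generation``,
        ``genotyped`` (bool) and integer columns ``sire_idx``/``dam_idx``
        (row positions, ``-1`` for founders).
    haplotypes:
        ``uint8`` array of shape ``(n_individuals, 2, n_snps)`` holding 0/1
        alleles (``MISSING_ALLELE`` = missing).
    lethal_tags:
        Optional bool array ``(n_individuals, 2)`` marking chromosomes that
        carry the simulated lethal mutation (truth labels).
    """

    snp_map: pd.DataFrame
    individuals: pd.DataFrame
    haplotypes: np.ndarray
    lethal_tags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n_ind = len(self.individuals)
        if self.haplotypes.shape != (n_ind, 2, len(self.snp_map)):
            raise ValueError(
                "haplotypes shape "
                f"{self.haplotypes.shape} inconsistent with {n_ind} individuals "
                f"and {len(self.snp_map)} SNPs"
            )
        if self.lethal_tags is not None and self.lethal_tags.shape != (n_ind, 2):
            raise ValueError("lethal_tags must have shape (n_individuals, 2)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def window_snp_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of SNPs with ``bp`` in ``[start, end)`` on ``chrom``."""
        mask = (
            (self.snp_map["chrom"].to_numpy() == chrom)
            & (self.snp_map["bp"].to_numpy() >= start)
            & (self.snp_map["bp"].to_numpy() < end)
        )
        return np.flatnonzero(mask)

    def subset(self, rows: Sequence[int]) -> "PhasedPopulation":
        """Restrict to the given individual rows, remapping parent indices."""
        rows = np.asarray(rows, dtype=int)
        ind = self.individuals.iloc[rows].reset_index(drop=True)
        old_to_new = {old: new for new, old in enumerate(rows)}
        for col in ("sire_idx", "dam_idx"):
            ind[col] = [old_to_new.get(v, -1) for v in ind[col]]
        return PhasedPopulation(
            snp_map=self.snp_map,
            individuals=ind,
            haplotypes=self.haplotypes[rows],
            lethal_tags=None if self.lethal_tags is None else self.lethal_tags[rows],
        )

    def line_subset(self, line: str) -> "PhasedPopulation":
        rows = np.flatnonzero(self.individuals["line"].to_numpy() == line)
        return self.subset(rows)


@dataclass
class MatingTable:
    """Pre-grouped matings of a population.

    ``sire_idx``/``dam_idx`` index individual rows; ``offspring_offsets`` and
    ``offspring_rows`` store, CSR-style, the genotyped offspring of each
    mating.  ``n_pedigree_offspring`` counts all pedigree offspring of the
    pair, genotyped or not.
    """

    sire_idx: np.ndarray
    dam_idx: np.ndarray
    n_offspring: np.ndarray
    offspring_offsets: np.ndarray
    offspring_rows: np.ndarray
    n_pedigree_offspring: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_matings(self) -> int:
        return len(self.sire_idx)

    def offspring_of(self, mating: int) -> np.ndarray:
        lo, hi = self.offspring_offsets[mating], self.offspring_offsets[mating + 1]
        return self.offspring_rows[lo:hi]


def build_mating_table(population: PhasedPopulation) -> MatingTable:
    """Group offspring with two known parents by (sire, dam).

    Every pedigree pair appears; ``n_offspring`` and the offspring lists
    count genotyped offspring only, ``n_pedigree_offspring`` counts all.
    """
    ind = population.individuals
    sire = ind["sire_idx"].to_numpy()
    dam = ind["dam_idx"].to_numpy()
    genotyped = ind["genotyped"].to_numpy(dtype=bool)
    has_parents = (sire >= 0) & (dam >= 0)
    rows_all = np.flatnonzero(has_parents)

    pairs = pd.DataFrame(
        {
            "s": sire[rows_all],
            "d": dam[rows_all],
            "row": rows_all,
            "gt": genotyped[rows_all],
        }
    )
    sires, dams, counts, ped_counts, offspring = [], [], [], [], []
    for (s, d), grp in pairs.groupby(["s", "d"], sort=True):
        sires.append(s)
        dams.append(d)
        gt_rows = grp.loc[grp["gt"], "row"].to_numpy()
        counts.append(len(gt_rows))
        ped_counts.append(len(grp))
        offspring.append(gt_rows)

    offsets = np.zeros(len(sires) + 1, dtype=int)
    if counts:
        offsets[1:] = np.cumsum(counts)
    return MatingTable(
        sire_idx=np.asarray(sires, dtype=int),
        dam_idx=np.asarray(dams, dtype=int),
        n_offspring=np.asarray(counts, dtype=int),
        offspring_offsets=offsets,
        offspring_rows=(
            np.concatenate(offspring) if offspring else np.empty(0, dtype=int)
        ),
        n_pedigree_offspring=np.asarray(ped_counts, dtype=int),
    )
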