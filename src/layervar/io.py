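"""Readers and writers for the standard interchange formats.

Phased genotypes travel as VCF with ``|``-separated GT (1-based positions);
pedigree, genetic map, annotation and hatchability tables as TSV; chip
genotypes as PLINK-style PED/MAP.  Reading VCF uses :mod:`cyvcf2`.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .population import MISSING_ALLELE, PhasedPopulation

__all__ = [
    "write_phased_vcf",
    "read_phased_vcf",
    "write_ped_map",
    "write_pedigree",
    "read_pedigree",
    "write_genetic_map",
    "read_genetic_map",
    "write_annotated_vcf",
    "read_annotated_vcf",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "attach_pedigree",
]

_INFO_KEYS = (
    ("CSQ_CLASS", "consequence", str),
    ("GENE", "gene_id", str),
    ("SIFT", "sift", float),
    ("PROVEAN", "provean", float),
    ("AAPOS", "aa_pos", float),
    ("AALEN", "aa_len", float),
    ("ORTHO11", "ortho11", int),
    ("RNACOV", "rnacov", float),
)


def write_phased_vcf(population: PhasedPopulation, path: str) -> None:
    """Phased GT VCF; alleles are arbitrary REF=A / ALT=B placeholders."""
    ids = population.individuals["id"].tolist()
    genotyped = population.individuals["genotyped"].to_numpy(dtype=bool)
    cols = [i for i, g in zip(range(len(ids)), genotyped) if g]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in _chrom_lengths_of(population).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids[c] for c in cols)
            + "\n"
        )
        snp_map = population.snp_map
        markers = (
            snp_map["marker"]
            if "marker" in snp_map.columns
            else pd.Series([f"snp{i}" for i in range(len(snp_map))])
        )
        haps = population.haplotypes
        for j in range(len(snp_map)):
            gts = []
            for c in cols:
                a, b = haps[c, 0, j], haps[c, 1, j]
                sa = "." if a == MISSING_ALLELE else str(int(a))
                sb = "." if b == MISSING_ALLELE else str(int(b))
                gts.append(f"{sa}|{sb}")
            fh.write(
                f"{snp_map['chrom'].iat[j]}\t{int(snp_map['bp'].iat[j]) + 1}\t"
                f"{markers.iat[j]}\tA\tB\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _chrom_lengths_of(population: PhasedPopulation) -> dict[str, int]:
    out = {}
    for chrom, grp in population.snp_map.groupby("chrom", sort=False):
        out[str(chrom)] = int(grp["bp"].max()) + 2
    return out


def read_phased_vcf(path: str, pedigree: Optional[pd.DataFrame] = None) -> PhasedPopulation:
    """Load a phased VCF (GT with '|') into a :class:`PhasedPopulation`.

    Positions are converted to the package's 0-based internal coordinates.
    When a pedigree table is supplied, parent links and line labels are
    attached; otherwise all animals are unrelated singletons of line "NA".
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, bps, markers, rows = [], [], [], []
    for record in vcf:
        chroms.append(record.CHROM)
        bps.append(record.POS - 1)
        markers.append(record.ID or f"{record.CHROM}:{record.POS}")
        gts = np.array(record.genotypes)
        alleles = gts[:, :2].astype(np.int16)
        alleles[alleles < 0] = MISSING_ALLELE
        rows.append(alleles.astype(np.uint8))
    snp_map = pd.DataFrame({"marker": markers, "chrom": chroms, "bp": bps})
    haplotypes = (
        np.stack(rows, axis=2) if rows else np.empty((len(samples), 2, 0), np.uint8)
    )
    individuals = pd.DataFrame(
        {
            "id": samples,
            "line": "NA",
            "sire": None,
            "dam": None,
            "sex": "U",
            "generation": 0,
            "genotyped": True,
            "sire_idx": -1,
            "dam_idx": -1,
        }
    )
    pop = PhasedPopulation(snp_map=snp_map, individuals=individuals, haplotypes=haplotypes)
    if pedigree is not None:
        pop = attach_pedigree(pop, pedigree)
    return pop


def attach_pedigree(population: PhasedPopulation, pedigree: pd.DataFrame) -> PhasedPopulation:
    """Attach sire/dam/line/sex columns from a pedigree table (by id)."""
    ind = population.individuals.copy()
    ped = pedigree.set_index("id")
    pos = {iid: i for i, iid in enumerate(ind["id"])}
    for col in ("line", "sex"):
        if col in ped.columns:
            ind[col] = [
                ped[col].get(iid, ind[col].iat[i]) for i, iid in enumerate(ind["id"])
            ]
    for parent, idx_col in (("sire", "sire_idx"), ("dam", "dam_idx")):
        if parent in ped.columns:
            vals = [ped[parent].get(iid) for iid in ind["id"]]
            vals = [None if (v is None or (isinstance(v, float) and np.isnan(v)) or v in ("0", ""))
                    else v for v in vals]
            ind[parent] = vals
            ind[idx_col] = [pos.get(v, -1) if v is not None else -1 for v in vals]
    return PhasedPopulation(
        snp_map=population.snp_map,
        individuals=ind,
        haplotypes=population.haplotypes,
        lethal_tags=population.lethal_tags,
    )


def write_ped_map(population: PhasedPopulation, prefix: str) -> None:
    """PLINK-style .ped/.map (alleles 1/2, unphased order preserved)."""
    snp_map = population.snp_map
    with open(prefix + ".map", "w") as fh:
        for j in range(len(snp_map)):
            marker = (
                snp_map["marker"].iat[j] if "marker" in snp_map.columns else f"snp{j}"
            )
            fh.write(
                f"{snp_map['chrom'].iat[j]}\t{marker}\t0\t{int(snp_map['bp'].iat[j]) + 1}\n"
            )
    ind = population.individuals
    with open(prefix + ".ped", "w") as fh:
        for i in range(len(ind)):
            if not ind["genotyped"].iat[i]:
                continue
            sex = {"M": "1", "F": "2"}.get(ind["sex"].iat[i], "0")
            fields = [
                str(ind["line"].iat[i]),
                str(ind["id"].iat[i]),
                str(ind["sire"].iat[i] or "0"),
                str(ind["dam"].iat[i] or "0"),
                sex,
                "0",
            ]
            for j in range(population.n_snps):
                for k in (0, 1):
                    a = population.haplotypes[i, k, j]
                    fields.append("0" if a == MISSING_ALLELE else str(int(a) + 1))
            fh.write(" ".join(fields) + "\n")


def write_pedigree(population: PhasedPopulation, path: str) -> None:
    cols = ["id", "sire", "dam", "line", "sex"]
    df = population.individuals[cols].copy()
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})


def write_genetic_map(genetic_map: pd.DataFrame, path: str) -> None:
    out = genetic_map.copy()
    out["bp"] = out["bp"].astype(int) + 1  # 1-based on disk
    out[["marker", "chrom", "bp", "cm"]].to_csv(path, sep="\t", index=False)


def read_genetic_map(path: str) -> pd.DataFrame:
    gmap = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    gmap["bp"] = gmap["bp"].astype(int) - 1
    return gmap


def write_catalog_tsv(variants: pd.DataFrame, path: str) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=True,
                       na_values=[""], low_memory=False)


def write_annotated_vcf(
    variants: pd.DataFrame, path: str, lines: Sequence[str] = ()
) -> None:
    """Sites-only VCF with the catalogue's annotation in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, _, typ in _INFO_KEYS:
            vcftype = {str: "String", float: "Float", int: "Integer"}[typ]
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={vcftype},Description="{key}">\n'
            )
        for line in lines:
            for tag in ("AC", "AN", "NHOM"):
                fh.write(
                    f'##INFO=<ID={tag}_{line},Number=1,Type=Integer,'
                    f'Description="{tag} in line {line}">\n'
                )
        for chrom in pd.unique(variants["chrom"]):
            sub = variants[variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 2}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in variants.iterrows():
            info = []
            for key, col, typ in _INFO_KEYS:
                val = row.get(col)
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    continue
                if typ is int:
                    val = int(val)
                elif typ is float:
                    val = round(float(val), 6)
                info.append(f"{key}={val}")
            for line in lines:
                for tag, col in (("AC", "ac"), ("AN", "an"), ("NHOM", "nhom")):
                    if f"{col}_{line}" in row.index:
                        info.append(f"{tag}_{line}={int(row[f'{col}_{line}'])}")
            qual = row.get("qual")
            qual_s = "." if qual is None or (isinstance(qual, float) and np.isnan(qual)) else f"{qual:.1f}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual_s}\tPASS\t{';'.join(info) or '.'}\n"
            )


def read_annotated_vcf(path: str, lines: Sequence[str] = ()) -> pd.DataFrame:
    """Read a sites VCF with CSQ_CLASS/GENE/SIFT/... INFO keys into a catalogue."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    rows = []
    for record in vcf:
        row = {
            "chrom": record.CHROM,
            "pos": record.POS,
            "ref": record.REF,
            "alt": record.ALT[0] if record.ALT else "",
            "qual": record.QUAL if record.QUAL is not None else np.nan,
        }
        row["is_indel"] = len(row["ref"]) != len(row["alt"])
        row["indel_len"] = len(row["alt"]) - len(row["ref"])
        cr = record.INFO.get("CR")
        if cr is not None:
            row["call_rate"] = float(cr)
        for key, col, typ in _INFO_KEYS:
            val = record.INFO.get(key)
            if val is None:
                row[col] = np.nan if typ is not str else ""
            elif typ is int:
                row[col] = bool(int(val)) if col == "ortho11" else int(val)
            elif typ is float:
                row[col] = float(val)
            else:
                row[col] = str(val)
        row["ortho11"] = bool(row.get("ortho11") or False)
        for line in lines:
            for tag, col in (("AC", "ac"), ("AN", "an"), ("NHOM", "nhom")):
                val = record.INFO.get(f"{tag}_{line}")
                row[f"{col}_{line}"] = int(val) if val is not None else 0
        rows.append(row)
    return pd.DataFrame(rows)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
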