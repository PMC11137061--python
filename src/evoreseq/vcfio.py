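"""Standard-format readers and writers.

VCF 4.2 is the single variant interchange format: pooled libraries carry
FORMAT GT and AD (per-allele depths), individually sequenced flies carry GT,
DP and AD (whose two entries double as the reference/alternative supporting
read counts).  Sample metadata travels in a tab-separated sample sheet;
embryo measurements and per-individual covered-base totals in tab-separated
tables.  All positions are 1-based per the VCF standard.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .containers import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    EmbryoRecord,
    GenotypeMatrix,
    PoolADTable,
    embryos_to_frame,
    frame_to_embryos,
)

__all__ = [
    "read_sample_sheet",
    "write_sample_sheet",
    "read_pool_vcf",
    "write_pool_vcf",
    "read_individual_vcf",
    "write_individual_vcf",
    "read_individual_sheet",
    "read_embryo_table",
    "write_embryo_table",
    "load_yaml_config",
    "dump_yaml_config",
    "write_table_with_header",
]


class VcfFormatError(ValueError):
    """Malformed or inconsistent VCF content."""


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet: sample, population, generation, role, mutagenized."""
    sheet = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "population", "generation"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        dupes = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample names in sheet: {dupes}")
    if "role" not in sheet.columns:
        sheet["role"] = "pool"
    if "mutagenized" not in sheet.columns:
        sheet["mutagenized"] = True
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def _vcf_header(sites: pd.DataFrame, samples: Sequence[str], individual: bool):
    header = pysam.VariantHeader()
    for chrom in pd.unique(sites["chrom"]):
        length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1000
        header.contigs.add(str(chrom), length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(
        "AD", "R", "Integer", "Allelic depths for the ref and alt alleles"
    )
    if individual:
        header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(str(s))
    return header


_GT_TUPLE = {
    GT_HOM_REF: (0, 0),
    GT_HET: (0, 1),
    GT_HOM_ALT: (1, 1),
    GT_MISSING: (None, None),
}


def write_pool_vcf(table: PoolADTable, path) -> None:
    """Write pooled allele depths to VCF 4.2 (FORMAT GT:AD).

    Pools have no diploid genotype; GT is emitted as missing and AD carries
    the information.
    """
    header = _vcf_header(table.sites, table.samples["sample"], individual=False)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(table.n_sites):
            row = table.sites.iloc[i]
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            for j, name in enumerate(table.samples["sample"]):
                rec.samples[name]["GT"] = (None, None)
                rec.samples[name]["AD"] = (
                    int(table.ref_depth[i, j]),
                    int(table.alt_depth[i, j]),
                )
            vcf.write(rec)


def read_pool_vcf(path, sheet: pd.DataFrame) -> PoolADTable:
    """Read a multi-sample VCF with FORMAT AD into a pooled depth table.

    Biallelic SNPs are parsed for testing; multiallelic or indel records are
    kept with ``biallelic=False`` so downstream filters can see them.
    Missing AD becomes zero depth (the sample-site is effectively missing).
    Samples absent from the sheet, or malformed AD entries, raise an error
    naming the sample or record.
    """
    pool_sheet = sheet.loc[sheet.get("role", "pool") == "pool"]
    known = set(pool_sheet["sample"])
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        unknown = [s for s in vcf_samples if s not in known]
        if unknown:
            raise ValueError(
                f"VCF samples absent from the sample sheet: {unknown}"
            )
        site_rows = []
        ref_cols = []
        alt_cols = []
        for rec in vcf:
            alts = rec.alts or ()
            biallelic = len(alts) == 1
            is_indel = any(len(a) != len(rec.ref) for a in alts) or len(rec.ref) > 1
            site_rows.append(
                (
                    rec.contig,
                    rec.pos,
                    rec.ref,
                    alts[0] if alts else ".",
                    biallelic and not is_indel,
                )
            )
            ref_row = np.zeros(len(vcf_samples), dtype=np.int64)
            alt_row = np.zeros(len(vcf_samples), dtype=np.int64)
            for j, s in enumerate(vcf_samples):
                ad = rec.samples[s].get("AD")
                if ad is None or all(v is None for v in ad):
                    continue
                if len(ad) < 2 or any(
                    v is not None and v < 0 for v in ad
                ):
                    raise VcfFormatError(
                        f"malformed AD at {rec.contig}:{rec.pos} sample {s}"
                    )
                ref_row[j] = ad[0] or 0
                alt_row[j] = ad[1] or 0
            ref_cols.append(ref_row)
            alt_cols.append(alt_row)
    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "ref", "alt", "biallelic"]
    )
    meta = pool_sheet.set_index("sample").loc[vcf_samples].reset_index()
    samples = meta[["sample", "population", "generation"]].copy()
    n = len(sites)
    ref = np.vstack(ref_cols) if n else np.zeros((0, len(vcf_samples)), dtype=np.int64)
    alt = np.vstack(alt_cols) if n else np.zeros((0, len(vcf_samples)), dtype=np.int64)
    return PoolADTable(sites=sites, samples=samples, ref_depth=ref, alt_depth=alt)


def write_individual_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write an individual genotype matrix to VCF 4.2 (FORMAT GT:DP:AD)."""
    names = matrix.individuals["name"].tolist()
    header = _vcf_header(matrix.sites, names, individual=True)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(matrix.n_sites):
            row = matrix.sites.iloc[i]
            ref = str(row["ref"])
            alt = str(row["alt"])
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(ref, alt),
            )
            for j, name in enumerate(names):
                rec.samples[name]["GT"] = _GT_TUPLE[int(matrix.gt[i, j])]
                rec.samples[name]["DP"] = int(matrix.depth[i, j])
                rec.samples[name]["AD"] = (
                    int(matrix.ref_reads[i, j]),
                    int(matrix.alt_reads[i, j]),
                )
            vcf.write(rec)


def read_individual_sheet(path) -> pd.DataFrame:
    """Sidecar table of per-individual covered bases and mutagenized flags."""
    sheet = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "covered_bases", "mutagenized"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"individual sheet lacks columns: {sorted(missing)}")
    return sheet


def read_individual_vcf(path, individuals: pd.DataFrame) -> GenotypeMatrix:
    """Read individually sequenced flies (FORMAT GT, DP, AD) from VCF.

    ``individuals`` is the sidecar table from :func:`read_individual_sheet`;
    every VCF sample must appear in it.
    """
    meta = individuals.set_index("name")
    with pysam.VariantFile(str(path)) as vcf:
        names = list(vcf.header.samples)
        unknown = [s for s in names if s not in meta.index]
        if unknown:
            raise ValueError(
                f"VCF samples absent from the individual sheet: {unknown}"
            )
        site_rows = []
        gt_rows, dp_rows, ref_rows, alt_rows = [], [], [], []
        for rec in vcf:
            alts = rec.alts or ()
            # multiallelic records keep their first alternative but are
            # flagged so the variant filter removes them
            alt_allele = alts[0] if alts else "."
            is_indel = (
                len(rec.ref) > 1
                or any(len(a) != len(rec.ref) for a in alts)
                or len(alts) != 1
            )
            site_rows.append((rec.contig, rec.pos, rec.ref, alt_allele, is_indel))
            gt_row = np.full(len(names), GT_MISSING, dtype=np.int8)
            dp_row = np.zeros(len(names), dtype=np.int64)
            ref_row = np.zeros(len(names), dtype=np.int64)
            alt_row = np.zeros(len(names), dtype=np.int64)
            for j, s in enumerate(names):
                sample = rec.samples[s]
                gt = sample.get("GT")
                if gt is not None and None not in gt:
                    gt_row[j] = int(sum(gt))
                dp = sample.get("DP")
                dp_row[j] = int(dp) if dp is not None else 0
                ad = sample.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    ref_row[j] = ad[0]
                    alt_row[j] = ad[1] or 0
            gt_rows.append(gt_row)
            dp_rows.append(dp_row)
            ref_rows.append(ref_row)
            alt_rows.append(alt_row)
    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "ref", "alt", "is_indel"]
    )
    ind = meta.loc[names].reset_index()[["name", "mutagenized", "covered_bases"]]
    n = len(sites)
    shape = (n, len(names))
    return GenotypeMatrix(
        sites=sites,
        individuals=ind,
        gt=np.vstack(gt_rows) if n else np.zeros(shape, dtype=np.int8),
        depth=np.vstack(dp_rows) if n else np.zeros(shape, dtype=np.int64),
        ref_reads=np.vstack(ref_rows) if n else np.zeros(shape, dtype=np.int64),
        alt_reads=np.vstack(alt_rows) if n else np.zeros(shape, dtype=np.int64),
    )


def write_embryo_table(records: Sequence[EmbryoRecord], path, header_lines=()) -> None:
    frame = embryos_to_frame(records)
    write_table_with_header(frame, path, header_lines)


def read_embryo_table(path) -> list[EmbryoRecord]:
    return frame_to_embryos(pd.read_csv(path, sep="\t", comment="#"))


def write_table_with_header(frame: pd.DataFrame, path, header_lines=()) -> None:
    """Write a TSV with leading ``#`` comment lines (version/seed/thresholds)."""
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data


def dump_yaml_config(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
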