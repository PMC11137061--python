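"""Shared in-memory containers for variant tables and embryo measurements.

The analysis modules exchange three tabular containers built on pandas /
numpy: per-individual genotype matrices (mutation-rate estimation), pooled
allele-depth tables (recurrence and association scans), and per-embryo
measurement records (phenomics).  All genomic coordinates are 1-based, as in
VCF; all embryo coordinates are micrometers with the anterior pole at x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: genotype codes used throughout: -1 missing, 0 hom-ref, 1 het, 2 hom-alt
GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2


@dataclass
class GenotypeMatrix:
    """Per-individual genotype calls with read support.

    Attributes
    ----------
    sites : pandas.DataFrame
        Site registry with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``, ``is_indel``.
    individuals : pandas.DataFrame
        One row per sequenced fly: ``name``, ``mutagenized`` (bool),
        ``covered_bases`` (bases passing the caller's quality/depth filters).
    gt : numpy.ndarray
        ``(n_sites, n_individuals)`` int8 array of genotype codes.
    depth : numpy.ndarray
        Read depth per genotype, same shape.
    ref_reads, alt_reads : numpy.ndarray
        Reads supporting the reference / alternative allele per genotype.
    """

    sites: pd.DataFrame
    individuals: pd.DataFrame
    gt: np.ndarray
    depth: np.ndarray
    ref_reads: np.ndarray
    alt_reads: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_ind = self.gt.shape
        if len(self.sites) != n_sites or len(self.individuals) != n_ind:
            raise ValueError("registry sizes do not match genotype array shape")
        for name in ("depth", "ref_reads", "alt_reads"):
            if getattr(self, name).shape != self.gt.shape:
                raise ValueError(f"{name} shape does not match gt")
        nonmiss = self.gt != GT_MISSING
        if np.any((self.ref_reads + self.alt_reads)[nonmiss] > self.depth[nonmiss]):
            raise ValueError("supporting read counts exceed depth")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gt.shape[1]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            individuals=self.individuals.copy(),
            gt=self.gt[mask].copy(),
            depth=self.depth[mask].copy(),
            ref_reads=self.ref_reads[mask].copy(),
            alt_reads=self.alt_reads[mask].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset_sites(np.ones(self.n_sites, dtype=bool))


@dataclass
class PoolADTable:
    """Per-site, per-(population, generation) reference/alternative depths.

    ``samples`` has one row per pooled library with columns ``sample``,
    ``population``, ``generation``; ``ref_depth``/``alt_depth`` are
    ``(n_sites, n_samples)`` integer arrays.  Sites flagged non-biallelic are
    carried through I/O but excluded from testing.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        if self.ref_depth.shape != self.alt_depth.shape:
            raise ValueError("ref/alt depth shapes differ")
        if self.ref_depth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("depth array shape does not match registries")
        if np.any(self.ref_depth < 0) or np.any(self.alt_depth < 0):
            raise ValueError("depths must be non-negative")
        if "biallelic" not in self.sites.columns:
            self.sites = self.sites.assign(biallelic=True)

    @property
    def n_sites(self) -> int:
        return self.ref_depth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ref_depth.shape[1]

    def sample_index(self, population, generation) -> int:
        hit = np.flatnonzero(
            (self.samples["population"].to_numpy() == population)
            & (self.samples["generation"].to_numpy() == generation)
        )
        if len(hit) != 1:
            raise KeyError(
                f"expected exactly one sample for population {population!r} "
                f"generation {generation!r}, found {len(hit)}"
            )
        return int(hit[0])

    @staticmethod
    def concat_samples(tables: Sequence["PoolADTable"]) -> "PoolADTable":
        """Column-bind tables that share an identical site registry."""
        first = tables[0]
        for t in tables[1:]:
            if not first.sites[["chrom", "pos"]].equals(t.sites[["chrom", "pos"]]):
                raise ValueError("site registries differ between tables")
        return PoolADTable(
            sites=first.sites.copy(),
            samples=pd.concat([t.samples for t in tables], ignore_index=True),
            ref_depth=np.hstack([t.ref_depth for t in tables]),
            alt_depth=np.hstack([t.alt_depth for t in tables]),
        )


@dataclass
class EmbryoRecord:
    """One embryo's length, stripe coordinates and nuclei coordinates.

    Lengths and coordinates are micrometers, anterior pole at 0, pole cells
    excluded.  ``stripes_um`` holds anterior boundaries of up to seven
    pair-rule stripes, non-decreasing from stripe 1 to 7.  ``nuclei_um`` is an
    ``(n, 2)`` array of (x, y) nucleus centers ordered along the A-P axis.
    """

    embryo_id: str
    population: str
    generation: int
    length_um: float
    stripes_um: np.ndarray
    nuclei_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    experimenter: str = ""

    def __post_init__(self) -> None:
        self.stripes_um = np.asarray(self.stripes_um, dtype=float)
        self.nuclei_um = np.asarray(self.nuclei_um, dtype=float).reshape(-1, 2)
        if self.length_um <= 0:
            raise ValueError("length_um must be positive")
        s = self.stripes_um
        if s.size:
            if np.any(s < 0) or np.any(s > self.length_um):
                raise ValueError("stripe coordinates must lie within [0, length]")
            if np.any(np.diff(s) < 0):
                raise ValueError("stripe coordinates must be non-decreasing")


@dataclass
class ProfileTrace:
    """An intensity trace sampled along the A-P axis of one embryo."""

    positions_um: np.ndarray
    intensity: np.ndarray
    posterior_um: float

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions_um.shape != self.intensity.shape:
            raise ValueError("positions and intensities differ in length")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def embryos_to_frame(records: Sequence[EmbryoRecord]) -> pd.DataFrame:
    """Flatten embryo records into the tab-separated table layout.

    Columns: embryo_id, population, generation, length_um, stripe1_um ..
    stripe7_um, then ``nuc{i}_x_um``/``nuc{i}_y_um`` pairs padded to the
    largest nucleus count (empty cells for shorter embryos).
    """
    max_nuc = max((r.nuclei_um.shape[0] for r in records), default=0)
    rows = []
    for r in records:
        row = {
            "embryo_id": r.embryo_id,
            "population": r.population,
            "generation": r.generation,
            "length_um": r.length_um,
        }
        for i in range(7):
            row[f"stripe{i + 1}_um"] = (
                r.stripes_um[i] if i < len(r.stripes_um) else np.nan
            )
        for i in range(max_nuc):
            if i < r.nuclei_um.shape[0]:
                row[f"nuc{i + 1}_x_um"] = r.nuclei_um[i, 0]
                row[f"nuc{i + 1}_y_um"] = r.nuclei_um[i, 1]
            else:
                row[f"nuc{i + 1}_x_um"] = np.nan
                row[f"nuc{i + 1}_y_um"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_embryos(frame: pd.DataFrame) -> list[EmbryoRecord]:
    """Inverse of :func:`embryos_to_frame`."""
    records = []
    stripe_cols = [c for c in frame.columns if c.startswith("stripe")]
    nuc_x = sorted(
        (c for c in frame.columns if c.startswith("nuc") and c.endswith("_x_um")),
        key=lambda c: int(c.split("_")[0][3:]),
    )
    for _, row in frame.iterrows():
        stripes = row[stripe_cols].to_numpy(dtype=float)
        stripes = stripes[~np.isnan(stripes)]
        nuclei = []
        for cx in nuc_x:
            cy = cx.replace("_x_", "_y_")
            if not np.isnan(row[cx]):
                nuclei.append((row[cx], row[cy]))
        records.append(
            EmbryoRecord(
                embryo_id=str(row["embryo_id"]),
                population=str(row["population"]),
                generation=int(row["generation"]),
                length_um=float(row["length_um"]),
                stripes_um=np.asarray(stripes),
                nuclei_um=np.asarray(nuclei, dtype=float).reshape(-1, 2),
            )
        )
    return records
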