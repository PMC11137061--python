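"""EMS mutation-rate estimation from individually sequenced F1 flies.

Chemically mutagenized males carry new point mutations that appear as
heterozygous singletons when a small cohort of F1 individuals is sequenced.
The estimator separates these from shared standing variation by (1) strict
depth/missingness filtering, (2) pruning of small linkage blocks (correlated
dosages within a short window are background variation, not independent new
mutations), (3) counting private minor alleles with adequate read support,
and (4) normalizing per-individual counts by the bases each individual
covers, yielding a per-Mb rate that extrapolates to the mutation budget of
the founding populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GT_HET, GT_MISSING, GenotypeMatrix

__all__ = [
    "RateEstimate",
    "filter_individual_variants",
    "prune_linked_sites",
    "identify_private_mutations",
    "estimate_rate",
    "extrapolate_total",
    "covered_megabases",
]


def filter_individual_variants(
    matrix: GenotypeMatrix,
    max_missing: int = 2,
    depth_min: int = 4,
    depth_max: int = 50,
) -> GenotypeMatrix:
    """Apply the background-variant filters, in a fixed order.

    1. indel sites are removed;
    2. genotypes with depth outside ``[depth_min, depth_max]`` (inclusive)
       become missing;
    3. sites whose mean depth over the remaining non-missing genotypes falls
       outside the same bounds are removed (as are all-missing sites);
    4. sites missing in more than ``max_missing`` individuals are removed.

    The operation is idempotent: a second application changes nothing.
    """
    if matrix.n_sites == 0 or matrix.n_individuals == 0:
        raise ValueError("cannot filter an empty genotype matrix")

    out = matrix.subset_sites(~matrix.sites["is_indel"].to_numpy(dtype=bool))

    bad_depth = (out.depth < depth_min) | (out.depth > depth_max)
    out.gt[bad_depth] = GT_MISSING

    nonmiss = out.gt != GT_MISSING
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(
            nonmiss.any(axis=1),
            np.where(nonmiss, out.depth, 0).sum(axis=1)
            / np.maximum(nonmiss.sum(axis=1), 1),
            np.nan,
        )
    keep = (mean_depth >= depth_min) & (mean_depth <= depth_max)
    out = out.subset_sites(np.nan_to_num(keep, nan=False).astype(bool))

    n_missing = (out.gt == GT_MISSING).sum(axis=1)
    return out.subset_sites(n_missing <= max_missing)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls."""
    ok = (x != GT_MISSING) & (y != GT_MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def prune_linked_sites(
    matrix: GenotypeMatrix,
    r2_threshold: float = 0.6,
    window_bp: int = 1000,
) -> GenotypeMatrix:
    """Greedy left-to-right linkage pruning within short windows.

    Scanning each chromosome in position order, a site is dropped when its
    dosage vector has squared correlation above ``r2_threshold`` with any
    already-retained site no more than ``window_bp`` upstream.  The first
    site of a chromosome is always retained, and the output is a subset of
    the input.
    """
    keep = np.ones(matrix.n_sites, dtype=bool)
    chrom = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    order = np.lexsort((pos, chrom))
    retained_by_chrom: dict = {}
    for i in order:
        retained = retained_by_chrom.setdefault(chrom[i], [])
        linked = False
        for j in reversed(retained):
            if pos[i] - pos[j] > window_bp:
                break
            if _pairwise_r2(matrix.gt[i], matrix.gt[j]) > r2_threshold:
                linked = True
                break
        if linked:
            keep[i] = False
        else:
            retained.append(i)
    return matrix.subset_sites(keep)


def identify_private_mutations(
    matrix: GenotypeMatrix, min_support: int = 3
) -> np.ndarray:
    """Count private mutations per individual.

    A site is a private mutation of individual *i* when the minor allele
    across all individuals has allele count exactly 1 -- a single
    heterozygote, which may carry either the alternative or the reference as
    the minor allele -- and at least ``min_support`` of *i*'s reads support
    that allele.  Returns an integer count per individual.
    """
    counts = np.zeros(matrix.n_individuals, dtype=np.int64)
    gt = matrix.gt
    for s in range(matrix.n_sites):
        row = gt[s]
        ok = row != GT_MISSING
        n_ok = int(ok.sum())
        if n_ok < 2:
            continue
        alt_count = int(row[ok].sum())
        ref_count = 2 * n_ok - alt_count
        if alt_count == 1:
            support = matrix.alt_reads[s]
        elif ref_count == 1:
            support = matrix.ref_reads[s]
        else:
            continue
        carriers = np.flatnonzero(ok & (row == GT_HET))
        if len(carriers) != 1:
            continue
        i = int(carriers[0])
        if support[i] >= min_support:
            counts[i] += 1
    return counts


@dataclass
class RateEstimate:
    """Per-individual private-mutation rates and their cohort summary."""

    per_individual: pd.DataFrame  # name, mutagenized, count, covered_mb, rate_per_mb
    mean_rate_per_mb: float       # unweighted mean over mutagenized individuals
    mean_count: float             # mean raw count over mutagenized individuals
    mean_count_display: int       # the same, rounded to nearest integer
    background_counts: np.ndarray  # counts in non-mutagenized individuals


def estimate_rate(
    private_counts,
    covered_mb,
    mutagenized_flags,
    names=None,
) -> RateEstimate:
    """Normalize private-mutation counts to per-Mb rates.

    Each individual's rate is ``count / covered Mb``; the summary mean is the
    unweighted mean over mutagenized individuals only.  Non-mutagenized
    individuals are reported as background, never entering the mean.
    """
    counts = np.asarray(private_counts, dtype=float)
    mb = np.asarray(covered_mb, dtype=float)
    mut = np.asarray(mutagenized_flags, dtype=bool)
    if names is None:
        names = [f"ind{i}" for i in range(len(counts))]
    for i, m in enumerate(mb):
        if not m > 0:
            raise ValueError(f"individual {names[i]!r} has zero covered bases")
    rates = counts / mb
    per_individual = pd.DataFrame(
        {
            "name": list(names),
            "mutagenized": mut,
            "count": counts.astype(np.int64),
            "covered_mb": mb,
            "rate_per_mb": rates,
        }
    )
    if not mut.any():
        raise ValueError("no mutagenized individuals to summarize")
    mean_rate = float(rates[mut].mean())
    mean_count = float(counts[mut].mean())
    return RateEstimate(
        per_individual=per_individual,
        mean_rate_per_mb=mean_rate,
        mean_count=mean_count,
        mean_count_display=int(round(mean_count)),
        background_counts=counts[~mut].astype(np.int64),
    )


def extrapolate_total(
    rate_per_mb: float, genome_mb: float, n_individuals: int
) -> int:
    """Total novel mutations introduced: rate x genome size x individuals."""
    if rate_per_mb < 0 or genome_mb < 0 or n_individuals < 0:
        raise ValueError("all arguments must be non-negative")
    return int(round(rate_per_mb * genome_mb * n_individuals))


def covered_megabases(
    per_base_depth: np.ndarray, depth_min: int = 4, depth_max: int = 50
) -> float:
    """Covered Mb from a per-base depth vector, applying the depth filter.

    Helper for when covered bases were not supplied as an input column; the
    usual workflow takes them from a sidecar table computed upstream.
    """
    d = np.asarray(per_base_depth)
    return float(((d >= depth_min) & (d <= depth_max)).sum()) / 1e6
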