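"""Embryo phenomics statistics.

Positions along the anterior-posterior (A-P) axis are reported in percent
egg length (% EL) with the anterior pole at 0%, the convention under which
the first pair-rule stripe of a wild-type blastoderm sits near 28% EL and a
high-morphogen-dosage line near 37% EL.  Generation-wise comparisons use
two-sided Wilcoxon rank-sum tests -- exact while the group sizes allow full
enumeration, tie-corrected normal approximation beyond that -- with
Benjamini-Hochberg adjustment across the seven stripes.  Proportion
comparisons (viability, nucleus-class fractions) share the package's
probability-mass Fisher exact convention.
"""

from __future__ import annotations

from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._fisher import fisher_two_sided
from .containers import EmbryoRecord, ProfileTrace
from .recurrence import fdr_adjust

__all__ = [
    "scale_positions",
    "rank_sum_test",
    "stripe_shift_test",
    "length_summary",
    "internuclei_distances",
    "aggregate_counts",
    "summarize_counts",
    "normalize_posterior_profile",
    "align_profiles",
    "viability_summary",
    "proportion_test",
]

#: exact rank-sum enumeration is used while C(n+m, n) stays at or below this
EXACT_RANKSUM_LIMIT = 10_000


def scale_positions(record: EmbryoRecord) -> np.ndarray:
    """Stripe coordinates rescaled to percent egg length (anterior = 0)."""
    if record.length_um <= 0:
        raise ValueError("length_um must be positive")
    return 100.0 * record.stripes_um / record.length_um


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact while ``C(n+m, n) <= EXACT_RANKSUM_LIMIT`` and the pooled sample is
    tie-free; otherwise the tie-corrected normal approximation (without
    continuity correction, so that it matches the exact enumeration's
    convention in the large-sample limit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = comb(len(x) + len(y), len(x)) <= EXACT_RANKSUM_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def stripe_shift_test(group_a, group_b, alpha: float = 0.05) -> pd.DataFrame:
    """Per-stripe shift tests between two embryo cohorts.

    ``group_a``/``group_b`` are ``(n_embryos, n_stripes)`` arrays of scaled
    positions (% EL).  Each stripe is tested with the two-sided rank-sum
    test; q-values are BH-adjusted across the stripes.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with matching stripe counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 embryos per group")
    rows = []
    for k in range(a.shape[1]):
        xa = a[:, k][~np.isnan(a[:, k])]
        xb = b[:, k][~np.isnan(b[:, k])]
        p = rank_sum_test(xa, xb)
        rows.append((k + 1, len(xa), len(xb), float(xb.mean() - xa.mean()), p))
    out = pd.DataFrame(
        rows, columns=["stripe", "n_a", "n_b", "shift_pct_el", "p"]
    )
    out["q"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def length_summary(
    records: Sequence[EmbryoRecord] | pd.DataFrame,
    group_keys: Sequence[str] = ("generation",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median embryo length per group, plus pairwise generation comparisons.

    Returns ``(medians, tests)``: per-group medians/counts, and two-sided
    rank-sum p-values between every pair of generations (all groups within a
    generation aggregated).
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(
            {
                "population": [r.population for r in records],
                "generation": [r.generation for r in records],
                "length_um": [r.length_um for r in records],
            }
        )
    if frame.empty:
        raise ValueError("no embryo records")
    medians = (
        frame.groupby(list(group_keys))["length_um"]
        .agg(median_um="median", n="size")
        .reset_index()
    )
    gens = sorted(frame["generation"].unique())
    rows = []
    for i, ga in enumerate(gens):
        for gb in gens[i + 1:]:
            xa = frame.loc[frame["generation"] == ga, "length_um"].to_numpy()
            xb = frame.loc[frame["generation"] == gb, "length_um"].to_numpy()
            rows.append((ga, gb, rank_sum_test(xa, xb)))
    tests = pd.DataFrame(rows, columns=["generation_a", "generation_b", "p"])
    return medians, tests


def internuclei_distances(record: EmbryoRecord, trace: bool = False):
    """Euclidean distances between neighboring nuclei along the A-P axis.

    ``D = sqrt((x1 - x2)^2 + (y1 - y2)^2)`` for consecutive nuclei in A-P
    order.  Returns ``(distances, mean)``, or with ``trace=True`` a third
    element: a DataFrame of distance against the downstream nucleus's x.
    """
    nuc = record.nuclei_um
    if nuc.shape[0] < 2:
        raise ValueError("need at least 2 nuclei")
    deltas = np.diff(nuc, axis=0)
    d = np.hypot(deltas[:, 0], deltas[:, 1])
    if trace:
        tr = pd.DataFrame({"x_um": nuc[1:, 0], "distance_um": d})
        return d, float(d.mean()), tr
    return d, float(d.mean())


def aggregate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Average replicated per-embryo counts across experimenters.

    ``counts`` needs columns ``embryo_id`` and ``count`` (an ``experimenter``
    column, when present, is what the averaging collapses); extra grouping
    columns (population, generation, ...) are carried through.
    """
    if counts.empty:
        raise ValueError("no counts")
    carry = [
        c for c in counts.columns if c not in ("count", "experimenter")
    ]
    out = counts.groupby(carry, sort=False)["count"].mean().reset_index()
    return out.rename(columns={"count": "mean_count"})


def summarize_counts(
    per_embryo: pd.DataFrame, group_keys: Sequence[str]
) -> pd.DataFrame:
    """Group mean +/- standard error of per-embryo mean counts."""
    def agg(g: pd.Series) -> pd.Series:
        n = len(g)
        se = g.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series({"mean": g.mean(), "se": se, "n": n})

    return (
        per_embryo.groupby(list(group_keys))["mean_count"]
        .apply(agg)
        .unstack()
        .reset_index()
    )


def normalize_posterior_profile(trace: ProfileTrace) -> ProfileTrace:
    """Peak-normalize a trace and align it at the posterior end.

    Intensities are divided by their maximum (new max = 1); positions are
    re-expressed relative to the posterior end (``position - posterior``,
    zero at the posterior, negative toward the anterior) so that traces from
    embryos of different lengths align at 0.
    """
    peak = trace.intensity.max()
    if peak <= 0:
        raise ValueError("maximum intensity must be positive")
    return ProfileTrace(
        positions_um=trace.positions_um - trace.posterior_um,
        intensity=trace.intensity / peak,
        posterior_um=0.0,
    )


def align_profiles(
    traces: Sequence[ProfileTrace], grid_spacing_um: float = 1.0
) -> pd.DataFrame:
    """Interpolate posterior-aligned traces onto a shared 1 um grid.

    The grid spans the overlap of all traces (distances from the posterior
    where every trace has data); interpolation is linear.  Returns a column
    per trace plus the shared coordinate.
    """
    aligned = [normalize_posterior_profile(t) for t in traces]
    lo = max(t.positions_um[0] for t in aligned)
    hi = min(t.positions_um[-1] for t in aligned)
    if hi < lo:
        raise ValueError("traces share no overlap region")
    grid = np.arange(lo, hi + 1e-9, grid_spacing_um)
    out = {"position_from_posterior_um": grid}
    for i, t in enumerate(aligned):
        out[f"trace{i}"] = np.interp(grid, t.positions_um, t.intensity)
    return pd.DataFrame(out)


def viability_summary(
    records: pd.DataFrame, group_keys: Sequence[str] = ("group",)
) -> pd.DataFrame:
    """Per-group mean eclosion percentage +/- standard error over replicates.

    ``records`` needs columns ``n_embryos`` (plated) and ``n_eclosed`` plus
    the grouping columns.  The standard error is the sample SD of replicate
    proportions over the square root of the replicate count; single-replicate
    groups report no SE.
    """
    if np.any(records["n_eclosed"] > records["n_embryos"]):
        raise ValueError("n_eclosed exceeds n_embryos")
    work = records.assign(
        proportion=records["n_eclosed"] / records["n_embryos"]
    )

    def agg(g: pd.Series) -> pd.Series:
        n = len(g)
        se = g.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series(
            {"mean_pct": 100.0 * g.mean(), "se_pct": 100.0 * se, "n_replicates": n}
        )

    return (
        work.groupby(list(group_keys))["proportion"]
        .apply(agg)
        .unstack()
        .reset_index()
    )


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact comparison of two proportions.

    Tests the 2x2 table ``(k1, n1-k1; k2, n2-k2)`` under the same
    probability-mass convention as the allele-depth recurrence test.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n for both groups")
    return fisher_two_sided(k1, n1 - k1, k2, n2 - k2)
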