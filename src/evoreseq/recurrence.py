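"""Allele-frequency recurrence analysis across parallel populations.

For every biallelic site and every population, the reference/alternative
allele depths at an early and a late generation form a 2x2 table tested with
a two-sided Fisher exact test (probability-mass convention).  P-values are
Benjamini-Hochberg adjusted -- per population by default, mirroring a
per-population test invocation; a global scope is available -- and each
significant site gets a directional call from the raw depth fractions.  The
per-site sign score

    S = N_REF_increase - N_REF_decrease

counts populations with a significant rise minus those with a significant
fall in reference-allele frequency; a large |S| marks recurrent directional
change suggestive of selection (S > 0: the alternative allele tends to be
purged; S < 0: fixed).  Populations where the site is excluded or not
significant contribute nothing to S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._fisher import fisher_two_sided
from .containers import PoolADTable

__all__ = [
    "ADFisherResult",
    "RecurrenceReport",
    "ad_fisher",
    "fdr_adjust",
    "direction_call",
    "sign_score",
    "sign_scores",
    "recurrent_sites",
    "recurrence_percentages",
    "test_generation_pair",
    "recurrence_scan",
]

REF_INCREASE = "REF_increase"
REF_DECREASE = "REF_decrease"
NONE = "none"


@dataclass(frozen=True)
class ADFisherResult:
    """Outcome of one allele-depth Fisher test (p-value or exclusion)."""

    p: float | None
    excluded: bool
    reason: str | None = None


def ad_fisher(
    ref_a: int,
    alt_a: int,
    ref_b: int,
    alt_b: int,
    min_alt: int = 2,
    min_depth: int = 10,
) -> ADFisherResult:
    """Fisher exact test of the allele ratio between two generations.

    The site is excluded when either generation's total depth is below
    ``min_depth``, or when the alternative depth is below ``min_alt`` in both
    generations (an essentially invariant site carries no information).
    """
    if min(ref_a, alt_a, ref_b, alt_b) < 0:
        raise ValueError("allele depths must be non-negative")
    if ref_a + alt_a < min_depth or ref_b + alt_b < min_depth:
        return ADFisherResult(p=None, excluded=True, reason="low_depth")
    if alt_a < min_alt and alt_b < min_alt:
        return ADFisherResult(p=None, excluded=True, reason="low_alt")
    return ADFisherResult(
        p=fisher_two_sided(ref_a, alt_a, ref_b, alt_b), excluded=False
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_call(
    ref_a: int, alt_a: int, ref_b: int, alt_b: int, q: float, alpha: float = 0.05
) -> str:
    """Directional call for a tested site in one population.

    ``REF_increase`` when significant (q < alpha) and the reference fraction
    rose from the earlier to the later generation; ``REF_decrease`` when it
    strictly fell; ``none`` otherwise, including exact ties.
    """
    if q >= alpha:
        return NONE
    frac_a = ref_a / (ref_a + alt_a)
    frac_b = ref_b / (ref_b + alt_b)
    if frac_b > frac_a:
        return REF_INCREASE
    if frac_b < frac_a:
        return REF_DECREASE
    return NONE


def sign_score(calls) -> tuple[int, int, int]:
    """(n_ref_increase, n_ref_decrease, S) from per-population calls."""
    calls = list(calls)
    n_inc = sum(c == REF_INCREASE for c in calls)
    n_dec = sum(c == REF_DECREASE for c in calls)
    return n_inc, n_dec, n_inc - n_dec


def test_generation_pair(
    table: PoolADTable,
    gen_a: int,
    gen_b: int,
    *,
    alpha: float = 0.05,
    min_alt: int = 2,
    min_depth: int = 10,
    fdr_scope: str = "population",
) -> pd.DataFrame:
    """Per-(site, population) Fisher tests between two generations.

    Returns a long table with the 2x2 depths, p, q, exclusion flag/reason and
    the directional call.  Only biallelic sites are tested.  FDR adjustment
    runs within each population (default) or globally across all tests.
    """
    if fdr_scope not in ("population", "global"):
        raise ValueError("fdr_scope must be 'population' or 'global'")
    biallelic = table.sites["biallelic"].to_numpy(dtype=bool)
    site_idx = np.flatnonzero(biallelic)
    populations = sorted(table.samples["population"].unique())
    rows = []
    for pop in populations:
        ia = table.sample_index(pop, gen_a)
        ib = table.sample_index(pop, gen_b)
        ra = table.ref_depth[site_idx, ia]
        aa = table.alt_depth[site_idx, ia]
        rb = table.ref_depth[site_idx, ib]
        ab = table.alt_depth[site_idx, ib]
        for k, s in enumerate(site_idx):
            res = ad_fisher(
                ra[k], aa[k], rb[k], ab[k], min_alt=min_alt, min_depth=min_depth
            )
            rows.append(
                (
                    int(s), pop, int(ra[k]), int(aa[k]), int(rb[k]), int(ab[k]),
                    res.p, res.excluded, res.reason,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "site", "population", "ref_a", "alt_a", "ref_b", "alt_b",
            "p", "excluded", "reason",
        ],
    )
    out["q"] = np.nan
    tested = ~out["excluded"]
    if fdr_scope == "population":
        for pop in populations:
            sel = tested & (out["population"] == pop)
            if sel.any():
                out.loc[sel, "q"] = fdr_adjust(out.loc[sel, "p"].to_numpy())
    else:
        if tested.any():
            out.loc[tested, "q"] = fdr_adjust(out.loc[tested, "p"].to_numpy())
    # vectorized equivalent of direction_call over all tested rows
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = out["ref_a"] / (out["ref_a"] + out["alt_a"])
        frac_b = out["ref_b"] / (out["ref_b"] + out["alt_b"])
    significant = tested.to_numpy() & (out["q"].to_numpy() < alpha)
    calls = np.full(len(out), NONE, dtype=object)
    calls[significant & (frac_b > frac_a).to_numpy()] = REF_INCREASE
    calls[significant & (frac_b < frac_a).to_numpy()] = REF_DECREASE
    out["direction"] = calls
    return out


def sign_scores(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-population calls into per-site sign-score records.

    A population counts as significant for a site when it received a
    directional call (q < alpha with a strict change in reference fraction;
    a significant Fisher p with exactly equal fractions cannot occur for
    2x2 tables, so the two notions coincide).  Excluded populations
    contribute an implicit ``none``.
    """

    work = pd.DataFrame(
        {
            "site": results["site"],
            "inc": (results["direction"] == REF_INCREASE).astype(np.int64),
            "dec": (results["direction"] == REF_DECREASE).astype(np.int64),
        }
    )
    grouped = work.groupby("site", sort=True).sum()
    out = pd.DataFrame(
        {
            "site": grouped.index.to_numpy(),
            "n_ref_increase": grouped["inc"].to_numpy(),
            "n_ref_decrease": grouped["dec"].to_numpy(),
        }
    )
    out["n_significant"] = out["n_ref_increase"] + out["n_ref_decrease"]
    out["S"] = out["n_ref_increase"] - out["n_ref_decrease"]
    return out


def recurrence_percentages(
    n_tested: int, n_significant: int, n_recurrent: int, n_flagged: int
) -> dict:
    """Bookkeeping percentages of a recurrence report (nearest integer)."""
    def pct(num: int, den: int) -> int:
        return int(round(100.0 * num / den)) if den else 0

    return {
        "pct_significant": pct(n_significant, n_tested),
        "pct_recurrent": pct(n_recurrent, n_tested),
        "pct_flagged_of_recurrent": pct(n_flagged, n_recurrent),
    }


@dataclass
class RecurrenceReport:
    """Summary of the sign-score scan.

    ``significant`` sites changed significantly in at least one population;
    ``recurrent`` sites in at least two; ``flagged`` sites have |S| strictly
    above the cutoff.  Percentages are nearest-integer: significant and
    recurrent relative to tested sites, flagged relative to recurrent sites.
    """

    n_tested: int
    n_significant: int
    n_recurrent: int
    n_flagged: int
    pct_significant: int
    pct_recurrent: int
    pct_flagged_of_recurrent: int
    mean_s_recurrent: float
    significant_sites: np.ndarray
    recurrent_sites: np.ndarray
    flagged_sites: np.ndarray


def recurrent_sites(
    scores: pd.DataFrame, cutoff: int = 5, n_tested: int | None = None
) -> RecurrenceReport:
    """Build the recurrence report from sign-score records.

    The |S| cutoff is strict (``|S| > cutoff``).  ``n_tested`` defaults to
    the number of score records.
    """
    if n_tested is None:
        n_tested = len(scores)
    sig = scores.loc[scores["n_significant"] >= 1, "site"].to_numpy()
    rec_mask = scores["n_significant"] >= 2
    rec = scores.loc[rec_mask, "site"].to_numpy()
    flag_mask = scores["S"].abs() > cutoff
    flagged = scores.loc[flag_mask, "site"].to_numpy()
    pcts = recurrence_percentages(n_tested, len(sig), len(rec), len(flagged))
    mean_s = float(scores.loc[rec_mask, "S"].mean()) if rec_mask.any() else 0.0
    return RecurrenceReport(
        n_tested=int(n_tested),
        n_significant=len(sig),
        n_recurrent=len(rec),
        n_flagged=len(flagged),
        mean_s_recurrent=mean_s,
        significant_sites=sig,
        recurrent_sites=rec,
        flagged_sites=flagged,
        **pcts,
    )


def recurrence_scan(
    table: PoolADTable,
    gen_a: int,
    gen_b: int,
    *,
    alpha: float = 0.05,
    min_alt: int = 2,
    min_depth: int = 10,
    fdr_scope: str = "population",
    cutoff: int = 5,
):
    """End-to-end scan: per-population tests, sign scores, report."""
    results = test_generation_pair(
        table, gen_a, gen_b,
        alpha=alpha, min_alt=min_alt, min_depth=min_depth, fdr_scope=fdr_scope,
    )
    scores = sign_scores(results)
    n_tested = int(table.sites["biallelic"].sum())
    report = recurrent_sites(scores, cutoff=cutoff, n_tested=n_tested)
    return results, scores, report
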