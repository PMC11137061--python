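"""Genotype-phenotype association between pooled genotype calls and embryo size.

Shallow pooled sequencing does not support per-fly genotypes, so each pooled
library gets a diploid-style call from its allele-depth fraction (hom-ref /
het / hom-alt), and the phenotype of a sequenced generation g is the mean
embryo length of generation g + 1 (the offspring the sequenced parents
produced).  Per site, an ordinary least-squares model estimates the genotype
effect on mean length; with all three genotype classes present, both an
additive-dosage coding and a two-contrast categorical coding are fitted and
the smaller coefficient p-value is reported.  The scan is a prioritization
aid, not a powered mapping study: no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    PoolADTable,
)

__all__ = [
    "AssocResult",
    "PopGenotypeTable",
    "call_pool_genotype",
    "build_genotype_table",
    "associate",
    "associate_table",
]


def call_pool_genotype(
    ref_depth: int,
    alt_depth: int,
    het_band: tuple[float, float] = (0.1, 0.9),
) -> int:
    """Diploid-style genotype call for a pooled sample from its AD fraction.

    Alt fraction below ``het_band[0]`` gives hom-ref, above ``het_band[1]``
    hom-alt, anything in the closed band a het; zero total depth is missing.
    The band bounds themselves call het (low inclusive).
    """
    total = ref_depth + alt_depth
    if total <= 0:
        return GT_MISSING
    frac = alt_depth / total
    low, high = het_band
    if frac < low:
        return GT_HOM_REF
    if frac > high:
        return GT_HOM_ALT
    return GT_HET


@dataclass
class PopGenotypeTable:
    """Per-(population, generation) genotype calls for tested sites.

    Only sites with mean depth across samples at or above the configured
    minimum are retained.  ``calls`` is ``(n_sites, n_samples)`` with the
    shared genotype codes; ``mean_depth`` is per retained site.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray
    mean_depth: np.ndarray


def build_genotype_table(
    table: PoolADTable,
    min_mean_depth: float = 10.0,
    het_band: tuple[float, float] = (0.1, 0.9),
) -> PopGenotypeTable:
    """Call pooled genotypes and apply the mean-depth site filter."""
    total = table.ref_depth + table.alt_depth
    mean_depth = total.mean(axis=1)
    keep = mean_depth >= min_mean_depth
    ref = table.ref_depth[keep]
    alt = table.alt_depth[keep]
    tot = total[keep]
    low, high = het_band
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    calls = np.full(ref.shape, GT_HET, dtype=np.int8)
    calls[frac < low] = GT_HOM_REF
    calls[frac > high] = GT_HOM_ALT
    calls[tot == 0] = GT_MISSING
    sites = (
        table.sites.loc[keep]
        .reset_index(drop=False)
        .rename(columns={"index": "site_index"})
    )
    return PopGenotypeTable(
        sites=sites,
        samples=table.samples.copy(),
        calls=calls,
        mean_depth=mean_depth[keep],
    )


@dataclass
class AssocResult:
    """Effect estimate for one site (um per coding unit)."""

    effect: float | None
    p: float | None
    coding: str | None  # 'additive' | 'categorical'
    n: int
    testable: bool
    reason: str | None = None


def _fit_additive(dosage: np.ndarray, y: np.ndarray):
    x = sm.add_constant(dosage.astype(float))
    fit = sm.OLS(y, x).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def _fit_categorical(dosage: np.ndarray, y: np.ndarray):
    levels = np.unique(dosage)
    dummies = np.column_stack(
        [(dosage == lvl).astype(float) for lvl in levels[1:]]
    )
    x = sm.add_constant(dummies)
    fit = sm.OLS(y, x).fit()
    pvals = fit.pvalues[1:]
    k = int(np.argmin(pvals))
    return float(fit.params[1 + k]), float(pvals[k])


def associate(genotypes, phenotypes, coding: str = "both") -> AssocResult:
    """OLS association of one site's genotype calls with the phenotype.

    With two genotype classes: simple regression of phenotype on allele
    dosage, reporting the slope and its two-sided t-test p.  With three
    classes and ``coding='both'``: the additive-dosage and categorical
    (two-contrast) models are both fitted and the smaller coefficient
    p-value wins, with the winning coding recorded.  Fewer than three
    complete samples or a constant genotype is not testable.
    """
    if coding not in ("both", "additive", "categorical"):
        raise ValueError("coding must be 'both', 'additive' or 'categorical'")
    g = np.asarray(genotypes)
    y = np.asarray(phenotypes, dtype=float)
    ok = (g != GT_MISSING) & ~np.isnan(y)
    g = g[ok].astype(float)
    y = y[ok]
    n = len(g)
    if n < 3:
        return AssocResult(None, None, None, n, False, "fewer than 3 samples")
    if len(np.unique(g)) < 2:
        return AssocResult(None, None, None, n, False, "constant genotype")

    n_classes = len(np.unique(g))
    fits = []
    if coding in ("both", "additive") or n_classes == 2:
        fits.append(("additive", *_fit_additive(g, y)))
    if n_classes >= 3 and coding in ("both", "categorical"):
        fits.append(("categorical", *_fit_categorical(g, y)))
    name, effect, p = min(fits, key=lambda t: t[2])
    return AssocResult(effect=effect, p=p, coding=name, n=n, testable=True)


def associate_table(
    gtable: PopGenotypeTable,
    phenotypes: pd.DataFrame,
    pairing: dict,
    coding: str = "both",
) -> pd.DataFrame:
    """Associate every retained site with offspring mean embryo length.

    ``phenotypes`` needs columns ``population``, ``generation``,
    ``mean_length_um``; ``pairing`` maps each sequenced generation to the
    embryo generation whose mean length serves as its phenotype
    (e.g. ``{3: 4, 7: 8}``).  Samples whose paired phenotype is absent are
    dropped from every site's model.
    """
    pheno_lookup = {
        (row["population"], row["generation"]): row["mean_length_um"]
        for _, row in phenotypes.iterrows()
    }
    y = np.full(len(gtable.samples), np.nan)
    for i, row in gtable.samples.reset_index(drop=True).iterrows():
        target = pairing.get(row["generation"])
        if target is not None:
            y[i] = pheno_lookup.get((row["population"], target), np.nan)
    has_orig = "site_index" in gtable.sites.columns
    rows = []
    for s in range(gtable.calls.shape[0]):
        res = associate(gtable.calls[s], y, coding=coding)
        rows.append(
            (
                int(gtable.sites.at[s, "site_index"]) if has_orig else s,
                gtable.sites.at[s, "chrom"],
                gtable.sites.at[s, "pos"],
                res.effect,
                res.p,
                res.coding,
                res.n,
                res.testable,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site", "chrom", "pos", "effect_um", "p", "coding", "n", "testable",
        ],
    )
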