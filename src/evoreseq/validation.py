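"""Self-contained validation experiments run on the package's own generator.

Each function builds a synthetic dataset whose ground truth is known by
construction, runs the corresponding analysis end to end, and returns the
measured quantities.  The experiments double as acceptance checks and as
worked examples of how the modules compose; problem sizes are chosen so the
whole battery runs in a few minutes on one CPU (the methods note discusses
the choices).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import mutrate as mutrate_mod
from . import pheno as pheno_mod
from . import recurrence as recurrence_mod
from . import simgen

__all__ = [
    "ems_rate_recovery",
    "neutral_recurrence",
    "selection_recurrence",
    "assoc_recovery",
    "stripe_shift_power",
    "length_median_recovery",
]

_MOD = 2**31


def _seed(base: int, k: int) -> int:
    return (base + 7919 * k) % _MOD


def ems_rate_recovery(seed: int, *, true_rate: float = 3.0) -> dict:
    """Recover an injected EMS rate from individually sequenced founders.

    Twenty mutagenized founders over a 20 Mb genome at deep uniform
    coverage, against a background of 500 intermediate-frequency standing
    variants; the full filter -> prune -> private-count -> normalize chain
    runs as it would on real calls.
    """
    config = simgen.SimConfig(
        genome_size_mb=20.0,
        n_sites_standing=500,
        ems_rate_per_mb=true_rate,
        n_founders=20,
        n_populations=1,
        seed=_seed(seed, 1),
    )
    founders = simgen.simulate_founders(config)
    matrix = simgen.founders_to_genotype_matrix(founders, mean_depth=30.0)
    filtered = mutrate_mod.filter_individual_variants(matrix)
    pruned = mutrate_mod.prune_linked_sites(filtered)
    counts = mutrate_mod.identify_private_mutations(pruned)
    est = mutrate_mod.estimate_rate(
        counts,
        pruned.individuals["covered_bases"].to_numpy() / 1e6,
        pruned.individuals["mutagenized"].to_numpy(),
    )
    return {
        "true_rate_per_mb": true_rate,
        "estimated_rate_per_mb": est.mean_rate_per_mb,
        "relative_error": abs(est.mean_rate_per_mb - true_rate) / true_rate,
        "n_individuals": config.n_founders,
    }


def _scan_config(seed: int, n_sites: int, mean_depth: float, dispersion: float):
    return simgen.SimConfig(
        genome_size_mb=180.0,
        n_sites_standing=n_sites,
        ems_rate_per_mb=0.0,
        n_founders=200,
        n_populations=18,
        pop_size=300,
        n_generations=7,
        mean_depth=mean_depth,
        depth_dispersion=dispersion,
        seed=seed,
    )


def neutral_recurrence(seed: int, *, n_sites: int = 20_000) -> dict:
    """Sign-score scan of a fully neutral 18-population experiment.

    With every s = 0, recurrent directional change is sampling noise only;
    the fraction of recurrent sites reaching |S| > 5 should be essentially
    zero.  Run at the study's shallow coverage (mean 29, overdispersed).
    """
    config = _scan_config(_seed(seed, 2), n_sites, 29.0, 1.0)
    founders = simgen.simulate_founders(config)
    traj = simgen.evolve_all(founders, config)
    table = simgen.sample_pool_generations(traj, config, (3, 7))
    _, scores, report = recurrence_mod.recurrence_scan(table, 3, 7)
    frac = (
        report.n_flagged / report.n_recurrent if report.n_recurrent else 0.0
    )
    return {
        "n_tested": report.n_tested,
        "n_significant": report.n_significant,
        "n_recurrent": report.n_recurrent,
        "n_flagged": report.n_flagged,
        "flagged_fraction_of_recurrent": frac,
        "max_abs_s": int(scores["S"].abs().max()) if len(scores) else 0,
    }


def selection_recurrence(
    seed: int, *, n_sites: int = 20_000, n_selected: int = 10, s: float = 0.25
) -> dict:
    """Parallel selection against a neutral background.

    Ten standing sites at intermediate founder frequency get s = 0.25 in all
    18 populations; pools are sequenced deep (mean 300) because a
    four-generation shift of this size is invisible to per-population Fisher
    tests at shallow coverage.  Selected sites should land above the 99th
    percentile of the neutral |S| distribution.
    """
    config = _scan_config(_seed(seed, 3), n_sites, 300.0, 0.2)
    founders = simgen.simulate_founders(config)
    freqs = founders.frequencies()
    candidates = np.flatnonzero((freqs >= 0.4) & (freqs <= 0.6))[:n_selected]
    config = config.replace(
        selected_sites=tuple((int(i), s) for i in candidates)
    )
    traj = simgen.evolve_all(founders, config)
    table = simgen.sample_pool_generations(traj, config, (3, 7))
    _, scores, _ = recurrence_mod.recurrence_scan(table, 3, 7)
    abs_s = scores.set_index("site")["S"].abs()
    selected = set(int(i) for i in candidates)
    neutral_abs = abs_s[~abs_s.index.isin(selected)].to_numpy()
    selected_abs = abs_s[abs_s.index.isin(selected)].to_numpy()
    q99 = float(np.quantile(neutral_abs, 0.99))
    return {
        "selected_abs_s": selected_abs.tolist(),
        "neutral_q99_abs_s": q99,
        "n_selected_above_q99": int((selected_abs > q99).sum()),
        "n_selected": len(selected_abs),
    }


def assoc_recovery(seed: int, *, n_reps: int = 20, effect_um: float = 12.0) -> dict:
    """Rank of a single true effect site among neutral sites.

    Per replicate: 500 neutral standing sites plus one site with a 12 um per
    allele-copy effect on embryo length, across 18 parallel populations.
    Bottle transfers are modelled with a small effective size (5 diploids)
    and genotypes are taken at generation 15, when drift has carried most
    pools near fixation or loss -- the regime where the three-class pooled
    genotype call is informative (intermediate pools all collapse onto
    'het' and carry almost no contrast).  One sample per population keeps
    the tests free of the pseudoreplication that repeated sampling of the
    same drifting lineage would introduce.  The phenotype is the mean
    length of 100 generation-16 embryos.  Success = the effect site attains
    the smallest association p-value of all testable sites.
    """
    gen = 15
    wins = 0
    details = []
    for rep in range(n_reps):
        config = simgen.SimConfig(
            genome_size_mb=180.0,
            n_sites_standing=501,
            ems_rate_per_mb=0.0,
            n_founders=200,
            n_populations=18,
            pop_size=5,
            n_generations=gen + 1,
            mean_depth=29.0,
            depth_dispersion=1.0,
            pheno_noise_sd_um=15.0,
            seed=_seed(seed, 100 + rep),
        )
        founders = simgen.simulate_founders(config)
        freqs = founders.frequencies()
        effect_site = int(np.argmin(np.abs(freqs - 0.5)))
        config = config.replace(pheno_effects=((effect_site, effect_um),))
        traj = simgen.evolve_all(founders, config)
        table = simgen.sample_pool_reads(traj, config, gen)
        gtable = assoc_mod.build_genotype_table(table)
        pheno_rows = [
            (r.population, r.generation, r.length_um)
            for r in simgen.simulate_phenotypes(traj, config, gen + 1, 100)
        ]
        pheno = (
            pd.DataFrame(pheno_rows, columns=["population", "generation", "length_um"])
            .groupby(["population", "generation"])["length_um"]
            .mean()
            .reset_index()
            .rename(columns={"length_um": "mean_length_um"})
        )
        results = assoc_mod.associate_table(gtable, pheno, {gen: gen + 1})
        testable = results.loc[results["testable"]]
        if testable.empty:
            details.append(None)
            continue
        win = int(testable.loc[testable["p"].idxmin(), "site"]) == effect_site
        wins += win
        details.append(bool(win))
    return {
        "n_reps": n_reps,
        "n_wins": wins,
        "win_fraction": wins / n_reps,
        "per_rep": details,
    }


def stripe_shift_power(
    seed: int,
    *,
    n_reps: int = 20,
    shift_um: float = 17.0,
    n_a: int = 60,
    n_b: int = 217,
) -> dict:
    """Power to detect the observed between-generation stripe shift.

    Group A embryos at the 550 um baseline, group B at baseline + 17 um
    (the observed median increase); the length-position coupling turns the
    size change into a ~1.1% EL anterior stripe shift.  Success = stripe 1
    significant at q < 0.01 in the rank-sum/FDR test at the study's sample
    sizes (60 vs 217 embryos).
    """
    detections = 0
    shifts = []
    for rep in range(n_reps):
        base = simgen.SimConfig(
            n_sites_standing=1,
            ems_rate_per_mb=0.0,
            n_founders=10,
            n_populations=1,
            n_generations=1,
            seed=_seed(seed, 200 + rep),
        )
        shifted = base.replace(
            pheno_baseline_um=base.pheno_baseline_um + shift_um,
            seed=_seed(seed, 500 + rep),
        )
        f_a = simgen.simulate_founders(base)
        f_b = simgen.simulate_founders(shifted)
        t_a = simgen.evolve_all(f_a, base)
        t_b = simgen.evolve_all(f_b, shifted)
        emb_a = simgen.simulate_phenotypes(t_a, base, 1, n_a)
        emb_b = simgen.simulate_phenotypes(t_b, shifted, 1, n_b)
        a = np.vstack([pheno_mod.scale_positions(r) for r in emb_a])
        b = np.vstack([pheno_mod.scale_positions(r) for r in emb_b])
        table = pheno_mod.stripe_shift_test(a, b)
        stripe1 = table.loc[table["stripe"] == 1].iloc[0]
        detections += bool(stripe1["q"] < 0.01)
        shifts.append(float(stripe1["shift_pct_el"]))
    return {
        "n_reps": n_reps,
        "n_detected": detections,
        "detection_fraction": detections / n_reps,
        "mean_stripe1_shift_pct_el": float(np.mean(shifts)),
    }


def length_median_recovery(seed: int, *, n_embryos: int = 200) -> dict:
    """Round-trip of the 550 -> 567 um median-length regime."""
    medians = {}
    for label, baseline in (("gen4", 550.0), ("gen8", 567.0)):
        config = simgen.SimConfig(
            n_sites_standing=1,
            ems_rate_per_mb=0.0,
            n_founders=10,
            n_populations=1,
            n_generations=1,
            pheno_baseline_um=baseline,
            seed=_seed(seed, 300) if label == "gen4" else _seed(seed, 301),
        )
        founders = simgen.simulate_founders(config)
        traj = simgen.evolve_all(founders, config)
        emb = simgen.simulate_phenotypes(traj, config, 1, n_embryos)
        medians[label] = float(np.median([r.length_um for r in emb]))
    return medians
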