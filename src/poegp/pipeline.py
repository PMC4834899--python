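"""Experiment plumbing: filtering, cross-validation, metrics, grid runner.

``run_grid`` reproduces the simulation comparison between the additive
(ADD) and parent-of-origin (POE) whole-genome prediction models: for each
replicate one base population is simulated, the imprinting overlay is
applied for every (rho, s) scenario reusing the same environmental
deviations, each requested model is trained on the second recent generation
with the third generation's phenotypes masked, and Pearson/Spearman
correlations and mean squared error are recorded on both sets.  At rho = 1
all values of s give identical phenotypes, so only one scenario is run and
its rows carry s = NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes, imprint, kinship, poescan, popsim
from .genotypes import OrderedGenotypes

__all__ = [
    "CvPlan", "MetricReport", "maf_filter", "split_within_family", "evaluate",
    "scaled_sim_config", "scaled_mcmc_config", "run_grid",
    "poe_superiority",
]


@dataclass
class CvPlan:
    train_ids: np.ndarray
    test_ids: np.ndarray
    replicate: int = 0
    scheme: str = "within_family"


@dataclass
class MetricReport:
    pearson: float
    spearman: float
    mse: float
    n: int
    degenerate: bool = False


def maf_filter(genotypes: OrderedGenotypes, threshold: float = 0.05):
    """Remove markers with minor allele frequency strictly below the threshold.

    Returns the filtered genotypes and the number of retained markers.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    freq = genotypes.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= threshold
    if not keep.any():
        raise ValueError("no markers remain after MAF filtering")
    return genotypes.subset_markers(keep), int(keep.sum())


def split_within_family(pedigree: pd.DataFrame, test_fraction: float,
                        rng: np.random.Generator,
                        replicate: int = 0) -> CvPlan:
    """Assign a fraction of each full-sib family to the test set.

    Families are full-sib groups (same sire and dam, both known); singleton
    families and individuals with unknown parents go to the training set.
    Every multi-member family contributes at least one member to each set;
    a request that would empty a family's training side raises.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    train, test = [], []
    known = pedigree[(pedigree["sire"] != 0) & (pedigree["dam"] != 0)]
    train.extend(pedigree.loc[(pedigree["sire"] == 0) | (pedigree["dam"] == 0),
                              "id"].tolist())
    for (_, _), fam in known.groupby(["sire", "dam"]):
        members = fam["id"].to_numpy()
        size = len(members)
        if size == 1:
            train.extend(members.tolist())
            continue
        n_test = max(1, int(np.floor(test_fraction * size + 0.5)))
        if n_test >= size:
            raise ValueError(
                f"test_fraction {test_fraction} would empty the training side "
                f"of a family of size {size}")
        perm = rng.permutation(members)
        test.extend(perm[:n_test].tolist())
        train.extend(perm[n_test:].tolist())
    return CvPlan(train_ids=np.array(train), test_ids=np.array(test),
                  replicate=replicate, scheme="within_family")


def evaluate(observed: np.ndarray, predicted: np.ndarray) -> MetricReport:
    """Pearson and Spearman correlation plus mean squared error."""
    observed = np.asarray(observed, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(observed)
    if n < 3:
        raise ValueError("need at least 3 pairs to evaluate")
    mse = float(np.mean((observed - predicted) ** 2))
    if np.std(observed) == 0 or np.std(predicted) == 0:
        warnings.warn("zero-variance vector: correlations undefined", stacklevel=2)
        return MetricReport(np.nan, np.nan, mse, n, degenerate=True)
    pear = float(stats.pearsonr(observed, predicted).statistic)
    spear = float(stats.spearmanr(observed, predicted).statistic)
    return MetricReport(pear, spear, mse, n)


# ---------------------------------------------------------------------------
# simulation-grid experiment
# ---------------------------------------------------------------------------

def scaled_sim_config(seed: int = 0) -> popsim.SimConfig:
    """Desk-scale simulation profile: 3 chromosomes x 300 SNPs, 45 QTL,
    recent generations of 1000 (500 train / 500 test after splitting by
    generation is not needed: generation 2 trains, generation 3 tests)."""
    return popsim.SimConfig(n_chrom=3, snps_per_chrom=300, n_qtl=45,
                            recent_size=500, seed=seed)


def scaled_mcmc_config(seed: int = 0) -> bayes.McmcConfig:
    """Desk-scale MCMC schedule: 15,000 iterations, 3,000 burn-in, thin 10."""
    return bayes.McmcConfig(iterations=15_000, burn_in=3_000, thin=10, seed=seed)


def _distinct_scenarios(rhos: Sequence[float], s_values: Sequence[float]):
    """(rho, s) pairs with the redundant rho = 1 rows collapsed to one."""
    out = []
    for rho in rhos:
        if rho == 1.0:
            out.append((1.0, None))
        else:
            out.extend((rho, s) for s in s_values)
    seen, uniq = set(), []
    for sc in out:
        if sc not in seen:
            seen.add(sc)
            uniq.append(sc)
    return uniq


def run_grid(rhos: Sequence[float],
             s_values: Sequence[float],
             n_replicates: int = 3,
             models: Sequence[str] = ("ADD", "POE"),
             sim_config: Optional[popsim.SimConfig] = None,
             mcmc: Optional[bayes.McmcConfig] = None,
             h2: float = 0.5,
             sigma2_qtl: float = 1.0,
             include_polygenic: bool = True,
             include_gametic: bool = True,
             train_generation: int = 2,
             test_generation: int = 3,
             seed: int = 0,
             phi_from_scan: bool = False,
             scan_alpha: float = 0.05,
             verbose: bool = False) -> pd.DataFrame:
    """Run the (rho, s) scenario grid and return a tidy results table.

    One base population is simulated per replicate; every scenario reuses
    its QTL effects and environmental deviations, so within a replicate the
    phenotype differences between scenarios are purely genetic.  Returned
    columns: replicate, rho, s, model, dataset (train/test), pearson,
    spearman, mse, n.  ADD_POE models derive Phi from the Sidak-corrected
    scan on the training generation when ``phi_from_scan`` is set.
    """
    sim_config = sim_config if sim_config is not None else scaled_sim_config()
    mcmc = mcmc if mcmc is not None else scaled_mcmc_config()
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_replicates)
    scenarios = _distinct_scenarios(rhos, s_values)
    rows = []
    for rep in range(n_replicates):
        ss = rep_seeds[rep]
        s_sim, s_eff, s_part, s_mcmc = ss.spawn(4)
        cfg = replace(sim_config, seed=int(s_sim.generate_state(1)[0] % 2**31))
        pop = popsim.simulate_population(cfg)
        data = popsim.export_dataset(pop, pop.generations_present())
        gen = data.pedigree.set_index("id").loc[data.genotypes.ids, "generation"].to_numpy()
        train_mask = gen == train_generation
        test_mask = gen == test_generation
        fit_mask = train_mask | test_mask
        geno_fit = data.genotypes.subset_individuals(fit_mask)
        rel = None
        if include_polygenic or include_gametic:
            rel = kinship.relationship_matrices(
                kinship.Pedigree.from_frame(data.pedigree))
        effects = imprint.draw_qtl_effects(
            data.qtl_ids, data.qtl_maternal, data.qtl_paternal,
            data.genotypes.ids, np.random.default_rng(s_eff),
            sigma2_qtl=sigma2_qtl, h2=h2)
        part_rng = np.random.default_rng(s_part)
        mcmc_seeds = s_mcmc.generate_state(len(scenarios) * len(models) * 2)
        si = 0
        # assemble phi-free models once per replicate; kernels and their
        # eigendecompositions are then shared across scenarios
        spec_cache = {}
        for model_name in models:
            kind = model_name.upper().replace("-", "_")
            if kind != "ADD_POE":
                spec_cache[kind] = bayes.assemble_model(
                    kind, geno_fit, kinship=rel,
                    include_polygenic=include_polygenic,
                    include_gametic=include_gametic and kind != "ADD")
        for rho, s in scenarios:
            s_eff_val = s if s is not None else s_values[0]
            scenario = imprint.assign_imprint_status(
                data.qtl_ids, s_eff_val, rho, part_rng)
            pheno = imprint.simulate_phenotypes(
                data.qtl_maternal, data.qtl_paternal, effects, scenario)
            y = pheno.phenotype[fit_mask]
            obs = train_mask[fit_mask]
            phi = None
            if any(m.upper().replace("-", "_") == "ADD_POE" for m in models):
                if phi_from_scan:
                    tr = train_mask[fit_mask]
                    scan = poescan.scan_poe(y[tr], geno_fit.subset_individuals(tr))
                    thr = poescan.sidak_threshold(scan_alpha, geno_fit.n_markers)
                    phi = poescan.select_phi(scan, thr)
                else:
                    phi = []
            for model_name in models:
                kind = model_name.upper().replace("-", "_")
                if kind in spec_cache:
                    spec = spec_cache[kind]
                else:
                    spec = bayes.assemble_model(
                        kind, geno_fit, kinship=rel, phi=phi,
                        include_polygenic=include_polygenic,
                        include_gametic=include_gametic and kind != "ADD")
                priors = bayes.default_priors(y, spec, mask_observed=obs)
                fit_mcmc = replace(mcmc, seed=int(mcmc_seeds[si] % 2**31))
                si += 1
                if verbose:
                    print(f"rep {rep} rho={rho} s={s} {kind}", flush=True)
                fit = bayes.run_gibbs(spec, priors, fit_mcmc, y,
                                      mask_observed=obs,
                                      keep_effect_samples=False)
                yhat = fit.linpred_mean
                for name, mask in (("train", obs), ("test", ~obs)):
                    rep_metrics = evaluate(pheno.phenotype[fit_mask][mask], yhat[mask])
                    rows.append(dict(replicate=rep, rho=rho,
                                     s=np.nan if s is None else s,
                                     model=kind, dataset=name,
                                     pearson=rep_metrics.pearson,
                                     spearman=rep_metrics.spearman,
                                     mse=rep_metrics.mse, n=rep_metrics.n))
    return pd.DataFrame(rows)


def poe_superiority(grid: pd.DataFrame, dataset: str = "test",
                    better: str = "POE", baseline: str = "ADD") -> pd.DataFrame:
    """Relative superiority of one model over another per scenario.

    Metrics are first averaged over replicates; correlations are compared as
    ``100 * (m_better - m_baseline) / m_baseline`` and MSE as
    ``100 * (mse_baseline - mse_better) / mse_baseline`` so that positive
    numbers always favour ``better``.
    """
    d = grid[grid["dataset"] == dataset]
    avg = (d.groupby(["rho", "s", "model"], dropna=False)
           [["pearson", "spearman", "mse"]].mean().reset_index())
    out = []
    for (rho, s), g in avg.groupby(["rho", "s"], dropna=False):
        a = g[g["model"] == baseline]
        p = g[g["model"] == better]
        if a.empty or p.empty:
            continue
        a, p = a.iloc[0], p.iloc[0]
        out.append(dict(
            rho=rho, s=s,
            pearson_gain_pct=100.0 * (p["pearson"] - a["pearson"]) / a["pearson"],
            spearman_gain_pct=100.0 * (p["spearman"] - a["spearman"]) / a["spearman"],
            mse_gain_pct=100.0 * (a["mse"] - p["mse"]) / a["mse"],
        ))
    return pd.DataFrame(out)
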