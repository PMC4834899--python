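"""Imprinting phenotype overlay and one-locus variance decompositions.

Parent-of-origin effects are generated by partially or completely silencing
one parental allele at a random subset of QTL.  Each QTL ``j`` carries two
allele effects ``theta_j1, theta_j2 ~ N(0, sigma2_qtl)``.  Writing
``theta_m`` / ``theta_p`` for the effect of the maternally / paternally
inherited allele of an individual, the genotypic contribution of QTL j is

* ``theta_m + theta_p``             for a non-imprinted QTL (set NI),
* ``rho * theta_m + theta_p``       for a maternally imprinted QTL (MI),
* ``theta_m + rho * theta_p``       for a paternally imprinted QTL (PI),

where ``rho`` in [0, 1] is the expression level of the silenced allele:
``rho = 0`` is complete imprinting, ``rho = 1`` none.  A fraction ``s`` of
QTL is imprinted, maternally or paternally with equal frequency.  Phenotype
is the summed genotypic value plus an environmental deviation
``eps ~ N(0, sigma2_eps)`` that is drawn once per base population and reused
across all (rho, s) scenarios, so scenario-to-scenario phenotype differences
are purely genetic.

For a single imprinted locus with allele frequencies (p, q) under
Hardy-Weinberg equilibrium, the four ordered genotypes (maternal allele
written first) have values ``G_11 = rho*theta_1 + theta_1``,
``G_21 = rho*theta_2 + theta_1``, ``G_12 = rho*theta_1 + theta_2``,
``G_22 = rho*theta_2 + theta_2`` (as deviations from the mean), giving a
genetic variance ``(1 + rho^2) p q (theta_1 - theta_2)^2`` and a
parent-of-origin variance ``0.5 p q (theta_1 - theta_2)^2 (1 - rho)^2``; at
``rho = 1`` the former reduces to the classical ``2 p q alpha^2`` and the
latter vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QTLEffectSet",
    "ImprintScenario",
    "PhenotypeTable",
    "draw_qtl_effects",
    "assign_imprint_status",
    "genotypic_value",
    "simulate_phenotypes",
    "locus_genetic_variance",
    "locus_poe_variance",
]


@dataclass
class QTLEffectSet:
    """Allele effects of all QTL plus the environmental layer of one base population.

    ``theta`` has shape (n_qtl, 2): column 0 is the effect of allele 1,
    column 1 of allele 2.  ``env`` holds the per-individual environmental
    deviations drawn once (shared across scenarios); ``sigma2_eps`` is
    calibrated so that heritability equals ``h2`` under the unimprinted
    (rho = 1) overlay.
    """

    qtl_ids: np.ndarray
    theta: np.ndarray
    sigma2_qtl: float
    h2: float
    sigma2_eps: float
    env: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("QTL allele effects must be finite")
        if self.sigma2_eps < 0:
            raise ValueError("environmental variance must be >= 0")
        if not 0 < self.h2 <= 1:
            raise ValueError("heritability must be in (0, 1]")


@dataclass
class ImprintScenario:
    """One (rho, s) imprinting configuration with its NI/MI/PI QTL partition."""

    rho: float
    s: float
    ni: np.ndarray  # QTL indices (0-based into the effect set)
    mi: np.ndarray
    pi: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("s must be in [0, 1]")
        allq = np.concatenate([self.ni, self.mi, self.pi])
        if len(np.unique(allq)) != len(allq):
            raise ValueError("NI/MI/PI sets must be disjoint")

    @property
    def n_qtl(self) -> int:
        return len(self.ni) + len(self.mi) + len(self.pi)


@dataclass
class PhenotypeTable:
    """Per-individual phenotype split into genetic and environmental parts."""

    ids: np.ndarray
    phenotype: np.ndarray
    genetic_value: np.ndarray
    env: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "y": self.phenotype,
            "genetic_value": self.genetic_value, "env": self.env,
        })


def _theta_lookup(theta: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Map an (n, n_qtl) allele matrix in {1, 2} to per-copy allele effects."""
    cols = np.arange(theta.shape[0])[None, :]
    return theta[cols, np.asarray(alleles, dtype=np.int64) - 1]


def draw_qtl_effects(qtl_ids: np.ndarray,
                     qtl_maternal: np.ndarray,
                     qtl_paternal: np.ndarray,
                     individual_ids: np.ndarray,
                     rng: np.random.Generator,
                     sigma2_qtl: float = 1.0,
                     h2: float = 0.5) -> QTLEffectSet:
    """Draw allele effects and calibrate the environmental variance.

    Effects are ``N(0, sigma2_qtl)`` per allele.  The additive genetic values
    under no imprinting (rho = 1) are computed over the supplied base
    population and ``sigma2_eps`` is set so that
    ``h2 = var_G / (var_G + sigma2_eps)``; the environmental deviations are
    drawn once and stored for reuse across scenarios.
    """
    n_qtl = len(qtl_ids)
    theta = rng.normal(0.0, math.sqrt(sigma2_qtl), size=(n_qtl, 2))
    gm = _theta_lookup(theta, qtl_maternal)
    gp = _theta_lookup(theta, qtl_paternal)
    g_add = gm.sum(axis=1) + gp.sum(axis=1)
    var_g = float(np.var(g_add))
    sigma2_eps = var_g * (1.0 - h2) / h2
    env = rng.normal(0.0, math.sqrt(sigma2_eps), size=len(individual_ids))
    return QTLEffectSet(
        qtl_ids=np.asarray(qtl_ids), theta=theta, sigma2_qtl=sigma2_qtl,
        h2=h2, sigma2_eps=sigma2_eps, env=env,
        individual_ids=np.asarray(individual_ids),
    )


def assign_imprint_status(qtl_ids: np.ndarray, s: float, rho: float,
                          rng: np.random.Generator,
                          seed: int = 0) -> ImprintScenario:
    """Randomly partition QTL into NI / MI / PI sets for a given s.

    The total imprinted count is the round-half-up of ``s * n_qtl``; MI gets
    its floor-half and PI the rest, so the two sets differ by at most one.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must be in [0, 1]")
    n = len(qtl_ids)
    total = int(math.floor(s * n + 0.5 + 1e-9))
    n_mi = total // 2
    n_pi = total - n_mi
    perm = rng.permutation(n)
    mi = np.sort(perm[:n_mi])
    pi = np.sort(perm[n_mi:n_mi + n_pi])
    ni = np.sort(perm[n_mi + n_pi:])
    return ImprintScenario(rho=rho, s=s, ni=ni, mi=mi, pi=pi, seed=seed)


def genotypic_value(qtl_maternal: np.ndarray, qtl_paternal: np.ndarray,
                    effects: QTLEffectSet,
                    scenario: ImprintScenario) -> np.ndarray:
    """Total genotypic value per individual under an imprinting scenario.

    Computed as the full additive sum minus ``(1 - rho)`` times the silenced
    contributions; algebraically identical to summing the NI/MI/PI terms but
    bit-reproducible across scenarios that share rho = 1.
    """
    if scenario.n_qtl != len(effects.qtl_ids):
        raise ValueError("scenario partition does not cover the QTL effect set")
    gm = _theta_lookup(effects.theta, qtl_maternal)
    gp = _theta_lookup(effects.theta, qtl_paternal)
    value = gm.sum(axis=1) + gp.sum(axis=1)
    if scenario.rho != 1.0:
        silenced = np.zeros_like(value)
        if len(scenario.mi):
            silenced += gm[:, scenario.mi].sum(axis=1)
        if len(scenario.pi):
            silenced += gp[:, scenario.pi].sum(axis=1)
        value = value - (1.0 - scenario.rho) * silenced
    return value


def simulate_phenotypes(qtl_maternal: np.ndarray, qtl_paternal: np.ndarray,
                        effects: QTLEffectSet,
                        scenario: ImprintScenario) -> PhenotypeTable:
    """Phenotypes ``y = genotypic value + eps`` with the stored eps vector."""
    g = genotypic_value(qtl_maternal, qtl_paternal, effects, scenario)
    if len(g) != len(effects.env):
        raise ValueError("genotype rows do not match the base population of the effect set")
    return PhenotypeTable(
        ids=effects.individual_ids,
        phenotype=g + effects.env,
        genetic_value=g,
        env=effects.env,
    )


def locus_genetic_variance(p: float, theta1: float, theta2: float,
                           rho: float) -> float:
    """Genetic variance of one imprinted locus under HWE:
    ``(1 + rho^2) p q (theta1 - theta2)^2``; equals ``2 p q alpha^2`` at rho = 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return (1.0 + rho**2) * p * (1.0 - p) * (theta1 - theta2) ** 2


def locus_poe_variance(p: float, theta1: float, theta2: float,
                       rho: float) -> float:
    """Parent-of-origin variance of one imprinted locus under HWE:
    ``0.5 p q (theta1 - theta2)^2 (1 - rho)^2``; zero at rho = 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return 0.5 * p * (1.0 - p) * (theta1 - theta2) ** 2 * (1.0 - rho) ** 2
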