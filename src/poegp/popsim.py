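"""Forward-in-time simulation of a livestock-style SNP/QTL population.

The simulated design mirrors a classical linkage-disequilibrium-building
protocol: a genome of equally long chromosomes carrying randomly placed
biallelic SNPs plus a separate set of biallelic QTL, a small founder
population, a long historical phase of random mating at constant size with
recurrent mutation (which establishes mutation-drift equilibrium and LD
between QTL and SNPs), and a short recent phase in which the population is
expanded without mutation and the pedigree is recorded.  Haplotypes keep
their parental origin throughout, so exported genotypes are fully phased and
parent-assigned by construction.

Recombination follows the Haldane model: crossover counts per chromosome and
meiosis are Poisson with mean equal to the map length in Morgans, crossover
positions are uniform and there is no interference.  Mutation is a recurrent
allele flip (1 <-> 2) applied independently per locus per transmitted gamete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .genotypes import OrderedGenotypes

__all__ = [
    "SimConfig",
    "GenomeMap",
    "Population",
    "ExportedDataset",
    "build_genome_map",
    "meiose",
    "simulate_population",
    "export_dataset",
]

MALE, FEMALE = 0, 1


@dataclass(frozen=True)
class SimConfig:
    """Simulation design parameters.

    Defaults give the full-scale study design: 10 chromosomes of 1 Morgan with
    1000 SNPs each (10,000 SNPs total), ~150 QTL, 100 + 100 founders, 1000
    historical generations of random mating with per-meiosis mutation rates
    1e-4 per QTL and 1e-2 per SNP, then three recent generations of 2000
    individuals (1:1 sex ratio) without mutation.
    """

    n_chrom: int = 10
    chrom_len: float = 1.0  # Morgan
    snps_per_chrom: int = 1000
    n_qtl: int = 150
    founder_males: int = 100
    founder_females: int = 100
    hist_generations: int = 1000
    mu_qtl: float = 1e-4
    mu_snp: float = 1e-2
    recent_generations: int = 3
    recent_size: int = 2000
    sex_ratio: float = 0.5
    oversample: float = 1.3  # candidate-locus surplus for the segregation filter
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_chrom=self.n_chrom, snps_per_chrom=self.snps_per_chrom,
            n_qtl=self.n_qtl, founder_males=self.founder_males,
            founder_females=self.founder_females,
            hist_generations=self.hist_generations,
            recent_generations=self.recent_generations,
            recent_size=self.recent_size,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, v in dict(mu_qtl=self.mu_qtl, mu_snp=self.mu_snp,
                            sex_ratio=self.sex_ratio).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chrom_len <= 0:
            raise ValueError("chrom_len must be positive")
        if self.oversample < 1.0:
            raise ValueError("oversample must be >= 1")


@dataclass
class GenomeMap:
    """Loci sorted by (chromosome, position); role distinguishes SNP from QTL."""

    chrom: np.ndarray      # int32, 0-based chromosome index
    pos: np.ndarray        # float64, genetic position in Morgans within chromosome
    is_qtl: np.ndarray     # bool
    ids: np.ndarray        # locus identifiers (strings)
    chrom_len: float

    def __post_init__(self) -> None:
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.is_qtl = self.is_qtl[order]
            self.ids = self.ids[order]
        if len(self.pos) and (self.pos.min() < 0 or self.pos.max() > self.chrom_len):
            raise ValueError("locus positions outside [0, chrom_len]")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_snp(self) -> int:
        return int((~self.is_qtl).sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    def chrom_starts(self) -> np.ndarray:
        """Locus-index boundaries per chromosome, length n_chrom + 1."""
        n_chrom = int(self.chrom.max()) + 1 if len(self.chrom) else 0
        return np.searchsorted(self.chrom, np.arange(n_chrom + 1)).astype(np.int64)

    def subset(self, index: np.ndarray) -> "GenomeMap":
        return GenomeMap(self.chrom[index], self.pos[index], self.is_qtl[index],
                         self.ids[index], self.chrom_len)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.ids, "chrom": self.chrom + 1,
            "pos_morgan": self.pos,
            "role": np.where(self.is_qtl, "QTL", "SNP"),
        })


@dataclass
class Population:
    """Individuals of the retained generations with phased haplotypes.

    Haplotype axis 1 is ordered (maternal, paternal); alleles are coded
    {1, 2} with allele 1 being the A1 allele counted by exported genotype
    indicators.  Generation 0 is the last historical generation (unknown
    parents); generations 1..recent_generations form the recorded pedigree.
    """

    ids: np.ndarray         # int64, 1-based
    sire: np.ndarray        # int64 id, 0 = unknown
    dam: np.ndarray
    sex: np.ndarray         # int8: 0 = male, 1 = female
    generation: np.ndarray  # int32
    haps: np.ndarray        # (n, 2, L) int8 alleles in {1, 2}; axis1: 0=maternal, 1=paternal
    genome_map: GenomeMap
    config: SimConfig
    seed_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)

    def generations_present(self) -> np.ndarray:
        return np.unique(self.generation)


@dataclass
class ExportedDataset:
    """Origin-resolved SNP genotypes, pedigree and QTL alleles for a set of generations."""

    genotypes: OrderedGenotypes
    pedigree: pd.DataFrame           # id, sire, dam, sex, generation (0 = unknown parent)
    qtl_maternal: np.ndarray         # n x n_qtl alleles in {1, 2}
    qtl_paternal: np.ndarray
    qtl_ids: np.ndarray
    genome_map: GenomeMap            # map of the exported SNP + QTL loci

    def qtl_table(self) -> pd.DataFrame:
        """Long-format QTL allele table (individual, qtl, maternal_allele, paternal_allele)."""
        n, q = self.qtl_maternal.shape
        return pd.DataFrame({
            "individual": np.repeat(self.genotypes.ids, q),
            "qtl": np.tile(self.qtl_ids, n),
            "maternal_allele": self.qtl_maternal.ravel(),
            "paternal_allele": self.qtl_paternal.ravel(),
        })


def build_genome_map(config: SimConfig, rng: np.random.Generator) -> GenomeMap:
    """Place SNPs uniformly per chromosome and QTL uniformly genome-wide.

    QTL are drawn as separate loci and never coincide with a SNP position.
    """
    if config.chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    chroms, poss, roles = [], [], []
    for c in range(config.n_chrom):
        p = rng.uniform(0.0, config.chrom_len, size=config.snps_per_chrom)
        chroms.append(np.full(config.snps_per_chrom, c, dtype=np.int32))
        poss.append(p)
        roles.append(np.zeros(config.snps_per_chrom, dtype=bool))
    snp_pos = set(map(float, np.concatenate(poss))) if poss else set()
    if config.n_chrom > 0 and config.n_qtl > 0:
        qc = rng.integers(0, config.n_chrom, size=config.n_qtl).astype(np.int32)
        qp = rng.uniform(0.0, config.chrom_len, size=config.n_qtl)
        # exact coincidence with a SNP has probability zero but is resampled anyway
        for k in range(config.n_qtl):
            while float(qp[k]) in snp_pos:  # pragma: no cover
                qp[k] = rng.uniform(0.0, config.chrom_len)
        chroms.append(qc)
        poss.append(qp)
        roles.append(np.ones(config.n_qtl, dtype=bool))
    if chroms:
        chrom = np.concatenate(chroms)
        pos = np.concatenate(poss)
        is_qtl = np.concatenate(roles)
    else:
        chrom = np.empty(0, dtype=np.int32)
        pos = np.empty(0)
        is_qtl = np.empty(0, dtype=bool)
    order = np.lexsort((pos, chrom))
    chrom, pos, is_qtl = chrom[order], pos[order], is_qtl[order]
    ids = np.array([
        (f"Q{c + 1}_{i}" if q else f"S{c + 1}_{i}")
        for i, (c, q) in enumerate(zip(chrom, is_qtl))
    ])
    return GenomeMap(chrom, pos, is_qtl, ids, config.chrom_len)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nb_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _nb_gamete(hap_a, hap_b, chrom_starts, pos, chrom_len, out, origin):
    """One meiosis: Poisson crossovers per chromosome, uniform positions.

    origin[l] records which parental haplotype (0 = hap_a, 1 = hap_b)
    contributed locus l.
    """
    n_chrom = chrom_starts.shape[0] - 1
    for c in range(n_chrom):
        lo, hi = chrom_starts[c], chrom_starts[c + 1]
        k = np.random.poisson(chrom_len)
        xs = np.sort(np.random.uniform(0.0, chrom_len, k))
        cur = np.random.randint(0, 2)
        xi = 0
        for l in range(lo, hi):
            while xi < k and xs[xi] <= pos[l]:
                cur = 1 - cur
                xi += 1
            if cur == 0:
                out[l] = hap_a[l]
            else:
                out[l] = hap_b[l]
            origin[l] = cur


@njit(cache=True)
def _nb_mutate(gamete, locus_idx, rate):
    """Exact per-locus Bernoulli(rate) allele flips via geometric gap skipping."""
    if rate <= 0.0:
        return
    m = locus_idx.shape[0]
    i = np.random.geometric(rate) - 1
    while i < m:
        l = locus_idx[i]
        gamete[l] = np.int8(3 - gamete[l])
        i += np.random.geometric(rate)


@njit(cache=True)
def _nb_generation(par_haps, sire_pos, dam_pos, chrom_starts, pos, chrom_len,
                   snp_idx, qtl_idx, mu_snp, mu_qtl, seed):
    """Produce all offspring haplotypes of one generation.

    par_haps: (n_parents, 2, L) with axis1 = (maternal, paternal).
    Offspring haplotype 0 (maternal) is a meiosis of the dam's two
    haplotypes; haplotype 1 (paternal) of the sire's.
    """
    np.random.seed(seed)
    n_off = sire_pos.shape[0]
    L = pos.shape[0]
    out = np.empty((n_off, 2, L), dtype=np.int8)
    scratch = np.empty(L, dtype=np.int8)
    for o in range(n_off):
        d = dam_pos[o]
        _nb_gamete(par_haps[d, 0], par_haps[d, 1], chrom_starts, pos, chrom_len,
                   out[o, 0], scratch)
        _nb_mutate(out[o, 0], snp_idx, mu_snp)
        _nb_mutate(out[o, 0], qtl_idx, mu_qtl)
        s = sire_pos[o]
        _nb_gamete(par_haps[s, 0], par_haps[s, 1], chrom_starts, pos, chrom_len,
                   out[o, 1], scratch)
        _nb_mutate(out[o, 1], snp_idx, mu_snp)
        _nb_mutate(out[o, 1], qtl_idx, mu_qtl)
    return out


def meiose(parent_haplotypes: np.ndarray, genome_map: GenomeMap,
           rng: np.random.Generator, mu_snp: float = 0.0, mu_qtl: float = 0.0,
           return_origin: bool = False):
    """Simulate one gamete from a parent's two haplotypes.

    Crossover counts per chromosome are Poisson(chromosome length in
    Morgans), positions uniform, no interference (Haldane model); mutation
    flips alleles independently per locus at the given per-role rates.
    """
    haps = np.asarray(parent_haplotypes, dtype=np.int8)
    if haps.shape != (2, len(genome_map)):
        raise ValueError("parent haplotypes do not match the genome map")
    gamete = np.empty(len(genome_map), dtype=np.int8)
    origin = np.empty(len(genome_map), dtype=np.int8)
    _nb_seed(int(rng.integers(0, 2**32 - 1)))
    _nb_gamete(haps[0], haps[1], genome_map.chrom_starts(), genome_map.pos,
               genome_map.chrom_len, gamete, origin)
    snp_idx = np.flatnonzero(~genome_map.is_qtl)
    qtl_idx = np.flatnonzero(genome_map.is_qtl)
    _nb_mutate(gamete, snp_idx, mu_snp)
    _nb_mutate(gamete, qtl_idx, mu_qtl)
    if return_origin:
        return gamete, origin
    return gamete


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def _draw_parents(rng, n_off, male_pos, female_pos):
    if len(male_pos) == 0 or len(female_pos) == 0:
        raise ValueError("cannot mate: one sex has no individuals")
    sires = male_pos[rng.integers(0, len(male_pos), size=n_off)]
    dams = female_pos[rng.integers(0, len(female_pos), size=n_off)]
    return sires.astype(np.int64), dams.astype(np.int64)


def _segregating(haps: np.ndarray) -> np.ndarray:
    """Boolean per-locus mask: both alleles present among the given haplotypes."""
    flat = haps.reshape(-1, haps.shape[-1])
    return (flat == 1).any(axis=0) & (flat == 2).any(axis=0)


def simulate_population(config: SimConfig,
                        filter_segregating: bool = True) -> Population:
    """Run the full forward simulation and return the recent generations.

    The historical phase keeps only the current generation in memory; the
    returned population holds the last historical generation (generation 0,
    unknown parents) plus the recorded recent generations.  When
    ``filter_segregating`` is set, candidate loci are oversampled and, at the
    end of the historical phase, the first ``snps_per_chrom`` segregating
    SNPs per chromosome and the first ``n_qtl`` segregating QTL are kept
    (realized QTL counts may fall short when segregating candidates run out).
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_map, ss_founder, ss_hist, ss_recent = root.spawn(4)
    seed_log = {
        "root": cfg.seed,
        "map": int(ss_map.generate_state(1)[0]),
        "founders": int(ss_founder.generate_state(1)[0]),
    }

    cand_cfg = cfg
    if filter_segregating:
        cand_cfg = replace(
            cfg,
            snps_per_chrom=int(np.ceil(cfg.snps_per_chrom * cfg.oversample)),
            n_qtl=int(np.ceil(cfg.n_qtl * cfg.oversample)),
        )
    gmap = build_genome_map(cand_cfg, np.random.default_rng(ss_map))
    L = len(gmap)
    chrom_starts = gmap.chrom_starts()
    snp_idx = np.flatnonzero(~gmap.is_qtl).astype(np.int64)
    qtl_idx = np.flatnonzero(gmap.is_qtl).astype(np.int64)

    n0 = cfg.founder_males + cfg.founder_females
    founder_rng = np.random.default_rng(ss_founder)
    haps = founder_rng.integers(1, 3, size=(n0, 2, L), dtype=np.int8)
    sex = np.concatenate([
        np.zeros(cfg.founder_males, dtype=np.int8),
        np.ones(cfg.founder_females, dtype=np.int8),
    ])

    # historical phase: constant size, random mating, recurrent mutation
    mate_rng = np.random.default_rng(ss_hist)
    hist_seeds = ss_hist.generate_state(max(cfg.hist_generations, 1) + 1)
    for g in range(cfg.hist_generations):
        males = np.flatnonzero(sex == MALE)
        females = np.flatnonzero(sex == FEMALE)
        if n0 > 0:
            sires, dams = _draw_parents(mate_rng, n0, males, females)
            haps = _nb_generation(haps, sires, dams, chrom_starts, gmap.pos,
                                  cfg.chrom_len, snp_idx, qtl_idx,
                                  cfg.mu_snp, cfg.mu_qtl,
                                  int(hist_seeds[g] % (2**32 - 1)))
        # sex labels are fixed counts each generation (constant-size design)

    if filter_segregating and L > 0 and n0 > 0:
        seg = _segregating(haps)
        keep = np.zeros(L, dtype=bool)
        for c in range(cand_cfg.n_chrom):
            lo, hi = chrom_starts[c], chrom_starts[c + 1]
            snp_here = np.flatnonzero(~gmap.is_qtl[lo:hi] & seg[lo:hi]) + lo
            keep[snp_here[:cfg.snps_per_chrom]] = True
        qtl_seg = qtl_idx[seg[qtl_idx]]
        keep[qtl_seg[:cfg.n_qtl]] = True
        gmap = gmap.subset(keep)
        haps = np.ascontiguousarray(haps[:, :, keep])
        chrom_starts = gmap.chrom_starts()
        snp_idx = np.flatnonzero(~gmap.is_qtl).astype(np.int64)
        qtl_idx = np.flatnonzero(gmap.is_qtl).astype(np.int64)
        L = len(gmap)

    # recent phase: expansion, recorded pedigree, no mutation
    all_ids = [np.arange(1, n0 + 1, dtype=np.int64)]
    all_sire = [np.zeros(n0, dtype=np.int64)]
    all_dam = [np.zeros(n0, dtype=np.int64)]
    all_sex = [sex.copy()]
    all_gen = [np.zeros(n0, dtype=np.int32)]
    all_haps = [haps]

    recent_rng = np.random.default_rng(ss_recent)
    recent_seeds = ss_recent.generate_state(max(cfg.recent_generations, 1) + 1)
    prev_ids, prev_sex, prev_haps = all_ids[0], sex, haps
    next_id = n0 + 1
    n_rec_males = int(round(cfg.recent_size * cfg.sex_ratio))
    for g in range(1, cfg.recent_generations + 1):
        n_off = cfg.recent_size
        males = np.flatnonzero(prev_sex == MALE)
        females = np.flatnonzero(prev_sex == FEMALE)
        sires, dams = _draw_parents(recent_rng, n_off, males, females)
        off = _nb_generation(prev_haps, sires, dams, chrom_starts, gmap.pos,
                             cfg.chrom_len, snp_idx, qtl_idx, 0.0, 0.0,
                             int(recent_seeds[g] % (2**32 - 1)))
        osex = np.concatenate([
            np.zeros(n_rec_males, dtype=np.int8),
            np.ones(n_off - n_rec_males, dtype=np.int8),
        ])
        oids = np.arange(next_id, next_id + n_off, dtype=np.int64)
        next_id += n_off
        all_ids.append(oids)
        all_sire.append(prev_ids[sires])
        all_dam.append(prev_ids[dams])
        all_sex.append(osex)
        all_gen.append(np.full(n_off, g, dtype=np.int32))
        all_haps.append(off)
        prev_ids, prev_sex, prev_haps = oids, osex, off

    seed_log["historical"] = [int(s) for s in hist_seeds[:cfg.hist_generations]]
    seed_log["recent"] = [int(s) for s in recent_seeds[1:cfg.recent_generations + 1]]
    return Population(
        ids=np.concatenate(all_ids),
        sire=np.concatenate(all_sire),
        dam=np.concatenate(all_dam),
        sex=np.concatenate(all_sex),
        generation=np.concatenate(all_gen),
        haps=np.concatenate(all_haps, axis=0),
        genome_map=gmap,
        config=cfg,
        seed_log=seed_log,
    )


def export_dataset(population: Population,
                   generations: Sequence[int]) -> ExportedDataset:
    """Extract phased SNP genotypes, pedigree and QTL alleles for given generations.

    Loci monomorphic across the exported individuals are dropped so that the
    exported SNP and QTL sets are segregating in the export generations.
    Parents outside the population are coded 0 (unknown).
    """
    present = set(population.generations_present().tolist())
    for g in generations:
        if g not in present:
            raise ValueError(f"generation {g} not present in population")
    mask = np.isin(population.generation, list(generations))
    haps = population.haps[mask]
    seg = _segregating(haps)
    gmap = population.genome_map.subset(seg)
    haps = haps[:, :, seg]

    snp = ~gmap.is_qtl
    genotypes = OrderedGenotypes(
        ids=population.ids[mask],
        marker_ids=gmap.ids[snp],
        maternal=(haps[:, 0, :][:, snp] == 1).astype(np.int8),
        paternal=(haps[:, 1, :][:, snp] == 1).astype(np.int8),
    )
    known = set(population.ids[mask].tolist())
    sire = np.where(np.isin(population.sire[mask], list(known)),
                    population.sire[mask], 0)
    dam = np.where(np.isin(population.dam[mask], list(known)),
                   population.dam[mask], 0)
    pedigree = pd.DataFrame({
        "id": population.ids[mask],
        "sire": sire,
        "dam": dam,
        "sex": np.where(population.sex[mask] == MALE, "M", "F"),
        "generation": population.generation[mask],
    })
    return ExportedDataset(
        genotypes=genotypes,
        pedigree=pedigree,
        qtl_maternal=haps[:, 0, :][:, gmap.is_qtl].astype(np.int8),
        qtl_paternal=haps[:, 1, :][:, gmap.is_qtl].astype(np.int8),
        qtl_ids=gmap.ids[gmap.is_qtl],
        genome_map=gmap,
    )
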