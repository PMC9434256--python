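"""Forward-in-time simulation of diploid populations with full pedigree tracking.

The simulated world: a founding population of diploid individuals whose
haplotype alleles are i.i.d. Bernoulli(0.5) at every biallelic SNP, so any
structure in the final data is created by the simulation itself.  Each
generation, every subpopulation may fission (half its members emigrate to
found a new, reproductively isolated subpopulation), after which
individuals mate within their subpopulation — either randomly paired, or
truncation-selected on a quantitative trait before pairing.  Gametes
recombine at a constant rate of 1 cM/Mbp under the Haldane (no
interference) model.  The terminal generation is genotyped; the complete
pedigree, with generation and subpopulation annotations, is retained.

Defaults reproduce the stated benchmark world: 100 founders, 10
generations, 24,000 SNPs on 10 chromosomes of 100 Mbp, migration
probability 0.3 per subpopulation per generation, 1-4 offspring per
random-mating pair or 2-8 per pair of truncation-selected (top 50% on a
10-QTN, h² = 0.5 trait) parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .ground_truth import Pedigree

__all__ = [
    "SimulationConfig",
    "GenomeMap",
    "TraitModel",
    "Population",
    "SimulationResult",
    "ExtinctionError",
    "default_genome_map",
    "make_founders",
    "make_trait",
    "gamete",
    "phenotype",
    "random_mating_step",
    "assortative_mating_step",
    "migration_step",
    "simulate",
]


class ExtinctionError(RuntimeError):
    """All subpopulations fell below pairing size."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated population history."""

    n_founders: int = 100
    n_generations: int = 10
    n_snps: int = 24000
    recomb_rate: float = 1.0          # cM per Mbp
    migration_enabled: bool = True
    migration_prob: float = 0.3       # per subpopulation per generation
    mating: str = "random"            # "random" | "assortative"
    offspring_range_random: tuple[int, int] = (1, 4)
    offspring_range_assortative: tuple[int, int] = (2, 8)
    selection_fraction: float = 0.5
    n_qtn: int = 10
    h2: float = 0.5
    n_chromosomes: int = 10
    chrom_length_mbp: float = 100.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "n_snps", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.mating not in ("random", "assortative"):
            raise ValueError(f"unknown mating scheme: {self.mating!r}")
        for name in ("migration_prob", "selection_fraction", "h2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("offspring_range_random", "offspring_range_assortative"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= low <= high")
        if self.mating == "assortative" and self.n_qtn < 1:
            raise ValueError("assortative mating requires n_qtn >= 1")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")

    @property
    def offspring_range(self) -> tuple[int, int]:
        return (self.offspring_range_random if self.mating == "random"
                else self.offspring_range_assortative)


@dataclass(frozen=True)
class GenomeMap:
    """SNP coordinates on a set of autosomes.

    ``chrom_lengths_bp[c]`` is the physical length of chromosome ``c``;
    ``snp_chrom``/``snp_pos_bp`` give each SNP's chromosome and position.
    Positions are strictly increasing within a chromosome.
    """

    chrom_lengths_bp: np.ndarray
    snp_chrom: np.ndarray
    snp_pos_bp: np.ndarray

    def __post_init__(self):
        if self.snp_chrom.shape != self.snp_pos_bp.shape:
            raise ValueError("snp_chrom and snp_pos_bp must align")
        if self.snp_chrom.size == 0:
            raise ValueError("genome map has no SNPs")
        for c in range(len(self.chrom_lengths_bp)):
            pos = self.snp_pos_bp[self.snp_chrom == c]
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
            if pos.size and pos[-1] > self.chrom_lengths_bp[c]:
                raise ValueError(f"SNP beyond end of chromosome {c}")

    @property
    def n_snps(self) -> int:
        return int(self.snp_chrom.size)

    def chrom_slices(self) -> list[slice]:
        """Contiguous SNP index ranges per chromosome (SNPs are stored sorted)."""
        out = []
        start = 0
        for c in range(len(self.chrom_lengths_bp)):
            k = int(np.sum(self.snp_chrom == c))
            out.append(slice(start, start + k))
            start += k
        return out


def default_genome_map(config: SimulationConfig) -> GenomeMap:
    """Evenly spaced SNPs on ``n_chromosomes`` equal-length autosomes."""
    n_chrom = config.n_chromosomes
    length_bp = int(config.chrom_length_mbp * 1e6)
    per = np.full(n_chrom, config.n_snps // n_chrom, dtype=np.int64)
    per[: config.n_snps % n_chrom] += 1
    chroms, pos = [], []
    for c in range(n_chrom):
        k = int(per[c])
        if k == 0:
            continue
        # midpoints of k equal bins, keeping SNPs off the chromosome ends
        p = ((np.arange(k) + 0.5) / k * length_bp).astype(np.int64)
        chroms.append(np.full(k, c, dtype=np.int32))
        pos.append(p)
    return GenomeMap(
        chrom_lengths_bp=np.full(n_chrom, length_bp, dtype=np.int64),
        snp_chrom=np.concatenate(chroms),
        snp_pos_bp=np.concatenate(pos),
    )


@dataclass(frozen=True)
class TraitModel:
    """Additive quantitative trait: 10 QTN by default, calibrated to h²."""

    qtn_indices: np.ndarray
    qtn_effects: np.ndarray
    env_sd: float

    def genetic_value(self, dosage: np.ndarray) -> np.ndarray:
        """Sum of effect × dosage at the QTN; ``dosage`` is (n, n_snps)."""
        return dosage[:, self.qtn_indices].astype(np.float64) @ self.qtn_effects


@dataclass
class Population:
    """One generation of individuals (struct-of-arrays).

    ``haplotypes`` has shape (n, 2, n_snps) with 0/1 alleles; ``ids`` are
    globally unique positive integers (0 is the unknown-parent sentinel).
    """

    ids: np.ndarray
    sires: np.ndarray
    dams: np.ndarray
    subpop: np.ndarray
    haplotypes: np.ndarray
    generation: int
    phenotypes: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1, dtype=np.uint8)


@dataclass
class SimulationResult:
    """Terminal genotypes plus the full pedigree of the simulated history."""

    pedigree: Pedigree
    genotypes: "GenotypeMatrix"
    subpop_labels: np.ndarray
    trait: TraitModel
    config: SimulationConfig
    genome_map: GenomeMap

    @property
    def terminal_ids(self) -> list:
        return list(self.genotypes.ids)


# ---------------------------------------------------------------------------
# founders and trait calibration
# ---------------------------------------------------------------------------

def make_founders(config: SimulationConfig, genome_map: GenomeMap,
                  rng: np.random.Generator) -> Population:
    """Founding generation: every haplotype allele i.i.d. Bernoulli(0.5)."""
    if genome_map.n_snps != config.n_snps:
        raise ValueError("genome map SNP count does not match config")
    n = config.n_founders
    haps = rng.integers(0, 2, size=(n, 2, config.n_snps), dtype=np.uint8)
    ids = np.arange(1, n + 1, dtype=np.int64)
    zeros = np.zeros(n, dtype=np.int64)
    return Population(ids=ids, sires=zeros.copy(), dams=zeros.copy(),
                      subpop=np.zeros(n, dtype=np.int64),
                      haplotypes=haps, generation=0)


def make_trait(config: SimulationConfig, founders: Population,
               rng: np.random.Generator) -> TraitModel:
    """Draw QTN uniformly, effects ~ N(0,1); set env_sd so the founder
    generation has Var(G)/(Var(G)+Var(E)) = h²."""
    qtn = rng.choice(config.n_snps, size=min(config.n_qtn, config.n_snps),
                     replace=False)
    qtn.sort()
    effects = rng.standard_normal(qtn.size)
    g = founders.dosage()[:, qtn].astype(np.float64) @ effects
    var_g = float(np.var(g))
    if config.h2 <= 0 or var_g == 0.0:
        env_sd = 0.0
        if var_g == 0.0:
            warnings.warn("founder genetic variance is zero; trait is pure noise-free")
    elif config.h2 >= 1.0:
        env_sd = 0.0
    else:
        env_sd = float(np.sqrt(var_g * (1.0 - config.h2) / config.h2))
    return TraitModel(qtn_indices=qtn, qtn_effects=effects, env_sd=env_sd)


def phenotype(dosage: np.ndarray, trait: TraitModel,
              rng: np.random.Generator) -> np.ndarray:
    """Additive genetic value plus N(0, env_sd²) noise; ``dosage`` is (n, n_snps)."""
    g = trait.genetic_value(np.atleast_2d(dosage))
    return g + rng.normal(0.0, trait.env_sd, size=g.shape)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gametes_batch(parent_haps: np.ndarray, genome_map: GenomeMap,
                   rng: np.random.Generator) -> np.ndarray:
    """Recombinant gametes for a batch of parents.

    ``parent_haps`` is (k, 2, S); returns (k, S).  Crossover counts per
    chromosome are Poisson(length_Mbp × rate / 100 Morgans) with breakpoints
    uniform in bp; the transmitted strand alternates at each breakpoint
    starting from a fair coin per chromosome (Haldane model, no
    interference).  Chromosomes assort independently.
    """
    k, two, S = parent_haps.shape
    flips = np.zeros((k, S), dtype=np.uint8)
    slices = genome_map.chrom_slices()
    for c, sl in enumerate(slices):
        if sl.stop == sl.start:
            continue
        pos = genome_map.snp_pos_bp[sl]
        length_bp = genome_map.chrom_lengths_bp[c]
        morgans = length_bp / 1e6 * 0.01  # 1 cM/Mbp default
        # fresh fair-coin strand choice at the start of every chromosome
        flips[:, sl.start] += rng.integers(0, 2, size=k, dtype=np.uint8)
        nx = rng.poisson(morgans, size=k)
        total = int(nx.sum())
        if total:
            bp = rng.uniform(0, length_bp, size=total)
            snp_idx = np.searchsorted(pos, bp)  # first SNP at/after breakpoint
            keep = snp_idx < pos.size           # breakpoints past last SNP: no effect
            gam_idx = np.repeat(np.arange(k), nx)[keep]
            np.add.at(flips, (gam_idx, sl.start + snp_idx[keep]), 1)
    # uint8 accumulator wraps mod 256 (even), so parity survives overflow
    source = (flips.cumsum(axis=1, dtype=np.uint8) & 1).astype(bool)
    return np.where(source, parent_haps[:, 1, :], parent_haps[:, 0, :])


def gamete(parent: Population | np.ndarray, genome_map: GenomeMap,
           rng: np.random.Generator, rate: float = 1.0,
           index: int = 0) -> np.ndarray:
    """Single recombinant gamete from one parent.

    ``parent`` may be a Population (use individual ``index``) or a (2, S)
    haplotype pair.  ``rate`` is cM/Mbp.
    """
    if isinstance(parent, Population):
        haps = parent.haplotypes[index]
    else:
        haps = np.asarray(parent)
    if haps.shape[-1] != genome_map.n_snps:
        raise ValueError("parent haplotypes do not match genome map")
    gm = genome_map if rate == 1.0 else _rescaled_map(genome_map, rate)
    return _gametes_batch(haps[None, :, :], gm, rng)[0]


def _rescaled_map(genome_map: GenomeMap, rate: float) -> GenomeMap:
    """Fold a non-unit cM/Mbp rate into the physical lengths."""
    return GenomeMap(
        chrom_lengths_bp=(genome_map.chrom_lengths_bp * rate).astype(np.int64),
        snp_chrom=genome_map.snp_chrom,
        snp_pos_bp=(genome_map.snp_pos_bp * rate).astype(np.int64),
    )


# ---------------------------------------------------------------------------
# one-generation steps
# ---------------------------------------------------------------------------

def _pair_within_subpop(members: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Monogamous random pairing without replacement; odd leftover unpaired.

    Returns an (n_pairs, 2) array of positions into ``members``.
    """
    perm = rng.permutation(members.size)
    n_pairs = members.size // 2
    return perm[: 2 * n_pairs].reshape(n_pairs, 2)


def _produce_offspring(pop: Population, pair_parent_a: np.ndarray,
                       pair_parent_b: np.ndarray, counts: np.ndarray,
                       subpops: np.ndarray, genome_map: GenomeMap,
                       config: SimulationConfig, next_id: int,
                       rng: np.random.Generator) -> Population:
    """Materialize offspring for given pairs; parents indexed into ``pop``."""
    sire_pos = np.repeat(pair_parent_a, counts)
    dam_pos = np.repeat(pair_parent_b, counts)
    off_subpop = np.repeat(subpops, counts)
    m = sire_pos.size
    gm = (genome_map if config.recomb_rate == 1.0
          else _rescaled_map(genome_map, config.recomb_rate))
    hap_a = _gametes_batch(pop.haplotypes[sire_pos], gm, rng)
    hap_b = _gametes_batch(pop.haplotypes[dam_pos], gm, rng)
    haps = np.stack([hap_a, hap_b], axis=1)
    ids = np.arange(next_id, next_id + m, dtype=np.int64)
    return Population(
        ids=ids,
        sires=pop.ids[sire_pos].copy(),
        dams=pop.ids[dam_pos].copy(),
        subpop=off_subpop,
        haplotypes=haps,
        generation=pop.generation + 1,
    )


def random_mating_step(pop: Population, config: SimulationConfig,
                       genome_map: GenomeMap, next_id: int,
                       rng: np.random.Generator) -> Population:
    """Random monogamous pairing within each subpopulation.

    Each pair leaves k ~ uniform{lo..hi} offspring (inclusive; defaults
    1-4).  A subpopulation of one individual leaves no offspring.
    """
    lo, hi = config.offspring_range_random
    pa, pb, counts, subs = [], [], [], []
    for label in np.unique(pop.subpop):
        members = np.flatnonzero(pop.subpop == label)
        if members.size < 2:
            warnings.warn(f"subpopulation {label} has {members.size} member(s); "
                          "no offspring")
            continue
        pairs = _pair_within_subpop(members, rng)
        k = rng.integers(lo, hi + 1, size=pairs.shape[0])
        pa.append(members[pairs[:, 0]])
        pb.append(members[pairs[:, 1]])
        counts.append(k)
        subs.append(np.full(pairs.shape[0], label, dtype=np.int64))
    if not pa:
        raise ExtinctionError(
            f"no subpopulation large enough to pair at generation {pop.generation}")
    return _produce_offspring(pop, np.concatenate(pa), np.concatenate(pb),
                              np.concatenate(counts), np.concatenate(subs),
                              genome_map, config, next_id, rng)


def assortative_mating_step(pop: Population, config: SimulationConfig,
                            trait: TraitModel, genome_map: GenomeMap,
                            next_id: int,
                            rng: np.random.Generator) -> Population:
    """Truncation selection then random pairing among the selected.

    Within each subpopulation the top ``selection_fraction`` of individuals
    by phenotype reproduce; each pair leaves k ~ uniform{lo..hi} offspring
    (defaults 2-8).
    """
    lo, hi = config.offspring_range_assortative
    if pop.phenotypes is None:
        pop.phenotypes = phenotype(pop.dosage(), trait, rng)
    pa, pb, counts, subs = [], [], [], []
    for label in np.unique(pop.subpop):
        members = np.flatnonzero(pop.subpop == label)
        n_sel = int(np.floor(members.size * config.selection_fraction))
        if n_sel < 2:
            warnings.warn(f"subpopulation {label}: fewer than 2 selected; "
                          "no offspring")
            continue
        order = np.argsort(pop.phenotypes[members], kind="stable")[::-1]
        selected = members[order[:n_sel]]
        pairs = _pair_within_subpop(selected, rng)
        k = rng.integers(lo, hi + 1, size=pairs.shape[0])
        pa.append(selected[pairs[:, 0]])
        pb.append(selected[pairs[:, 1]])
        counts.append(k)
        subs.append(np.full(pairs.shape[0], label, dtype=np.int64))
    if not pa:
        raise ExtinctionError(
            f"no subpopulation large enough to select and pair at "
            f"generation {pop.generation}")
    return _produce_offspring(pop, np.concatenate(pa), np.concatenate(pb),
                              np.concatenate(counts), np.concatenate(subs),
                              genome_map, config, next_id, rng)


def migration_step(pop: Population, config: SimulationConfig,
                   rng: np.random.Generator) -> Population:
    """Subpopulation fission by emigration.

    Independently for each existing subpopulation, with probability
    ``migration_prob`` a uniformly random half (floor) of its members are
    relabeled into a brand-new subpopulation.  There is no back-migration;
    all subsequent mating is within subpopulation.
    """
    if not config.migration_enabled:
        return pop
    subpop = pop.subpop.copy()
    next_label = int(subpop.max()) + 1
    for label in np.unique(pop.subpop):
        if rng.random() >= config.migration_prob:
            continue
        members = np.flatnonzero(pop.subpop == label)
        n_emigrants = members.size // 2
        if n_emigrants == 0:
            continue
        emigrants = rng.choice(members, size=n_emigrants, replace=False)
        subpop[emigrants] = next_label
        next_label += 1
    return replace(pop, subpop=subpop)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig,
             genome_map: GenomeMap | None = None) -> SimulationResult:
    """Run the full forward simulation and genotype the terminal generation.

    Per generation: migration (fission) acts on the current generation if
    enabled, then the configured mating scheme produces the next
    generation.  Fully reproducible from ``config.seed``.
    """
    from .embeddings import GenotypeMatrix

    rng = np.random.default_rng(config.seed)
    if genome_map is None:
        genome_map = default_genome_map(config)
    pop = make_founders(config, genome_map, rng)
    trait = make_trait(config, pop, rng)
    next_id = int(pop.ids.max()) + 1

    ped_ids = [pop.ids]
    ped_sires = [pop.sires]
    ped_dams = [pop.dams]
    ped_gen = [np.zeros(pop.n, dtype=np.int64)]
    ped_sub = [pop.subpop]

    for g in range(1, config.n_generations + 1):
        pop = migration_step(pop, config, rng)
        # fission relabels current-generation members: keep pedigree in sync
        ped_sub[-1] = pop.subpop
        if config.mating == "random":
            pop = random_mating_step(pop, config, genome_map, next_id, rng)
        else:
            pop = assortative_mating_step(pop, config, trait, genome_map,
                                          next_id, rng)
        next_id = int(pop.ids.max()) + 1
        ped_ids.append(pop.ids)
        ped_sires.append(pop.sires)
        ped_dams.append(pop.dams)
        ped_gen.append(np.full(pop.n, g, dtype=np.int64))
        ped_sub.append(pop.subpop)

    all_ids = np.concatenate(ped_ids)
    all_sires = np.concatenate(ped_sires)
    all_dams = np.concatenate(ped_dams)
    pedigree = Pedigree(
        ids=[int(x) for x in all_ids],
        sires=[int(x) if x > 0 else None for x in all_sires],
        dams=[int(x) if x > 0 else None for x in all_dams],
        generation=np.concatenate(ped_gen),
        subpopulation=np.concatenate(ped_sub),
    )
    genotypes = GenotypeMatrix(
        values=pop.dosage(),
        ids=[int(x) for x in pop.ids],
        snp_chrom=genome_map.snp_chrom,
        snp_pos=genome_map.snp_pos_bp,
    )
    return SimulationResult(
        pedigree=pedigree,
        genotypes=genotypes,
        subpop_labels=pop.subpop.copy(),
        trait=trait,
        config=config,
        genome_map=genome_map,
    )
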