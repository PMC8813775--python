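"""Founder genomes and meiosis for a small outbred clonal crop.

Standing variation is generated by a discrete-generation Wright-Fisher
burn-in at small effective size (random mating, symmetric per-site
mutation, Poisson recombination without interference) run to
mutation-drift equilibrium, from which a handful of non-inbred founder
diploids are sampled. The genome is a fixed panel of biallelic candidate
sites with positions on a genetic (Morgan) map; physical positions follow
from one constant Morgans-per-base-pair rate. Only recombination and the
trait sites matter downstream, so no sequence-level realism is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InsufficientVariationError


@dataclass(frozen=True)
class GenomeConfig:
    """Genome and burn-in parameters.

    Defaults describe a cassava-like outbred diploid: 18 chromosomes of
    1.43 Morgans / 8x10^8 bp each, per-bp mutation rate 2x10^-9, and an
    effective population size of 30 standing in for a history of natural
    and artificial selection.
    """

    n_chromosomes: int = 18
    morgans_per_chromosome: float = 1.43
    bp_per_chromosome: int = 800_000_000
    mutation_rate_per_bp: float = 2e-9
    effective_population_size: int = 30
    sites_per_chromosome: int = 500
    burn_in_generations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.morgans_per_chromosome <= 0 or self.bp_per_chromosome <= 0:
            raise ValueError("chromosome lengths must be strictly positive")
        if self.mutation_rate_per_bp <= 0:
            raise ValueError("mutation rate must be strictly positive")
        if min(self.n_chromosomes, self.effective_population_size, self.sites_per_chromosome) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def mutation_rate_per_site(self) -> float:
        """Per-candidate-site per-gamete mutation probability.

        Each candidate site absorbs the mutation flux of the stretch of
        sequence it represents, so genome-wide mutation input matches the
        per-bp rate regardless of panel density.
        """
        bp_per_site = self.bp_per_chromosome / self.sites_per_chromosome
        return self.mutation_rate_per_bp * bp_per_site


def recombination_rate_per_bp(cfg: GenomeConfig) -> float:
    """Morgans per base pair implied by the genome lengths (full precision)."""
    return cfg.morgans_per_chromosome / cfg.bp_per_chromosome


def format_rate(rate: float, sig: int = 2) -> str:
    """Display form of a per-bp rate to ``sig`` significant figures."""
    return f"{rate:.{sig - 1}e}"


@dataclass(frozen=True)
class GeneticMap:
    """Sorted site positions per chromosome, in Morgans and base pairs."""

    chrom_lengths_morgans: np.ndarray  # (n_chrom,)
    positions_morgans: list[np.ndarray]  # per chromosome, strictly increasing
    positions_bp: list[np.ndarray]  # parallel physical positions

    def __post_init__(self):
        for pos in self.positions_morgans:
            if np.any(np.diff(pos) <= 0):
                raise ValueError("map positions must be strictly increasing")

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions_morgans)

    @property
    def sites_per_chromosome(self) -> np.ndarray:
        return np.array([len(p) for p in self.positions_morgans])

    @property
    def n_sites(self) -> int:
        return int(self.sites_per_chromosome.sum())

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Start index of each chromosome in the flat site axis."""
        return np.concatenate([[0], np.cumsum(self.sites_per_chromosome)[:-1]])

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """New map restricted to a boolean mask over the flat site axis."""
        offs = self.chrom_offsets
        pm, pb = [], []
        for c in range(self.n_chromosomes):
            sl = slice(offs[c], offs[c] + len(self.positions_morgans[c]))
            mask = keep[sl]
            pm.append(self.positions_morgans[c][mask])
            pb.append(self.positions_bp[c][mask])
        return GeneticMap(self.chrom_lengths_morgans, pm, pb)


@dataclass
class Individual:
    """One diploid with pedigree, genome, and per-stage phenotype history."""

    id: str
    haplotypes: np.ndarray  # (2, n_sites) uint8
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    birth_year: int = 0
    stage_history: list = field(default_factory=list)  # (stage, year, entry_mean)

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)

    def record_phenotype(self, stage: str, year: int, entry_mean: float) -> None:
        self.stage_history.append((stage, year, entry_mean))

    def entry_mean(self, stage: str) -> float:
        for s, _, m in reversed(self.stage_history):
            if s == stage:
                return m
        raise KeyError(f"{self.id}: no phenotype recorded at stage {stage!r}")


@dataclass
class HaplotypeSet:
    """Phased biallelic haplotypes for an ordered set of individuals."""

    ids: list[str]
    haplotypes: np.ndarray  # (n_individuals, 2, n_sites) uint8
    genetic_map: GeneticMap
    metadata: dict = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1)

    def segregating_mask(self) -> np.ndarray:
        flat = self.haplotypes.reshape(-1, self.n_sites)
        freq = flat.mean(axis=0)
        return (freq > 0) & (freq < 1)

    def individuals(self, id_prefix: str = "F") -> list[Individual]:
        return [
            Individual(id=self.ids[i], haplotypes=self.haplotypes[i].copy())
            for i in range(self.n_individuals)
        ]


# ---------------------------------------------------------------------------
# meiosis


def _gamete_batch(
    parent_haps: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
    return_breakpoints: bool = False,
):
    """Vectorised meiosis for ``n`` gametes.

    ``parent_haps`` has shape (n, 2, n_sites). Per chromosome the
    crossover count is Poisson with mean equal to the map length,
    positions are uniform (no interference, no obligate chiasma), and the
    starting haplotype is chosen with probability 1/2. The gamete allele
    at a site is taken from whichever haplotype is active there.
    """
    n = parent_haps.shape[0]
    out = np.empty((n, gmap.n_sites), dtype=np.uint8)
    breakpoints: list[list[np.ndarray]] = [[] for _ in range(n)] if return_breakpoints else None
    offs = gmap.chrom_offsets
    for c in range(gmap.n_chromosomes):
        L = float(gmap.chrom_lengths_morgans[c])
        pos = gmap.positions_morgans[c]
        s0 = offs[c]
        sl = slice(s0, s0 + len(pos))
        start = rng.integers(0, 2, size=n)
        if L > 0:
            k = rng.poisson(L, size=n)
            kmax = int(k.max()) if n else 0
        else:
            k = np.zeros(n, dtype=int)
            kmax = 0
        if kmax == 0 or len(pos) == 0:
            active = np.broadcast_to(start[:, None], (n, len(pos)))
        else:
            xo = rng.uniform(0.0, L, size=(n, kmax))
            xo[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
            # crossovers strictly left of a site flip the active haplotype
            counts = (xo[:, :, None] < pos[None, None, :]).sum(axis=1)
            active = (start[:, None] + counts) % 2
        out[:, sl] = np.take_along_axis(
            parent_haps[:, :, sl], active[:, None, :].astype(np.intp), axis=1
        )[:, 0, :]
        if return_breakpoints:
            for i in range(n):
                if kmax and k[i]:
                    breakpoints[i].append(np.sort(xo[i, : k[i]]))
                else:
                    breakpoints[i].append(np.empty(0))
    if return_breakpoints:
        return out, breakpoints
    return out


def meiosis(
    parent_haplotypes: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
    return_breakpoints: bool = False,
):
    """One gamete from a (2, n_sites) pair of parental haplotypes."""
    res = _gamete_batch(parent_haplotypes[None], gmap, rng, return_breakpoints)
    if return_breakpoints:
        gametes, bks = res
        return gametes[0], bks[0]
    return res[0]


def make_cross(
    mother: Individual,
    father: Individual,
    n_progeny: int,
    rng: np.random.Generator,
    gmap: GeneticMap,
    id_prefix: Optional[str] = None,
    birth_year: int = 0,
) -> list[Individual]:
    """Produce ``n_progeny`` full sibs with recorded pedigree."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if id_prefix is None:
        id_prefix = f"{mother.id}x{father.id}-"
    mg = _gamete_batch(np.broadcast_to(mother.haplotypes, (n_progeny, 2, gmap.n_sites)), gmap, rng)
    fg = _gamete_batch(np.broadcast_to(father.haplotypes, (n_progeny, 2, gmap.n_sites)), gmap, rng)
    return [
        Individual(
            id=f"{id_prefix}{j}",
            haplotypes=np.stack([mg[j], fg[j]]),
            mother_id=mother.id,
            father_id=father.id,
            birth_year=birth_year,
        )
        for j in range(n_progeny)
    ]


# ---------------------------------------------------------------------------
# Wright-Fisher burn-in


def _build_map(cfg: GenomeConfig, rng: np.random.Generator) -> GeneticMap:
    morgan_per_bp = recombination_rate_per_bp(cfg)
    pm, pb = [], []
    for _ in range(cfg.n_chromosomes):
        pos = np.sort(rng.uniform(0.0, cfg.morgans_per_chromosome, cfg.sites_per_chromosome))
        # enforce strict ordering at float resolution
        pos = np.maximum.accumulate(pos + np.arange(len(pos)) * 1e-12)
        pm.append(pos)
        pb.append(np.round(pos / morgan_per_bp).astype(np.int64))
    lengths = np.full(cfg.n_chromosomes, cfg.morgans_per_chromosome)
    return GeneticMap(lengths, pm, pb)


def simulate_founders(
    cfg: GenomeConfig,
    n_founders: int = 4,
    min_segregating_per_chromosome: int = 0,
    track_heterozygosity: bool = False,
) -> tuple[HaplotypeSet, GeneticMap]:
    """Sample founder diploids from an equilibrated Wright-Fisher population.

    A population of ``effective_population_size`` random-mating diploids
    evolves for ``burn_in_generations`` with per-site mutation and Poisson
    recombination; ``n_founders`` individuals are then sampled and sites
    monomorphic among them are pruned. Deterministic given ``cfg.seed``.

    Raises :class:`InsufficientVariationError` when any chromosome retains
    fewer segregating sites than ``min_segregating_per_chromosome``.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    ne = cfg.effective_population_size
    if n_founders > ne:
        raise ValueError("cannot sample more founders than the population size")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    gmap = _build_map(cfg, rng)
    n_sites = gmap.n_sites
    u = cfg.mutation_rate_per_site

    # population as 2Ne haplotypes; start monomorphic, mutation builds variation
    haps = np.zeros((2 * ne, n_sites), dtype=np.uint8)
    het_traj = np.empty(cfg.burn_in_generations) if track_heterozygosity else None

    for gen in range(cfg.burn_in_generations):
        parents = rng.integers(0, ne, size=(ne, 2))  # mother, father per offspring
        gamete_parents = parents.T.reshape(-1)  # 2Ne parental individuals
        parent_haps = haps.reshape(ne, 2, n_sites)[gamete_parents]
        gametes = _gamete_batch(parent_haps, gmap, rng)
        mut = rng.random(gametes.shape) < u
        gametes ^= mut.astype(np.uint8)
        # offspring i gets gametes i (maternal) and ne+i (paternal)
        haps = np.concatenate([gametes[:ne, None, :], gametes[ne:, None, :]], axis=1).reshape(
            2 * ne, n_sites
        )
        if track_heterozygosity:
            p = haps.mean(axis=0)
            het_traj[gen] = float(np.mean(2 * p * (1 - p)))

    chosen = rng.choice(ne, size=n_founders, replace=False)
    founder_haps = haps.reshape(ne, 2, n_sites)[chosen]

    seg = _segregating(founder_haps)
    pruned_map = gmap.subset(seg)
    founder_haps = founder_haps[:, :, seg]

    retained = pruned_map.sites_per_chromosome
    if min_segregating_per_chromosome and int(retained.min()) < min_segregating_per_chromosome:
        short = {
            f"chr{c + 1}": int(r)
            for c, r in enumerate(retained)
            if r < min_segregating_per_chromosome
        }
        raise InsufficientVariationError(
            f"need {min_segregating_per_chromosome} segregating sites per "
            f"chromosome, shortfall: {short}"
        )

    ids = [f"F{i + 1}" for i in range(n_founders)]
    meta = {
        "candidate_sites": n_sites,
        "retained_sites": int(retained.sum()),
        "retained_per_chromosome": retained.tolist(),
    }
    if track_heterozygosity:
        meta["heterozygosity_trajectory"] = het_traj
    return HaplotypeSet(ids, founder_haps, pruned_map, metadata=meta), pruned_map


def _segregating(haps: np.ndarray) -> np.ndarray:
    flat = haps.reshape(-1, haps.shape[-1])
    freq = flat.mean(axis=0)
    return (freq > 0) & (freq < 1)


def export_map(gmap: GeneticMap, path) -> None:
    """Write the map as 3-column text: chromosome, site id, position (cM)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tsite\tcM\n")
        for c in range(gmap.n_chromosomes):
            for j, pos in enumerate(gmap.positions_morgans[c]):
                fh.write(f"chr{c + 1}\tchr{c + 1}_s{j}\t{100 * pos:.6f}\n")


def export_vcf(haps: HaplotypeSet, path) -> None:
    """Write founder genotypes as a phased biallelic VCF (text)."""
    gmap = haps.genetic_map
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(haps.ids) + "\n")
        offs = gmap.chrom_offsets
        for c in range(gmap.n_chromosomes):
            for j in range(len(gmap.positions_morgans[c])):
                s = offs[c] + j
                gts = "\t".join(
                    f"{haps.haplotypes[i, 0, s]}|{haps.haplotypes[i, 1, s]}"
                    for i in range(haps.n_individuals)
                )
                fh.write(
                    f"chr{c + 1}\t{gmap.positions_bp[c][j]}\tchr{c + 1}_s{j}"
                    f"\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
                )
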