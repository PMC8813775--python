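"""Quantitative-trait layer with Finlay-Wilkinson genotype-by-environment.

A single additive trait (standing in for an index of yield, dry matter,
disease resistance, carotenoids and sprouting) is controlled by QTN drawn
from the segregating founder sites. Each QTN allele effect is linear in
an environmental covariate w:

    a_i(w) = b_i + m_i * w

so an individual's genetic value g(w) = sum_i x_i (b_i + m_i w) is itself
linear in w — the Finlay-Wilkinson regression property. The covariate
decomposes into a year effect u_j and a year-by-location deviation
v_jl, whose variances generate the genotype-by-year and
genotype-by-location interaction variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientVariationError, InvalidNoiseError
from .founders import HaplotypeSet, Individual, _gamete_batch


@dataclass(frozen=True)
class VarianceComponents:
    """Target variance components on the base-population scale.

    ``var_GxYxL`` is always the sum of the year and location interaction
    parts; it is derived, never set.
    """

    var_G: float = 1.0
    var_GxY: float = 2.0
    var_GxL: float = 1.0

    def __post_init__(self):
        if self.var_G <= 0 or self.var_GxY < 0 or self.var_GxL < 0:
            raise ValueError("variance components must be non-negative (var_G > 0)")

    @property
    def var_GxYxL(self) -> float:
        return self.var_GxY + self.var_GxL


@dataclass
class TraitArchitecture:
    """QTN site indices with intercept and slope effects.

    ``site_indices`` index the flat site axis of the founder map. After
    construction the intercepts are scaled so the base population's
    genetic variance at w = 0 equals ``var_G`` and the slopes so the
    base-population variance of the FW slope score (sum of dosage x m) is
    exactly 1, letting environmental covariates carry the GxY / GxL
    variance targets directly.
    """

    site_indices: np.ndarray  # flat indices, grouped by chromosome
    chromosomes: np.ndarray  # chromosome index per QTN
    b: np.ndarray  # intercepts
    m: np.ndarray  # slopes
    vc: VarianceComponents

    @property
    def n_qtn(self) -> int:
        return len(self.site_indices)

    def dosage_matrix(self, individuals) -> np.ndarray:
        """(n, n_qtn) dosage matrix for Individuals or a HaplotypeSet."""
        if isinstance(individuals, HaplotypeSet):
            return individuals.dosages[:, self.site_indices].astype(np.float64)
        haps = np.stack([ind.haplotypes for ind in individuals])
        return haps.sum(axis=1)[:, self.site_indices].astype(np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosomes,
                "site_index": self.site_indices,
                "b": self.b,
                "m": self.m,
            }
        )


def _expand_population(
    founders: HaplotypeSet, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Random-mating expansion of the founders: ``n`` F1 haplotype pairs.

    Used to calibrate effect scales on a population wider than the
    handful of founder genotypes themselves.
    """
    nf = founders.n_individuals
    mothers = rng.integers(0, nf, size=n)
    fathers = (mothers + rng.integers(1, nf, size=n)) % nf  # no selfing
    mg = _gamete_batch(founders.haplotypes[mothers], founders.genetic_map, rng)
    fg = _gamete_batch(founders.haplotypes[fathers], founders.genetic_map, rng)
    return np.stack([mg, fg], axis=1)


def sample_architecture(
    founders: HaplotypeSet,
    vc: VarianceComponents,
    n_qtn_per_chrom: int = 100,
    rng: Optional[np.random.Generator] = None,
    calibration_size: int = 2000,
) -> TraitArchitecture:
    """Draw and calibrate a QTN architecture from founder variation.

    Per chromosome, ``n_qtn_per_chrom`` segregating sites are chosen at
    random; intercepts and slopes are standard-normal draws rescaled
    against a random-mating expansion of the founders (Monte-Carlo
    calibration) so realised variances hit their targets. The default
    calibration population is large enough that the remaining
    calibration error is a few percent.
    """
    rng = np.random.default_rng() if rng is None else rng
    gmap = founders.genetic_map
    offs = gmap.chrom_offsets
    per_chrom = gmap.sites_per_chromosome

    sites, chroms = [], []
    for c in range(gmap.n_chromosomes):
        avail = int(per_chrom[c])
        if avail < n_qtn_per_chrom:
            raise InsufficientVariationError(
                f"chromosome {c + 1}: {avail} segregating sites available, "
                f"{n_qtn_per_chrom} QTN requested"
            )
        pick = rng.choice(avail, size=n_qtn_per_chrom, replace=False)
        sites.append(offs[c] + np.sort(pick))
        chroms.append(np.full(n_qtn_per_chrom, c))
    site_indices = np.concatenate(sites)
    chromosomes = np.concatenate(chroms)

    b = rng.standard_normal(len(site_indices))
    m = rng.standard_normal(len(site_indices))

    pop = _expand_population(founders, calibration_size, rng)
    X = pop.sum(axis=1)[:, site_indices].astype(np.float64)
    var_b = float(np.var(X @ b))
    var_m = float(np.var(X @ m))
    if var_b <= 0 or var_m <= 0:
        raise InsufficientVariationError("calibration population shows no genetic variance")
    b = b * np.sqrt(vc.var_G / var_b)
    m = m / np.sqrt(var_m)
    return TraitArchitecture(site_indices, chromosomes, b, m, vc)


def allele_effect(arch: TraitArchitecture, i: int, w: float) -> float:
    """Effect of QTN ``i`` in an environment with covariate ``w``."""
    return float(arch.b[i] + arch.m[i] * w)


def genetic_value(ind, arch: TraitArchitecture, w: float = 0.0) -> float:
    """Sum of dosage-weighted allele effects at covariate ``w``."""
    dosage = ind.dosage if isinstance(ind, Individual) else np.asarray(ind)
    x = dosage[arch.site_indices].astype(np.float64)
    return float(x @ arch.b + (x @ arch.m) * w)


def genetic_scores(X: np.ndarray, arch: TraitArchitecture) -> tuple[np.ndarray, np.ndarray]:
    """FW intercept and slope scores (A, S) per row of a dosage matrix."""
    return X @ arch.b, X @ arch.m


@dataclass(frozen=True)
class EnvCovariates:
    """Environmental covariates, years in rows, locations in columns.

    ``w[j, l] = u[j] + v[j, l]`` with independent zero-mean normal year
    effects u and year-by-location deviations v.
    """

    w: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def n_years(self) -> int:
        return self.w.shape[0]

    @property
    def n_locations(self) -> int:
        return self.w.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.w,
            index=pd.RangeIndex(self.n_years, name="year"),
            columns=[f"loc{j + 1}" for j in range(self.n_locations)],
        )


def sample_env_covariates(
    n_years: int,
    n_locations_max: int,
    vc: VarianceComponents,
    arch: TraitArchitecture,
    rng: Optional[np.random.Generator] = None,
) -> EnvCovariates:
    """Sample the covariate matrix carrying the GxE variance targets.

    Because the architecture's slope score has unit base-population
    variance, setting var(u) = var_GxY and var(v) = var_GxL makes the
    realised genotype-by-year and genotype-by-location interaction
    variances match their targets.
    """
    rng = np.random.default_rng() if rng is None else rng
    u = rng.normal(0.0, np.sqrt(vc.var_GxY), size=n_years)
    v = rng.normal(0.0, np.sqrt(vc.var_GxL), size=(n_years, n_locations_max))
    return EnvCovariates(w=u[:, None] + v, u=u, v=v)


@dataclass(frozen=True)
class StageNoise:
    """Per-stage plot-error specification.

    Each stage is given either a target plot heritability
    h2 = var_G / (var_G + var_GxYxL + var_e) on a single-plot basis, or
    an error variance directly; the other is derived. Stage h2 defaults
    are package choices (unreplicated early stages get lower plot h2) and
    should be recalibrated against a real program's trial data.
    """

    h2: dict[str, float] = field(
        default_factory=lambda: {"CE": 0.2, "PYT": 0.3, "AYT": 0.4, "UYT": 0.45}
    )
    var_e_override: dict[str, float] = field(default_factory=dict)

    def var_e(self, stage_name: str, vc: VarianceComponents) -> float:
        if stage_name in self.var_e_override:
            ve = self.var_e_override[stage_name]
            if ve < 0:
                raise InvalidNoiseError(f"{stage_name}: negative error variance")
            return ve
        try:
            h2 = self.h2[stage_name]
        except KeyError:
            raise InvalidNoiseError(f"no noise specification for stage {stage_name!r}")
        if not 0 < h2 <= 1:
            raise InvalidNoiseError(f"{stage_name}: plot h2 must be in (0, 1], got {h2}")
        return (vc.var_G + vc.var_GxYxL) * (1 - h2) / h2

    def plot_h2(self, stage_name: str, vc: VarianceComponents) -> float:
        ve = self.var_e(stage_name, vc)
        return vc.var_G / (vc.var_G + vc.var_GxYxL + ve)


def phenotype(
    cohort: Sequence[Individual],
    stage,
    env: EnvCovariates,
    noise: StageNoise,
    year: int,
    rng: np.random.Generator,
    arch: TraitArchitecture = None,
    vc: Optional[VarianceComponents] = None,
    record: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Phenotype a cohort at one stage in one year.

    Every entry gets ``n_locations x reps_per_location`` plot values
    ``g(w[year, loc]) + e`` with e ~ N(0, var_e(stage)); the entry mean
    averages the plots. Returns (plot records, entry means) and, when
    ``record`` is set, appends the entry mean to each individual's stage
    history.
    """
    vc = arch.vc if vc is None else vc
    n_loc = stage.evaluation.n_locations
    reps = stage.evaluation.reps_per_location
    if year >= env.n_years or n_loc > env.n_locations:
        raise ValueError(
            f"covariate matrix ({env.n_years} years x {env.n_locations} locations) "
            f"does not cover year {year} at {n_loc} locations"
        )
    ve = noise.var_e(stage.name, vc)
    X = arch.dosage_matrix(cohort)
    A, S = genetic_scores(X, arch)
    w = env.w[year, :n_loc]  # (n_loc,)
    g = A[:, None] + S[:, None] * w[None, :]  # (n, n_loc)
    plots = g[:, :, None] + rng.normal(0.0, np.sqrt(ve), size=(len(cohort), n_loc, reps))
    entry_means = plots.mean(axis=(1, 2))

    records = pd.DataFrame(
        {
            "entry": np.repeat([ind.id for ind in cohort], n_loc * reps),
            "location": np.tile(np.repeat(np.arange(1, n_loc + 1), reps), len(cohort)),
            "rep": np.tile(np.arange(1, reps + 1), len(cohort) * n_loc),
            "value": plots.reshape(-1),
        }
    )
    if record:
        for ind, mean in zip(cohort, entry_means):
            ind.record_phenotype(stage.name, year, float(mean))
    return records, entry_means


def export_architecture(arch: TraitArchitecture, path) -> None:
    arch.to_frame().to_csv(path, index=False)


def import_architecture(path, vc: VarianceComponents) -> TraitArchitecture:
    df = pd.read_csv(path)
    return TraitArchitecture(
        site_indices=df["site_index"].to_numpy(),
        chromosomes=df["chrom"].to_numpy(),
        b=df["b"].to_numpy(float),
        m=df["m"].to_numpy(float),
        vc=vc,
    )
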