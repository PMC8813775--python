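"""Stage-gate program engine: crossing, advancement, parent recycling.

Runs a breeding scheme year by year with overlapping cohorts: every
simulated year each evaluation cohort is phenotyped and truncation-
selected into the next stage, the seedling nursery moves to clonal
evaluation, and a new crossing block is assembled by recycling the
best-performing clones from the stages named in the recycling policy.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConstraintError, StateError
from .founders import (
    GenomeConfig,
    GeneticMap,
    Individual,
    _gamete_batch,
    simulate_founders,
)
from .scheme import BreedingScheme, StageDefinition
from .traits import (
    EnvCovariates,
    StageNoise,
    TraitArchitecture,
    VarianceComponents,
    genetic_scores,
    phenotype,
    sample_architecture,
    sample_env_covariates,
)


@dataclass(frozen=True)
class RecyclingPolicy:
    """Which stages feed the crossing block, and in what proportions."""

    quotas: dict[str, float]

    def __post_init__(self):
        total = sum(self.quotas.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"policy proportions must sum to 1, got {total}")
        if any(not 0 <= p <= 1 for p in self.quotas.values()):
            raise ValueError("proportions must lie in [0, 1]")

    def validate_against(self, scheme: BreedingScheme) -> None:
        recycling = set(scheme.recycling_stage_names)
        missing = [s for s in self.quotas if s not in recycling]
        if missing:
            raise ValueError(
                f"policy stages {missing} are not recycling sources in scheme {scheme.id!r}"
            )

    def apportion(self, n_parents: int, stage_order: Sequence[str]) -> dict[str, int]:
        """Largest-remainder apportionment of parents; ties favour the
        earlier stage in ``stage_order``."""
        names = [s for s in stage_order if s in self.quotas]
        exact = {s: n_parents * self.quotas[s] for s in names}
        counts = {s: int(np.floor(exact[s])) for s in names}
        left = n_parents - sum(counts.values())
        by_remainder = sorted(
            names, key=lambda s: (-(exact[s] - counts[s]), stage_order.index(s))
        )
        for s in by_remainder[:left]:
            counts[s] += 1
        return counts


MIXED_PYT_AYT = RecyclingPolicy({"PYT": 0.5, "AYT": 0.5})


@dataclass(frozen=True)
class CrossPlan:
    """Parent index pairs plus the common family size."""

    pairs: list[tuple[int, int]]  # (mother_idx, father_idx)
    n_progeny_per_cross: int

    @property
    def n_crosses(self) -> int:
        return len(self.pairs)

    @property
    def total_progeny(self) -> int:
        return self.n_crosses * self.n_progeny_per_cross


def plan_crosses(
    parents: Sequence,
    n_crosses: int,
    n_progeny: int,
    allow_reciprocals: bool,
    rng: np.random.Generator,
) -> CrossPlan:
    """Sample distinct non-self parent pairs for one crossing block.

    Pairs are unordered unless reciprocals are allowed. Whenever the
    plan is large enough (n_crosses >= ceil(nP / 2)), a random
    near-perfect matching is laid down first so every parent appears in
    at least one cross; remaining crosses are drawn uniformly without
    replacement from the unused pairs.
    """
    np_ = len(parents)
    if np_ < 2:
        raise ConstraintError("need at least two parents to cross")
    cap = np_ * (np_ - 1) if allow_reciprocals else np_ * (np_ - 1) // 2
    if n_crosses > cap:
        kind = "ordered" if allow_reciprocals else "unordered"
        raise ConstraintError(
            f"{n_crosses} crosses requested but only {cap} distinct {kind} "
            f"non-self pairs exist for {np_} parents"
        )

    chosen: list[tuple[int, int]] = []
    used: set[tuple[int, int]] = set()

    def key(i, j):
        return (i, j) if allow_reciprocals else (min(i, j), max(i, j))

    if n_crosses >= (np_ + 1) // 2:
        order = rng.permutation(np_)
        for k in range(0, np_ - 1, 2):
            pair = (int(order[k]), int(order[k + 1]))
            chosen.append(pair)
            used.add(key(*pair))
        if np_ % 2:  # odd count: mate the leftover with a random partner;
            # the leftover appears in no matching pair, so no duplicate arises
            leftover = int(order[-1])
            partner = int(order[rng.integers(0, np_ - 1)])
            pair = (leftover, partner)
            chosen.append(pair)
            used.add(key(*pair))
        chosen = chosen[:n_crosses]

    if len(chosen) < n_crosses:
        if allow_reciprocals:
            all_pairs = [(i, j) for i in range(np_) for j in range(np_) if i != j]
        else:
            all_pairs = [(i, j) for i in range(np_) for j in range(i + 1, np_)]
        remaining = [p for p in all_pairs if key(*p) not in used]
        extra = rng.choice(len(remaining), size=n_crosses - len(chosen), replace=False)
        chosen.extend(remaining[int(e)] for e in sorted(extra))

    return CrossPlan(pairs=chosen, n_progeny_per_cross=n_progeny)


def advance(cohort: Sequence[Individual], stage: StageDefinition, n_select: int) -> list[Individual]:
    """Truncation-select the top entries on this stage's entry means.

    Ties break by ascending id; the return order is descending merit.
    """
    if n_select > len(cohort):
        raise ConstraintError(f"cannot select {n_select} from {len(cohort)} entries")
    try:
        keyed = [(-ind.entry_mean(stage.name), ind.id, ind) for ind in cohort]
    except KeyError as exc:
        raise StateError(str(exc)) from exc
    keyed.sort(key=lambda t: (t[0], t[1]))
    return [ind for _, _, ind in keyed[:n_select]]


@dataclass
class ProgramState:
    """Everything a running program carries between years."""

    scheme: BreedingScheme
    arch: TraitArchitecture
    env: EnvCovariates
    noise: StageNoise
    rng: np.random.Generator
    gmap: GeneticMap
    year: int = 0
    cohorts: dict[str, list[Individual]] = field(default_factory=dict)
    uyt_second_year: list[Individual] = field(default_factory=list)
    parents: list[Individual] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)
    parent_ages: list[float] = field(default_factory=list)

    def fork(self) -> "ProgramState":
        """Deep copy for common-burn-in treatment forking."""
        return copy.deepcopy(self)


def select_parents(
    state: ProgramState, policy: RecyclingPolicy, n_parents: int
) -> list[Individual]:
    """Recycle the best clones from the policy stages into a crossing block."""
    stage_order = [s.name for s in state.scheme.stages]
    quotas = policy.apportion(n_parents, stage_order)
    parents: list[Individual] = []
    for name, quota in quotas.items():
        if quota == 0:
            continue
        cohort = state.cohorts.get(name, [])
        if not cohort:
            raise StateError(f"no phenotyped cohort at stage {name!r} this year")
        if quota > len(cohort):
            raise ConstraintError(
                f"quota {quota} exceeds the {len(cohort)}-entry cohort at {name!r}"
            )
        parents.extend(advance(cohort, state.scheme.stage(name), quota))
    return parents


def _policy_ready(state: ProgramState, policy: RecyclingPolicy) -> bool:
    return all(
        state.cohorts.get(name) and state.cohorts[name][0].stage_history
        for name, q in policy.quotas.items()
        if q > 0
    )


def run_year(state: ProgramState, treatment) -> ProgramState:
    """Advance the program by one simulated year.

    Within one simulated year: every occupied trial cohort is phenotyped
    and its genetic mean/variance at w = 0 recorded; parents are recycled
    from this year's data (or the current block is kept while the ladder
    fills); a new crossing block produces the F1 cohort, which is
    multiplied in the seedling nursery the same year; finally every
    cohort moves up one stage. Crossing and nursery multiplication share
    a year, so a clone crossed in year y reaches clonal evaluation in
    year y+1 and the preliminary yield trial in year y+2.
    """
    scheme = state.scheme
    trial_stages = [s for s in scheme.evaluation_stages if s.evaluation.design_label != "nursery"]
    nursery = next(
        (s for s in scheme.evaluation_stages if s.evaluation.design_label == "nursery"), None
    )

    # 1. phenotype + record
    for s in trial_stages:
        cohort = state.cohorts.get(s.name)
        if cohort:
            phenotype(cohort, s, state.env, state.noise, state.year, state.rng, arch=state.arch)
            _record(state, s.name, cohort)
    if state.uyt_second_year:
        # a multi-year terminal trial is phenotyped again in its second
        # season; product-development bookkeeping, not recorded as a new row
        last = scheme.stages[-1]
        if last.n_years > 1:
            phenotype(
                state.uyt_second_year, last, state.env, state.noise, state.year, state.rng,
                arch=state.arch,
            )

    # 2. recycle parents (this year's data) or fall back to the current block
    policy = treatment.policy
    if _policy_ready(state, policy):
        new_parents = select_parents(state, policy, treatment.n_parents)
        ages = [state.year - p.birth_year + 1 for p in new_parents]
        state.parent_ages.append(float(np.mean(ages)))
        state.parents = new_parents
    elif not state.parents:
        raise StateError("no parents available and recycling sources are empty")

    # 3. cross; the F1 sits in the seedling nursery this same year
    plan = plan_crosses(
        state.parents,
        treatment.n_crosses,
        treatment.n_progeny_per_cross,
        treatment.allow_reciprocals,
        state.rng,
    )
    f1 = _execute_plan(state, plan)
    if nursery is not None:
        _record(state, nursery.name, f1)

    # 4. shift cohorts up the ladder; the nursery feeds the first trial stage
    new_cohorts: dict[str, list[Individual]] = {}
    prev: Optional[StageDefinition] = None
    for s in trial_stages:
        if prev is None:
            new_cohorts[s.name] = f1  # multiplication: no selection, no loss
        else:
            source = state.cohorts.get(prev.name)
            if source:
                new_cohorts[s.name] = advance(source, prev, s.selection.n_entries_in)
        prev = s
    last = scheme.stages[-1]
    if last.n_years > 1:
        state.uyt_second_year = state.cohorts.get(last.name, [])
    if nursery is not None:
        new_cohorts[nursery.name] = f1

    state.cohorts = new_cohorts
    state.year += 1
    return state


def _execute_plan(state: ProgramState, plan: CrossPlan) -> list[Individual]:
    """Make every planned cross in one batched meiosis pass."""
    n_per = plan.n_progeny_per_cross
    total = plan.total_progeny
    mother_idx = np.repeat([p[0] for p in plan.pairs], n_per)
    father_idx = np.repeat([p[1] for p in plan.pairs], n_per)
    parent_haps = np.stack([p.haplotypes for p in state.parents])
    mg = _gamete_batch(parent_haps[mother_idx], state.gmap, state.rng)
    fg = _gamete_batch(parent_haps[father_idx], state.gmap, state.rng)
    haps = np.stack([mg, fg], axis=1)
    out = []
    y = state.year
    for k, (mi, fi) in enumerate(plan.pairs):
        mother, father = state.parents[mi], state.parents[fi]
        for j in range(n_per):
            idx = k * n_per + j
            out.append(
                Individual(
                    id=f"Y{y}C{k}P{j}",
                    haplotypes=haps[idx],
                    mother_id=mother.id,
                    father_id=father.id,
                    birth_year=y,
                )
            )
    assert len(out) == total
    return out


def _record(state: ProgramState, stage_name: str, cohort: Sequence[Individual]) -> None:
    X = state.arch.dosage_matrix(cohort)
    g, _ = genetic_scores(X, state.arch)
    state.records.append(
        {
            "year": state.year,
            "stage": stage_name,
            "n": len(cohort),
            "genetic_mean": float(g.mean()),
            "genetic_var": float(g.var(ddof=1)) if len(g) > 1 else 0.0,
        }
    )


@dataclass(frozen=True)
class BaselineTreatment:
    """Crossing-block configuration used during the recent-breeding burn-in."""

    n_parents: int = 4
    n_crosses: int = 12
    n_progeny_per_cross: int = 136
    policy: RecyclingPolicy = MIXED_PYT_AYT
    allow_reciprocals: bool = True
    id: str = "baseline"


def initialize_program(
    scheme: BreedingScheme,
    genome_cfg: GenomeConfig,
    vc: VarianceComponents = VarianceComponents(),
    noise: Optional[StageNoise] = None,
    n_qtn_per_chrom: int = 100,
    n_founders: int = 4,
    total_years: int = 60,
    seed: int = 0,
) -> ProgramState:
    """Build founders, trait architecture and covariates for a fresh program."""
    cfg = GenomeConfig(**{**genome_cfg.__dict__, "seed": seed})
    founders, gmap = simulate_founders(
        cfg, n_founders=n_founders, min_segregating_per_chromosome=n_qtn_per_chrom
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    arch = sample_architecture(founders, vc, n_qtn_per_chrom, rng)
    max_loc = max(s.evaluation.n_locations for s in scheme.evaluation_stages)
    env = sample_env_covariates(total_years + 1, max_loc, vc, arch, rng)
    state = ProgramState(
        scheme=scheme,
        arch=arch,
        env=env,
        noise=noise or StageNoise(),
        rng=rng,
        gmap=gmap,
        parents=founders.individuals(),
    )
    return state


def run_program(
    scheme: BreedingScheme,
    treatment,
    n_years: int,
    burn_in_years: int = 20,
    seed: int = 0,
    genome_cfg: Optional[GenomeConfig] = None,
    vc: VarianceComponents = VarianceComponents(),
    noise: Optional[StageNoise] = None,
    n_qtn_per_chrom: int = 100,
) -> pd.DataFrame:
    """Burn the baseline scheme in, then run one treatment; tidy records out.

    The burn-in applies the baseline crossing block (4 parents, 12
    reciprocal crosses of 136) with mixed PYT+AYT recycling; after
    ``burn_in_years`` the treatment's configuration takes over for
    ``n_years``. The ``year`` column is re-indexed so the last burn-in
    year is 0. Fully deterministic given ``seed``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    genome_cfg = genome_cfg or GenomeConfig()
    state = initialize_program(
        scheme,
        genome_cfg,
        vc=vc,
        noise=noise,
        n_qtn_per_chrom=n_qtn_per_chrom,
        total_years=burn_in_years + n_years,
        seed=seed,
    )
    baseline = BaselineTreatment()
    for _ in range(burn_in_years):
        run_year(state, baseline)
    for _ in range(n_years):
        run_year(state, treatment)
    return results_table(state, burn_in_years)


def results_table(state: ProgramState, burn_in_years: int) -> pd.DataFrame:
    df = pd.DataFrame(state.records)
    df["year"] = df["year"] - (burn_in_years - 1)
    return df[["year", "stage", "n", "genetic_mean", "genetic_var"]]
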