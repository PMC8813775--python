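"""Treatment grids and the resource-allocation optimisation experiment.

Enumerates all (parents, crosses, progeny-per-cross) configurations at a
fixed F1 size, runs them over Monte-Carlo replicates with a common
founder/burn-in realisation per replicate (a paired design: every
treatment contrast is within-replicate), and summarises genetic gain
relative to the end of burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (
    BaselineTreatment,
    MIXED_PYT_AYT,
    RecyclingPolicy,
    run_year,
    initialize_program,
    results_table,
)
from .errors import ConfigurationError
from .founders import GenomeConfig
from .scheme import BreedingScheme
from .traits import StageNoise, VarianceComponents

PARENT_LEVELS = (4, 8, 16, 32, 64)
CROSS_LEVELS = (6, 12, 24, 48, 96, 204, 408, 816)
TOTAL_F1 = 1632


@dataclass(frozen=True)
class Treatment:
    """One crossing-block configuration at fixed total F1 size."""

    n_parents: int
    n_crosses: int
    n_progeny_per_cross: int
    policy: RecyclingPolicy = MIXED_PYT_AYT
    allow_reciprocals: bool = False
    id: str = ""

    def __post_init__(self):
        cap = self.n_parents * (self.n_parents - 1)
        if not self.allow_reciprocals:
            cap //= 2
        if self.n_crosses > cap:
            raise ConfigurationError(
                f"{self.n_crosses} crosses exceed the cap of {cap} for "
                f"{self.n_parents} parents"
            )
        if not self.id:
            object.__setattr__(
                self, "id", f"p{self.n_parents}c{self.n_crosses}"
            )

    @property
    def total_f1(self) -> int:
        return self.n_crosses * self.n_progeny_per_cross


def enumerate_treatments(
    parent_levels: Sequence[int] = PARENT_LEVELS,
    cross_levels: Sequence[int] = CROSS_LEVELS,
    total_f1: int = TOTAL_F1,
    policy: RecyclingPolicy = MIXED_PYT_AYT,
) -> list[Treatment]:
    """All admissible (nParents, nCrosses) pairs at a fixed F1 size.

    A pair is admitted when the cross count divides ``total_f1`` exactly
    and does not exceed the half-diallel cap nP(nP-1)/2. Ordering is
    deterministic: parents ascending, then crosses ascending.
    """
    for nc in cross_levels:
        if total_f1 % nc:
            raise ConfigurationError(
                f"{nc} crosses do not divide the F1 size {total_f1} evenly"
            )
    out = []
    for np_ in sorted(parent_levels):
        cap = np_ * (np_ - 1) // 2
        for nc in sorted(cross_levels):
            if nc <= cap:
                out.append(
                    Treatment(
                        n_parents=np_,
                        n_crosses=nc,
                        n_progeny_per_cross=total_f1 // nc,
                        policy=policy,
                    )
                )
    return out


def run_grid(
    treatments: Sequence[Treatment],
    scheme: BreedingScheme,
    n_replicates: int = 10,
    n_years: int = 20,
    master_seed: int = 0,
    burn_in_years: int = 20,
    genome_cfg: Optional[GenomeConfig] = None,
    vc: VarianceComponents = VarianceComponents(),
    noise: Optional[StageNoise] = None,
    n_qtn_per_chrom: int = 100,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every treatment over common-burn-in replicates.

    Per replicate one founder genome and one burn-in of the baseline
    scheme are simulated; each treatment then continues from a fork of
    that state, so the burn-in segment of the records is identical
    across treatments within a replicate. Deterministic given
    ``master_seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    genome_cfg = genome_cfg or GenomeConfig()
    seeds = np.random.SeedSequence(master_seed).generate_state(n_replicates) % (2**31)
    frames = []
    for rep in range(n_replicates):
        if progress:
            print(f"replicate {rep + 1}/{n_replicates}", flush=True)
        base = initialize_program(
            scheme,
            genome_cfg,
            vc=vc,
            noise=noise,
            n_qtn_per_chrom=n_qtn_per_chrom,
            total_years=burn_in_years + n_years,
            seed=int(seeds[rep]),
        )
        baseline = BaselineTreatment()
        for _ in range(burn_in_years):
            run_year(base, baseline)
        for trt in treatments:
            state = base.fork()
            for _ in range(n_years):
                run_year(state, trt)
            df = results_table(state, burn_in_years)
            df.insert(0, "treatment_id", trt.id)
            df.insert(0, "replicate", rep)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class GridSummary:
    """Per (treatment, year) genetic gain relative to the end of burn-in."""

    stage: str
    baseline_year: int
    table: pd.DataFrame  # treatment_id, year, gain, se, n_replicates
    per_replicate: pd.DataFrame  # treatment_id, replicate, year, gain


def summarize(
    results: pd.DataFrame, stage: str = "CE", baseline_year: int = 0, relative: bool = False
) -> GridSummary:
    """Collapse a results table to mean gain with standard errors.

    Gain for a (replicate, treatment, year) cell is the stage genetic
    mean minus the same replicate/treatment's mean at ``baseline_year``;
    ``relative`` rescales by the baseline mean's magnitude. SE is the
    across-replicate standard deviation over sqrt(n); with a single
    replicate it is reported as NaN.
    """
    sub = results[results["stage"] == stage]
    if sub.empty:
        raise KeyError(f"stage {stage!r} not present in results")
    base = (
        sub[sub["year"] == baseline_year]
        .set_index(["replicate", "treatment_id"])["genetic_mean"]
    )
    per = sub.copy()
    keys = list(zip(per["replicate"], per["treatment_id"]))
    per["gain"] = per["genetic_mean"].to_numpy() - base.loc[keys].to_numpy()
    if relative:
        per["gain"] = per["gain"] / np.abs(base.loc[keys].to_numpy())
    per = per[["treatment_id", "replicate", "year", "gain"]].reset_index(drop=True)

    grouped = per.groupby(["treatment_id", "year"], sort=True)["gain"]
    table = grouped.agg(gain="mean", sd="std", n_replicates="count").reset_index()
    table["se"] = np.where(
        table["n_replicates"] > 1,
        table["sd"] / np.sqrt(table["n_replicates"]),
        np.nan,
    )
    table = table[["treatment_id", "year", "gain", "se", "n_replicates"]]
    return GridSummary(stage=stage, baseline_year=baseline_year, table=table, per_replicate=per)


@dataclass(frozen=True)
class Contrast:
    """Paired mean-gain difference between two treatment sets."""

    difference: float
    se: float
    direction: str  # 'positive', 'negative' or 'indistinguishable'
    n_replicates: int


def compare(
    summary: GridSummary,
    horizon_year: int,
    set_a: Sequence[str],
    set_b: Sequence[str],
) -> Contrast:
    """Contrast mean gain of treatment set A against set B at a horizon.

    Uses the paired (within-replicate) differences that the common-
    burn-in design affords; the direction label is attached only when
    the difference exceeds twice its standard error.
    """
    per = summary.per_replicate
    at = per[per["year"] == horizon_year]
    if at.empty:
        raise KeyError(f"no records at year {horizon_year}")

    def rep_means(ids):
        sub = at[at["treatment_id"].isin(ids)]
        if sub.empty:
            raise KeyError(f"no records for treatments {list(ids)}")
        return sub.groupby("replicate")["gain"].mean()

    a, b = rep_means(set_a), rep_means(set_b)
    common = a.index.intersection(b.index)
    diffs = (a.loc[common] - b.loc[common]).to_numpy()
    mean = float(diffs.mean())
    n = len(diffs)
    se = float(diffs.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    if np.isfinite(se) and abs(mean) > 2 * se:
        direction = "positive" if mean > 0 else "negative"
    else:
        direction = "indistinguishable"
    return Contrast(difference=mean, se=se, direction=direction, n_replicates=n)


def plot_gain_curves(summary: GridSummary, ax=None):
    """Gain vs cross count, coloured by parent number (optional helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = summary.table
    horizon = table["year"].max()
    at = table[table["year"] == horizon].copy()
    at["n_parents"] = at["treatment_id"].str.extract(r"p(\d+)c").astype(int)
    at["n_crosses"] = at["treatment_id"].str.extract(r"c(\d+)$").astype(int)
    for np_, grp in at.groupby("n_parents"):
        grp = grp.sort_values("n_crosses")
        ax.errorbar(
            grp["n_crosses"], grp["gain"], yerr=grp["se"], marker="o",
            label=f"{np_} parents",
        )
    ax.set_xscale("log", base=2)
    ax.set_xlabel("number of crosses")
    ax.set_ylabel(f"genetic gain at year {horizon} ({summary.stage})")
    ax.legend()
    return ax


def desk_profile() -> dict:
    """Reduced problem sizes for a single-workstation run.

    200 candidate sites and 50 QTN per chromosome, 10 replicates and a
    20-year horizon keep a multi-treatment grid in the minutes range
    while preserving the qualitative behaviour of the full-scale study.
    """
    return {
        "genome_cfg": GenomeConfig(sites_per_chromosome=200),
        "n_qtn_per_chrom": 50,
        "n_replicates": 10,
        "n_years": 20,
        "burn_in_years": 20,
    }
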