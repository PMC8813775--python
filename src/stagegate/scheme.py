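"""Machine-readable breeding schemes: pipelines, market segments, stages.

A breeding scheme is the blueprint of a breeding strategy: the ordered
crossing, evaluation and selection (CES) decisions made at each stage of
a stage-gate pipeline, linked to the market segments the pipeline serves.
This module provides the domain types, JSON/CSV (de)serialisation,
structural validation, derived program metrics (selected percentages,
expected cycle time, plot counts) and DOT flowchart export.
"""

from __future__ import annotations

import csv
import io
import json
import math
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import (
    DegenerateStageError,
    SchemeFormatError,
    SchemeValidationError,
)

SCHEMA_VERSION = "1.0"

# Controlled feature vocabularies for market segments: the client being
# served, the target population of environments, and the final product.
CLIENT_FEATURES = frozenset(
    {"geographical region", "income", "education", "farm size"}
)
ENVIRONMENT_FEATURES = frozenset(
    {
        "temperature",
        "humidity",
        "vegetation",
        "water availability",
        "soil fertility",
        "altitude",
        "soil ph",
        "production system",
        "prevailing biotic stresses",
    }
)
PRODUCT_FEATURES = frozenset(
    {"mode of reproduction", "maturity", "color", "shape", "biofortification", "end use"}
)


class TraitCategory(str, Enum):
    quality = "quality"
    survival = "survival"
    output = "output"
    agronomic = "agronomic"


class TraitDirection(str, Enum):
    at_least = "at_least"
    at_most = "at_most"
    target_range = "target_range"


class MarketSegment(BaseModel):
    """Clients x target environments x product features served by a pipeline."""

    id: str
    client_features: dict[str, str] = Field(default_factory=dict)
    environment_features: dict[str, str] = Field(default_factory=dict)
    product_features: dict[str, str] = Field(default_factory=dict)

    @field_validator("client_features")
    @classmethod
    def _client_keys(cls, v):
        _check_keys(v, CLIENT_FEATURES, "client_features")
        return v

    @field_validator("environment_features")
    @classmethod
    def _env_keys(cls, v):
        _check_keys(v, ENVIRONMENT_FEATURES, "environment_features")
        return v

    @field_validator("product_features")
    @classmethod
    def _product_keys(cls, v):
        _check_keys(v, PRODUCT_FEATURES, "product_features")
        return v


def _check_keys(mapping, allowed, label):
    unknown = sorted(set(k.lower() for k in mapping) - allowed)
    if unknown:
        raise ValueError(f"unknown {label} keys: {unknown}")


class TraitTarget(BaseModel):
    """One trait threshold in a product profile."""

    name: str
    category: TraitCategory
    direction: TraitDirection
    bound: Optional[float] = None
    upper_bound: Optional[float] = None
    unit: str = ""

    @model_validator(mode="after")
    def _finite_bound(self):
        bounds = [b for b in (self.bound, self.upper_bound) if b is not None]
        if not bounds or not all(math.isfinite(b) for b in bounds):
            raise ValueError(f"trait {self.name!r} needs at least one finite bound")
        if self.direction is TraitDirection.target_range and self.upper_bound is None:
            raise ValueError(f"trait {self.name!r}: target_range needs upper_bound")
        return self


class ProductProfile(BaseModel):
    """Trait-by-trait release thresholds for one market segment."""

    segment_id: str
    traits: list[TraitTarget]


class EvaluationDecisions(BaseModel):
    """Field-trial layout decisions for one stage."""

    n_locations: int = Field(ge=1, default=1)
    reps_per_location: int = Field(ge=1, default=1)
    design_label: str = ""
    plot_width: Optional[float] = None
    plot_length: Optional[float] = None
    plot_units: str = "m"
    n_checks: int = Field(ge=0, default=0)
    # open vocabulary: any further recorded evaluation decision
    extra: dict[str, Union[str, float, int]] = Field(default_factory=dict)


class SelectionDecisions(BaseModel):
    """Advancement decisions for one stage."""

    n_entries_in: int = Field(ge=0)
    n_selected_out: int = Field(ge=0)
    selection_method: str = "truncation"
    surrogate_of_merit: str = "phenotype"
    recycling_source: bool = False
    extra: dict[str, Union[str, float, int]] = Field(default_factory=dict)


class CrossingDecisions(BaseModel):
    """Mating decisions for a crossing stage."""

    n_parents: Optional[int] = None
    n_crosses: Optional[int] = None
    n_progeny_per_cross: Optional[int] = None
    coupling_method: str = "random"
    allow_reciprocals: bool = False
    extra: dict[str, Union[str, float, int]] = Field(default_factory=dict)


class StageDefinition(BaseModel):
    """One pipeline stage with its CES decisions.

    ``year`` is either a single 1-based year index or a ``(start, end)``
    range for stages evaluated across more than one season (e.g. a
    uniform yield trial spanning years 5-6).
    """

    name: str
    year: Union[int, tuple[int, int]]
    evaluation: EvaluationDecisions = Field(default_factory=EvaluationDecisions)
    selection: SelectionDecisions
    crossing: Optional[CrossingDecisions] = None

    @field_validator("year", mode="before")
    @classmethod
    def _coerce_year(cls, v):
        if isinstance(v, (list, tuple)):
            start, end = int(v[0]), int(v[1])
            if start == end:
                return start
            return (start, end)
        return int(v)

    @model_validator(mode="after")
    def _positive_years(self):
        if self.year_start < 1 or self.year_end < self.year_start:
            raise ValueError(f"stage {self.name!r}: invalid year {self.year!r}")
        return self

    @property
    def year_start(self) -> int:
        return self.year[0] if isinstance(self.year, tuple) else self.year

    @property
    def year_end(self) -> int:
        return self.year[1] if isinstance(self.year, tuple) else self.year

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def is_crossing(self) -> bool:
        return self.crossing is not None


class BreedingScheme(BaseModel):
    """Ordered stage table plus market-segment links."""

    id: str
    pipeline_id: str = ""
    segment_ids: list[str] = Field(default_factory=list)
    stages: list[StageDefinition]
    market_segments: list[MarketSegment] = Field(default_factory=list)
    product_profiles: list[ProductProfile] = Field(default_factory=list)

    @property
    def n_stage_years(self) -> int:
        """Stage count with multi-year stages counted once per year."""
        return sum(s.n_years for s in self.stages)

    def stage(self, name: str) -> StageDefinition:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def crossing_stage(self) -> StageDefinition:
        return self.stages[0]

    @property
    def evaluation_stages(self) -> list[StageDefinition]:
        return [s for s in self.stages if not s.is_crossing]

    @property
    def recycling_stage_names(self) -> list[str]:
        return [s.name for s in self.stages if s.selection.recycling_source]


class Violation(BaseModel):
    """One validation breach: which stage, which field, which rule."""

    stage: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.stage}.{self.field}] {self.rule}"


def validate_scheme(scheme: BreedingScheme) -> list[Violation]:
    """Check cross-stage invariants; violations are data, not exceptions."""
    out: list[Violation] = []
    stages = scheme.stages
    if not stages:
        return [Violation(stage="<scheme>", field="stages", rule="stage list is empty")]

    if not stages[0].is_crossing:
        out.append(
            Violation(
                stage=stages[0].name,
                field="crossing",
                rule="first stage must be the crossing stage",
            )
        )
    for s in stages[1:]:
        if s.is_crossing:
            out.append(
                Violation(
                    stage=s.name,
                    field="crossing",
                    rule="only the head stage may carry crossing decisions",
                )
            )

    for s in stages:
        if s.selection.n_selected_out > s.selection.n_entries_in:
            out.append(
                Violation(
                    stage=s.name,
                    field="selection.n_selected_out",
                    rule=(
                        f"n_selected_out ({s.selection.n_selected_out}) exceeds "
                        f"n_entries_in ({s.selection.n_entries_in})"
                    ),
                )
            )

    # conservation along the evaluation chain: what leaves stage k enters k+1
    evals = scheme.evaluation_stages
    for prev, nxt in zip(evals, evals[1:]):
        if nxt.selection.n_entries_in != prev.selection.n_selected_out:
            out.append(
                Violation(
                    stage=nxt.name,
                    field="selection.n_entries_in",
                    rule=(
                        f"entries in ({nxt.selection.n_entries_in}) != "
                        f"{prev.name} selected out ({prev.selection.n_selected_out})"
                    ),
                )
            )

    if not any(s.selection.recycling_source for s in stages):
        out.append(
            Violation(
                stage="<scheme>",
                field="selection.recycling_source",
                rule="no stage is flagged as a recycling source",
            )
        )

    years = [s.year_start for s in stages]
    if years != sorted(years):
        out.append(
            Violation(
                stage="<scheme>",
                field="year",
                rule="stage years must be non-decreasing in stage order",
            )
        )

    seen = set()
    for seg in scheme.market_segments:
        if seg.id in seen:
            out.append(
                Violation(stage="<scheme>", field="market_segments", rule=f"duplicate segment id {seg.id!r}")
            )
        seen.add(seg.id)
    for prof in scheme.product_profiles:
        if scheme.market_segments and prof.segment_id not in seen:
            out.append(
                Violation(
                    stage="<scheme>",
                    field="product_profiles",
                    rule=f"segment_id {prof.segment_id!r} does not resolve",
                )
            )
    return out


# ---------------------------------------------------------------------------
# serialisation


def _canonical_dict(scheme: BreedingScheme) -> dict:
    doc = scheme.model_dump(mode="json", exclude_none=True, exclude_defaults=True)
    # exclude_defaults drops required-with-default fields we want explicit
    doc["stages"] = [
        s.model_dump(mode="json", exclude_none=True) for s in scheme.stages
    ]
    return {"schema_version": SCHEMA_VERSION, "scheme": doc}


def save_scheme(scheme: BreedingScheme, path: Union[str, Path]) -> None:
    """Write canonical JSON (sorted keys, 2-space indent, UTF-8)."""
    payload = json.dumps(_canonical_dict(scheme), indent=2, sort_keys=True, ensure_ascii=False)
    Path(path).write_text(payload + "\n", encoding="utf-8")


def load_scheme(path: Union[str, Path], format: str = "json") -> BreedingScheme:
    """Load and validate a scheme from JSON or a CSV stage table.

    Raises :class:`SchemeFormatError` on parse failure and
    :class:`SchemeValidationError` (listing every breach) when structural
    invariants fail.
    """
    path = Path(path)
    if not path.exists():
        raise SchemeFormatError(f"no such file: {path}")
    if format == "json":
        scheme = _load_json(path)
    elif format == "csv":
        scheme = _load_csv(path)
    else:
        raise SchemeFormatError(f"unknown format {format!r}")
    violations = validate_scheme(scheme)
    if violations:
        raise SchemeValidationError(violations)
    return scheme


def _load_json(path: Path) -> BreedingScheme:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemeFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    body = doc.get("scheme", doc) if isinstance(doc, dict) else None
    if not isinstance(body, dict):
        raise SchemeFormatError(f"{path}: top level must be an object")
    try:
        return BreedingScheme.model_validate(body)
    except Exception as exc:
        raise SchemeFormatError(f"{path}: {exc}") from exc


# CSV dialect: one row per stage, decisions in columns with a fixed header
# vocabulary mirroring the tabular stage x decision view of a scheme.
_CSV_COLUMNS = [
    "stage",
    "year_start",
    "year_end",
    "n_entries_in",
    "n_selected_out",
    "selection_method",
    "surrogate_of_merit",
    "recycling_source",
    "n_locations",
    "reps_per_location",
    "design_label",
    "n_checks",
    "n_parents",
    "n_crosses",
    "n_progeny_per_cross",
    "coupling_method",
    "allow_reciprocals",
]


def _load_csv(path: Path) -> BreedingScheme:
    try:
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            unknown = [c for c in header if c not in _CSV_COLUMNS]
            if unknown:
                raise SchemeFormatError(f"{path}: unknown columns {unknown}")
            if "stage" not in header or "n_entries_in" not in header:
                raise SchemeFormatError(f"{path}: required columns 'stage', 'n_entries_in' missing")
            rows = list(reader)
    except csv.Error as exc:
        raise SchemeFormatError(f"{path}: CSV parse failure: {exc}") from exc

    stages = []
    for i, row in enumerate(rows, start=2):
        try:
            stages.append(_stage_from_row(row))
        except (KeyError, ValueError) as exc:
            raise SchemeFormatError(f"{path}: line {i}: {exc}") from exc
    return BreedingScheme(id=path.stem, stages=stages)


def _stage_from_row(row: dict) -> StageDefinition:
    def geti(key, default=None):
        v = row.get(key)
        if v is None or v == "":
            return default
        return int(v)

    year_start = geti("year_start", 1)
    year_end = geti("year_end", year_start)
    crossing = None
    if geti("n_parents") is not None:
        crossing = CrossingDecisions(
            n_parents=geti("n_parents"),
            n_crosses=geti("n_crosses"),
            n_progeny_per_cross=geti("n_progeny_per_cross"),
            coupling_method=row.get("coupling_method") or "random",
            allow_reciprocals=(row.get("allow_reciprocals") or "").lower() in ("1", "true", "yes"),
        )
    return StageDefinition(
        name=row["stage"],
        year=(year_start, year_end) if year_end != year_start else year_start,
        evaluation=EvaluationDecisions(
            n_locations=geti("n_locations", 1),
            reps_per_location=geti("reps_per_location", 1),
            design_label=row.get("design_label") or "",
            n_checks=geti("n_checks", 0),
        ),
        selection=SelectionDecisions(
            n_entries_in=geti("n_entries_in", 0),
            n_selected_out=geti("n_selected_out", geti("n_entries_in", 0)),
            selection_method=row.get("selection_method") or "truncation",
            surrogate_of_merit=row.get("surrogate_of_merit") or "phenotype",
            recycling_source=(row.get("recycling_source") or "").lower() in ("1", "true", "yes"),
        ),
        crossing=crossing,
    )


def save_scheme_csv(scheme: BreedingScheme, path: Union[str, Path]) -> None:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_CSV_COLUMNS)
    writer.writeheader()
    for s in scheme.stages:
        row = {
            "stage": s.name,
            "year_start": s.year_start,
            "year_end": s.year_end,
            "n_entries_in": s.selection.n_entries_in,
            "n_selected_out": s.selection.n_selected_out,
            "selection_method": s.selection.selection_method,
            "surrogate_of_merit": s.selection.surrogate_of_merit,
            "recycling_source": str(s.selection.recycling_source).lower(),
            "n_locations": s.evaluation.n_locations,
            "reps_per_location": s.evaluation.reps_per_location,
            "design_label": s.evaluation.design_label,
            "n_checks": s.evaluation.n_checks,
        }
        if s.crossing is not None:
            row.update(
                n_parents=s.crossing.n_parents,
                n_crosses=s.crossing.n_crosses,
                n_progeny_per_cross=s.crossing.n_progeny_per_cross,
                coupling_method=s.crossing.coupling_method,
                allow_reciprocals=str(s.crossing.allow_reciprocals).lower(),
            )
        writer.writerow(row)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# derived program metrics


def _round_sig(x: float, sig: int = 3) -> float:
    """Half-up rounding to ``sig`` significant figures.

    Matches how stage-gate summary tables print selected percentages:
    7.3529 -> 7.35, 53.333 -> 53.3, 37.5 -> 37.5, 100 -> 100.
    """
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = sig - 1 - math.floor(math.log10(abs(x)))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def selected_percentages(scheme: BreedingScheme) -> dict[str, float]:
    """Percent of the previous stage's entries that enter each stage.

    The head (crossing) stage has no predecessor and is omitted, matching
    the dash in pipeline summary tables.
    """
    out: dict[str, float] = {}
    stages = scheme.stages
    for prev, cur in zip(stages, stages[1:]):
        denom = prev.selection.n_entries_in
        if denom == 0:
            raise DegenerateStageError(
                f"stage {prev.name!r} has zero entries; percentage for "
                f"{cur.name!r} is undefined"
            )
        out[cur.name] = _round_sig(100.0 * cur.selection.n_entries_in / denom)
    return out


def expected_cycle_time(scheme: BreedingScheme, policy) -> float:
    """Proportion-weighted mean year index of the recycling stages.

    ``policy`` maps stage name -> proportion of the crossing block drawn
    from that stage (a :class:`~stagegate.engine.RecyclingPolicy` or plain
    dict). A multi-year stage contributes its final year.
    """
    quotas = getattr(policy, "quotas", policy)
    recycling = set(scheme.recycling_stage_names)
    total = 0.0
    for name, prop in quotas.items():
        if name not in recycling:
            raise KeyError(
                f"policy stage {name!r} is not a recycling source in scheme {scheme.id!r}"
            )
        total += prop * scheme.stage(name).year_end
    return total


def plots_per_stage(scheme: BreedingScheme) -> dict[str, int]:
    """Field plots per stage: entries x locations x reps (checks excluded)."""
    out = {}
    for s in scheme.evaluation_stages:
        out[s.name] = (
            s.selection.n_entries_in
            * s.evaluation.n_locations
            * s.evaluation.reps_per_location
        )
    return out


def to_flowchart(scheme: BreedingScheme) -> str:
    """Render the scheme as a DOT digraph.

    One node per stage-year (a stage spanning years 5-6 yields two nodes),
    solid edges along the pipeline, dashed back-edges from every recycling
    source to the crossing stage.
    """
    nodes = []  # (node_id, label, stage)
    for s in scheme.stages:
        for k, yr in enumerate(range(s.year_start, s.year_end + 1)):
            node_id = s.name.replace(" ", "_") + (f"_y{yr}" if s.n_years > 1 else "")
            label = f"{s.name}\\nyear {yr}\\nentries {s.selection.n_entries_in}"
            nodes.append((node_id, label, s, k))

    lines = ["digraph scheme {", "  rankdir=TB;", '  node [shape=box, style=rounded];']
    for node_id, label, _, _ in nodes:
        lines.append(f'  "{node_id}" [label="{label}"];')
    for (a, _, _, _), (b, _, _, _) in zip(nodes, nodes[1:]):
        lines.append(f'  "{a}" -> "{b}";')
    head = nodes[0][0]
    for node_id, _, s, k in nodes:
        # back-edge from the last node of each recycling-source stage
        if s.selection.recycling_source and k == s.n_years - 1:
            lines.append(f'  "{node_id}" -> "{head}" [style=dashed, constraint=false];')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# bundled baseline


def baseline_scheme_path() -> Path:
    """Path to the bundled east-African cassava baseline scheme."""
    return Path(__file__).parent / "data" / "baseline_scheme.json"


def load_baseline() -> BreedingScheme:
    return load_scheme(baseline_scheme_path())
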