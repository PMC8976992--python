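"""Strategy parameter sets, model settings, validation and document I/O.

The model compares treatment strategies for esophageal squamous cell
carcinoma (ESCC) within a stage group.  Each strategy is described by a
:class:`StrategyParams` record: initial treatment-episode probabilities
(complication, perioperative death), per-cycle transition probabilities out
of the no-recurrence state, one-time and per-cycle costs (US$ 2021), and
state utility weights.  Parameter documents are YAML files with one
``strategies`` block per stage group; the base-case input estimates for
both stage groups, the published low/high ranges used in one-way
sensitivity analysis, and the base-case discounted total costs used for
downstream-cost calibration ship as bundled fixtures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Union

import yaml

__all__ = [
    "STATES",
    "STATE_INDEX",
    "HealthState",
    "StrategyParams",
    "ParameterRange",
    "ModelSettings",
    "ParameterSet",
    "ParseError",
    "ValidationError",
    "load_parameters",
    "write_parameters",
    "load_ranges",
    "write_ranges",
    "load_totals",
    "validate_params",
    "fixture_path",
    "load_fixture",
]

#: Health-state labels, in canonical order.  ``dead`` is absorbing.
STATES = ("no_recurrence", "local_recurrence", "metastasis", "complication", "dead")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: Canonical strategy identifiers.
STRATEGY_NAMES = ("esophagectomy", "EMR", "EMR_ablation", "CRT", "CRT_surgery")

STAGE_GROUPS = ("I", "II_III")

#: Sentinel strategy name in ranges that applies to every strategy of the
#: stage group (used for the stage-level utility ranges).
ALL_STRATEGIES = "all"

#: Range-parameter aliases that fan out to several utility fields at once.
UTILITY_ALIASES = {
    "u_primary": ("u_nr", "u_comp", "u_lr"),
    "u_met": ("u_met",),
}


class ParseError(ValueError):
    """A parameter document does not conform to the schema."""


class ValidationError(ValueError):
    """A parsed object violates a model invariant."""


class HealthState(str):
    """A health-state label; restricted to the five canonical states."""

    def __new__(cls, label: str) -> "HealthState":
        if label not in STATES:
            raise ValidationError(f"unknown health state {label!r}; expected one of {STATES}")
        return super().__new__(cls, label)

    @property
    def index(self) -> int:
        return STATE_INDEX[str(self)]


# Structural per-cycle probabilities absent from the published input table.
# They close the model for the recurrence/metastasis states and are
# deliberately user-overridable; every report header flags them.
STRUCTURAL_DEFAULTS = {
    "p_comp_to_dead": 0.0,
    "p_lr_to_met": 0.25,
    "p_lr_to_dead": 0.20,
    "p_met_to_dead": 0.50,
}

PROBABILITY_FIELDS = (
    "p_complication_init",
    "p_death_init",
    "p_nr_to_lr",
    "p_nr_to_met",
    "p_nr_to_dead",
    "p_comp_to_dead",
    "p_lr_to_met",
    "p_lr_to_dead",
    "p_met_to_dead",
)
COST_FIELDS = (
    "cost_treatment",
    "cost_cycle_nr",
    "cost_cycle_lr",
    "cost_cycle_met",
    "cost_cycle_comp",
    "cost_terminal",
)
UTILITY_FIELDS = ("u_nr", "u_comp", "u_lr", "u_met")


@dataclass
class StrategyParams:
    """All model inputs for one treatment strategy in one stage group.

    Probabilities are per 6-month cycle (initial ones per treatment
    episode), costs are US$ 2021, utilities are in [0, 1].
    """

    name: str
    stage_group: str
    p_complication_init: float
    p_death_init: float
    p_nr_to_lr: float
    p_nr_to_met: float
    p_nr_to_dead: float
    cost_treatment: float
    u_nr: float
    u_comp: float
    u_lr: float
    u_met: float
    p_comp_to_dead: float = STRUCTURAL_DEFAULTS["p_comp_to_dead"]
    p_lr_to_met: float = STRUCTURAL_DEFAULTS["p_lr_to_met"]
    p_lr_to_dead: float = STRUCTURAL_DEFAULTS["p_lr_to_dead"]
    p_met_to_dead: float = STRUCTURAL_DEFAULTS["p_met_to_dead"]
    cost_cycle_nr: float = 0.0
    cost_cycle_lr: float = 0.0
    cost_cycle_met: float = 0.0
    cost_cycle_comp: float = 0.0
    cost_terminal: float = 0.0

    def replace(self, **changes: float) -> "StrategyParams":
        return dataclasses.replace(self, **changes)

    def validate(self) -> list[str]:
        return validate_params(self)


def validate_params(p: StrategyParams) -> list[str]:
    """Return every violated invariant of ``p`` (empty list when valid)."""
    violations: list[str] = []
    if p.stage_group not in STAGE_GROUPS:
        violations.append(f"{p.name}: unknown stage group {p.stage_group!r}")
    for f in PROBABILITY_FIELDS:
        v = getattr(p, f)
        if not 0.0 <= v <= 1.0:
            violations.append(f"{p.name}.{f}: probability {v} out of [0, 1]")
    for f in COST_FIELDS:
        v = getattr(p, f)
        if v < 0.0:
            violations.append(f"{p.name}.{f}: negative cost {v}")
    for f in UTILITY_FIELDS:
        v = getattr(p, f)
        if not 0.0 <= v <= 1.0:
            violations.append(f"{p.name}.{f}: utility out of range [0, 1]: {v}")
    if p.p_complication_init + p.p_death_init > 1.0:
        violations.append(
            f"{p.name}: initial probabilities exceed 1 "
            f"(complication {p.p_complication_init} + death {p.p_death_init})"
        )
    row = p.p_nr_to_lr + p.p_nr_to_met + p.p_nr_to_dead
    if row > 1.0:
        violations.append(f"{p.name}: no-recurrence exit probabilities sum to {row} > 1")
    if p.p_lr_to_met + p.p_lr_to_dead > 1.0:
        violations.append(
            f"{p.name}: local-recurrence exit probabilities sum to "
            f"{p.p_lr_to_met + p.p_lr_to_dead} > 1"
        )
    return violations


@dataclass
class ParameterRange:
    """Low/high bound for one parameter of one strategy (or ``all``).

    Bounds are stored sorted ascending; where a source prints them in the
    reverse order the original ordering is recorded in ``note``.
    """

    strategy: str
    stage_group: str
    parameter: str
    low: float
    high: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            self.low, self.high = self.high, self.low
            if not self.note:
                self.note = "bounds printed in reverse order; sorted ascending"
        known = set(PROBABILITY_FIELDS) | set(COST_FIELDS) | set(UTILITY_FIELDS) | set(UTILITY_ALIASES)
        if self.parameter not in known:
            raise ValidationError(
                f"unknown parameter {self.parameter!r}; valid names: {sorted(known)}"
            )

    def target_fields(self) -> tuple[str, ...]:
        return UTILITY_ALIASES.get(self.parameter, (self.parameter,))


@dataclass
class ModelSettings:
    """Global model configuration.

    15-year horizon in 6-month cycles, 3% annual discount rate on both
    costs and outcomes, and the 1x/3x GDP-per-capita willingness-to-pay
    thresholds for Iran (US$ 5627 and 16,881 per QALY).
    """

    horizon_years: float = 15.0
    cycle_length_years: float = 0.5
    annual_discount_rate: float = 0.03
    start_age_years: float = 60.0
    wtp_low: float = 5627.0
    wtp_high: float = 16881.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError(
                f"annual_discount_rate {self.annual_discount_rate} out of [0, 1)"
            )
        if self.cycle_length_years <= 0:
            raise ValidationError("cycle_length_years must be positive")
        ratio = self.horizon_years / self.cycle_length_years
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) <= 0:
            raise ValidationError(
                f"horizon {self.horizon_years} y is not a positive integer number of "
                f"{self.cycle_length_years} y cycles"
            )
        if self.wtp_low > self.wtp_high:
            raise ValidationError("wtp_low exceeds wtp_high")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))

    def replace(self, **changes) -> "ModelSettings":
        return dataclasses.replace(self, **changes)


@dataclass
class ParameterSet:
    """A validated stage-group document: strategies plus settings."""

    stage_group: str
    strategies: dict[str, StrategyParams]
    settings: ModelSettings = field(default_factory=ModelSettings)

    def __iter__(self) -> Iterable[StrategyParams]:
        return iter(self.strategies.values())

    def replace_strategy(self, p: StrategyParams) -> "ParameterSet":
        strategies = dict(self.strategies)
        strategies[p.name] = p
        return ParameterSet(self.stage_group, strategies, self.settings)


Source = Union[str, Path, IO[str]]

_SETTINGS_KEYS = {f.name for f in dataclasses.fields(ModelSettings)}
_PARAM_KEYS = {f.name for f in dataclasses.fields(StrategyParams)} - {"name", "stage_group"}
_REQUIRED_PARAM_KEYS = {
    "p_complication_init", "p_death_init", "p_nr_to_lr", "p_nr_to_met",
    "p_nr_to_dead", "cost_treatment", "u_nr", "u_comp", "u_lr", "u_met",
}


def _read_yaml(source: Source) -> dict:
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, dict):
        raise ParseError("document root must be a mapping")
    return doc


def load_parameters(source: Source) -> ParameterSet:
    """Load and validate a stage-group parameter document.

    Raises :class:`ParseError` on schema violations (naming the offending
    key) and :class:`ValidationError` when a parsed value breaks a model
    invariant (naming strategy and field).
    """
    doc = _read_yaml(source)
    try:
        stage_group = doc["stage_group"]
    except KeyError:
        raise ParseError("missing key 'stage_group'") from None
    if stage_group not in STAGE_GROUPS:
        raise ParseError(f"stage_group {stage_group!r} not one of {STAGE_GROUPS}")

    settings_doc = doc.get("settings", {})
    if not isinstance(settings_doc, dict):
        raise ParseError("'settings' must be a mapping")
    unknown = set(settings_doc) - _SETTINGS_KEYS
    if unknown:
        raise ParseError(f"unknown settings key(s): {sorted(unknown)}")
    settings = ModelSettings(**settings_doc)

    strategies_doc = doc.get("strategies")
    if not isinstance(strategies_doc, dict) or not strategies_doc:
        raise ValidationError("no strategies in document")
    strategies: dict[str, StrategyParams] = {}
    for name, block in strategies_doc.items():
        if not isinstance(block, dict):
            raise ParseError(f"strategy {name!r} block must be a mapping")
        unknown = set(block) - _PARAM_KEYS
        if unknown:
            raise ParseError(f"strategy {name!r}: unknown key(s) {sorted(unknown)}")
        missing = _REQUIRED_PARAM_KEYS - set(block)
        if missing:
            raise ParseError(f"strategy {name!r}: missing key(s) {sorted(missing)}")
        p = StrategyParams(name=name, stage_group=stage_group, **block)
        violations = validate_params(p)
        if violations:
            raise ValidationError("; ".join(violations))
        strategies[name] = p
    return ParameterSet(stage_group=stage_group, strategies=strategies, settings=settings)


def write_parameters(ps: ParameterSet, destination: Union[str, Path, IO[str], None] = None) -> str:
    """Serialise a parameter set to the document schema (round-trip exact)."""
    doc = {
        "stage_group": ps.stage_group,
        "settings": dataclasses.asdict(ps.settings),
        "strategies": {
            name: {k: v for k, v in dataclasses.asdict(p).items() if k in _PARAM_KEYS}
            for name, p in ps.strategies.items()
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
    return text


def load_ranges(source: Source) -> list[ParameterRange]:
    """Load a sensitivity-analysis ranges document."""
    doc = _read_yaml(source)
    entries = doc.get("ranges")
    if not isinstance(entries, list):
        raise ParseError("missing or malformed key 'ranges' (expected a list)")
    ranges = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise ParseError(f"ranges[{i}] must be a mapping")
        unknown = set(entry) - {"strategy", "stage_group", "parameter", "low", "high", "note"}
        if unknown:
            raise ParseError(f"ranges[{i}]: unknown key(s) {sorted(unknown)}")
        try:
            ranges.append(ParameterRange(**entry))
        except TypeError as exc:
            raise ParseError(f"ranges[{i}]: {exc}") from None
    return ranges


def write_ranges(ranges: list[ParameterRange], destination: Union[str, Path, IO[str], None] = None) -> str:
    doc = {"ranges": [dataclasses.asdict(r) for r in ranges]}
    text = yaml.safe_dump(doc, sort_keys=False)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
    return text


def load_totals(source: Source) -> dict[str, dict[str, float]]:
    """Load calibration targets: discounted base-case total cost per strategy.

    Returns ``{stage_group: {strategy: total_cost_disc}}``.
    """
    doc = _read_yaml(source)
    totals = doc.get("totals")
    if not isinstance(totals, dict):
        raise ParseError("missing or malformed key 'totals'")
    out: dict[str, dict[str, float]] = {}
    for stage, block in totals.items():
        if stage not in STAGE_GROUPS:
            raise ParseError(f"totals: unknown stage group {stage!r}")
        if not isinstance(block, dict):
            raise ParseError(f"totals[{stage}] must be a mapping")
        out[stage] = {str(k): float(v) for k, v in block.items()}
    return out


def fixture_path(name: str) -> Path:
    """Path to a bundled fixture document (``stage1_base``, ``stage23_base``,
    ``ranges``, ``basecase_totals``)."""
    ref = resources.files("esocea") / "data" / f"{name}.yaml"
    return Path(str(ref))


def load_fixture(name: str):
    """Load a bundled fixture by name with the appropriate loader."""
    path = fixture_path(name)
    if name == "ranges":
        return load_ranges(path)
    if name == "basecase_totals":
        return load_totals(path)
    return load_parameters(path)
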