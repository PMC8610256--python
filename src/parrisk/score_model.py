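"""Points-based risk scores: definition, raw-score computation, risk grouping.

A points-based score assigns a small non-negative integer weight to each of a
fixed set of binary predictors; a patient's raw score is the sum of weights
over the predictors present at discharge.  Two integer cut-points partition
the score range into *low* (< cut_low), *medium* (cut_low..cut_high,
inclusive) and *high* (> cut_high) risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ScoreItem",
    "RiskThresholds",
    "ScoreDefinition",
    "ScoredPatient",
    "RiskGroup",
    "RISK_GROUPS",
    "ScoreConfigError",
    "compute_raw_score",
    "assign_risk_group",
    "load_score_definition",
    "bundled_score_definition",
]

RISK_GROUPS = ("low", "medium", "high")
RiskGroup = str  # one of RISK_GROUPS

_DATA_DIR = Path(__file__).parent / "data"


class ScoreConfigError(ValueError):
    """A score definition is malformed or does not match the predictor set."""


@dataclass(frozen=True)
class ScoreItem:
    """One scored predictor: its identifier and integer point weight."""

    name: str
    points: int

    def __post_init__(self) -> None:
        if not isinstance(self.points, int) or isinstance(self.points, bool):
            raise ScoreConfigError(
                f"item {self.name!r}: points must be an integer, got {self.points!r}"
            )
        if self.points < 0:
            raise ScoreConfigError(f"item {self.name!r}: points must be >= 0")


@dataclass(frozen=True)
class RiskThresholds:
    """Integer cut pair: scores < cut_low are low, > cut_high are high."""

    cut_low: int
    cut_high: int

    def __post_init__(self) -> None:
        if self.cut_low > self.cut_high:
            raise ScoreConfigError(
                f"cut_low ({self.cut_low}) must be <= cut_high ({self.cut_high})"
            )


#: The development study's published cut-points (<3, 3-10, >10).
ORIGINAL_THRESHOLDS = RiskThresholds(cut_low=3, cut_high=10)


@dataclass(frozen=True)
class ScoreDefinition:
    """A complete points-based score: items, thresholds and a display label."""

    items: tuple[ScoreItem, ...]
    thresholds: RiskThresholds
    label: str = ""

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ScoreConfigError(f"duplicate item names: {dupes}")
        if self.max_score < self.thresholds.cut_high:
            raise ScoreConfigError(
                f"maximum attainable score {self.max_score} is below "
                f"cut_high {self.thresholds.cut_high}: the high group would be empty"
            )

    @property
    def max_score(self) -> int:
        return sum(it.points for it in self.items)

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(it.name for it in self.items)

    def points_for(self, name: str) -> int:
        for it in self.items:
            if it.name == name:
                return it.points
        raise ScoreConfigError(f"no item named {name!r} in score definition")


@dataclass(frozen=True)
class ScoredPatient:
    patient_id: str
    raw_score: int
    risk_group: RiskGroup
    outcome: int = field(default=0)


def compute_raw_score(flags: dict[str, bool], definition: ScoreDefinition) -> int:
    """Sum the points of the definition's items whose flag is set.

    ``flags`` maps predictor name to a boolean (presence at discharge).  Every
    item of the definition must resolve to a flag; a missing flag is a
    configuration error, not a zero.
    """
    total = 0
    for item in definition.items:
        if item.name not in flags:
            raise ScoreConfigError(
                f"score item {item.name!r} has no corresponding predictor flag"
            )
        if flags[item.name]:
            total += item.points
    return total


def assign_risk_group(score: int, thresholds: RiskThresholds) -> RiskGroup:
    """Map an integer score to low / medium / high.

    low iff score < cut_low; medium iff cut_low <= score <= cut_high;
    high iff score > cut_high.  Total over the non-negative integers.
    """
    if score < 0:
        raise ValueError(f"raw score must be non-negative, got {score}")
    if score < thresholds.cut_low:
        return "low"
    if score <= thresholds.cut_high:
        return "medium"
    return "high"


def load_score_definition(path: str | Path) -> ScoreDefinition:
    """Read a score definition from YAML.

    Expected keys: ``label``, ``items`` (list of ``{name, points}``) and
    ``thresholds`` (``{cut_low, cut_high}``).  Non-integer point values are
    rejected: a transposed scoring system is integer by construction.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        items = tuple(ScoreItem(d["name"], d["points"]) for d in raw["items"])
        thresholds = RiskThresholds(int(raw["thresholds"]["cut_low"]),
                                    int(raw["thresholds"]["cut_high"]))
    except (KeyError, TypeError) as exc:
        raise ScoreConfigError(f"malformed score definition {path}: {exc}") from exc
    return ScoreDefinition(items=items, thresholds=thresholds,
                           label=str(raw.get("label", "")))


def bundled_score_definition() -> ScoreDefinition:
    """The bundled 12-item readmission score definition.

    The point weights shipped here are a synthetic stand-in: only the anaemia
    weight (2 points) is published in the validation study's main text; the
    remaining eleven weights live in a supplement that is not redistributable,
    so plausible integer weights are bundled in its place (see the packaged
    ``par_risk_score_synthetic.yaml``).  Users validating the real score
    should supply their own transcription via ``load_score_definition``.
    """
    sd = load_score_definition(_DATA_DIR / "par_risk_score_synthetic.yaml")
    if len(sd.items) != 12:
        raise ScoreConfigError("bundled definition must carry exactly 12 items")
    return sd
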