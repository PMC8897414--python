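"""Predictor registry: metadata for pathogenicity prediction tools.

Each predictor is described by a :class:`PredictorSpec` carrying its family
(splicing vs non-splicing), the direction in which its score indicates risk,
the transformation applied to raw tool output, and its calibrated cutoff on
the native score scale.  A default registry ships with the 14 tools that are
commonly compared in inherited-retinal-dystrophy variant prioritization,
with cutoffs re-calibrated at 90% sensitivity on a curated training set.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, field_validator


class Family(str, enum.Enum):
    SPLICING = "splicing"
    NON_SPLICING = "non-splicing"


class Direction(str, enum.Enum):
    HIGHER = "higher-is-risk"
    LOWER = "lower-is-risk"


class Transform(str, enum.Enum):
    NONE = "none"
    NEGATE_FOR_ROC = "negate-for-roc"
    PERCENT_DELTA = "percent-delta"
    MAX_OF_DELTAS = "max-of-deltas"


class PredictorSpec(BaseModel):
    """Orientation, transformation, cutoff and missing-value policy of one tool.

    ``optimal_cutoff`` is on the native score scale; together with
    ``direction`` it defines the pass predicate (inclusive bound):
    higher-is-risk tools pass at ``score >= cutoff``, lower-is-risk tools at
    ``score <= cutoff``.  ``pass_if_missing`` states whether an absent score
    disqualifies a variant in the filtering cascade.
    """

    name: str
    family: Family
    direction: Direction
    transform: Transform = Transform.NONE
    optimal_cutoff: float
    literature_cutoff: Optional[float] = None
    pass_if_missing: bool = True

    model_config = {"frozen": True}

    @field_validator("name")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("predictor name must be non-empty")
        return v

    def passes(self, score: float | None) -> bool:
        """Pass predicate on the native scale (inclusive threshold)."""
        if score is None or score != score:  # None or NaN
            return self.pass_if_missing
        if self.direction is Direction.HIGHER:
            return score >= self.optimal_cutoff
        return score <= self.optimal_cutoff


class Registry:
    """A named collection of :class:`PredictorSpec`."""

    def __init__(self, specs: list[PredictorSpec]):
        self._specs: dict[str, PredictorSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate predictor name: {spec.name}")
            self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> PredictorSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(
                f"unknown predictor {name!r}; registered: {sorted(self._specs)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def family(self, family: Family | str) -> list[PredictorSpec]:
        family = Family(family)
        return [s for s in self if s.family is family]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Registry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ValueError("registry YAML must be a list of predictor specs")
        return cls([PredictorSpec(**entry) for entry in raw])

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {k: (v.value if isinstance(v, enum.Enum) else v) for k, v in s.model_dump().items()}
            for s in self
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def literature_registry(base: Optional[Registry] = None) -> Registry:
    """The default registry with each cutoff replaced by its published
    literature value where one exists (tools without an established
    literature threshold keep the calibrated cutoff)."""
    base = base or default_registry()
    specs = []
    for spec in base:
        if spec.literature_cutoff is not None:
            spec = spec.model_copy(update={"optimal_cutoff": spec.literature_cutoff})
        specs.append(spec)
    return Registry(specs)


def default_registry() -> Registry:
    """The 14-tool registry with cutoffs calibrated at 90% sensitivity.

    Splicing-site strength tools (SSF, MaxEnt, NNS) are scored as the percent
    loss of strength between the wild-type and variant sequence; SpliceAI as
    the maximum of its four delta scores.  CADDv1.6 and SpliceAI act as
    mandatory gates in the cascade (``pass_if_missing=False``); the remaining
    tools are lenient on missing scores.  Literature cutoffs are given only
    where a widely used published value exists.
    """
    S, NS = Family.SPLICING, Family.NON_SPLICING
    HI, LO = Direction.HIGHER, Direction.LOWER
    return Registry([
        PredictorSpec(name="SPiCE", family=S, direction=HI, optimal_cutoff=0.993),
        PredictorSpec(name="SSF", family=S, direction=HI, transform=Transform.PERCENT_DELTA,
                      optimal_cutoff=12.360, literature_cutoff=10.0),
        PredictorSpec(name="MaxEnt", family=S, direction=HI, transform=Transform.PERCENT_DELTA,
                      optimal_cutoff=53.580, literature_cutoff=15.0),
        PredictorSpec(name="NNS", family=S, direction=HI, transform=Transform.PERCENT_DELTA,
                      optimal_cutoff=62.730, literature_cutoff=10.0),
        PredictorSpec(name="SpliceAI", family=S, direction=HI, transform=Transform.MAX_OF_DELTAS,
                      optimal_cutoff=0.405, literature_cutoff=0.5, pass_if_missing=False),
        PredictorSpec(name="PhastCons", family=NS, direction=HI, optimal_cutoff=0.097),
        PredictorSpec(name="PhyloP", family=NS, direction=HI, optimal_cutoff=0.449),
        PredictorSpec(name="SIFT", family=NS, direction=LO, transform=Transform.NEGATE_FOR_ROC,
                      optimal_cutoff=0.175, literature_cutoff=0.05),
        PredictorSpec(name="MAPP", family=NS, direction=LO, transform=Transform.NEGATE_FOR_ROC,
                      optimal_cutoff=0.098),
        PredictorSpec(name="Grantham", family=NS, direction=HI, optimal_cutoff=28.000,
                      literature_cutoff=66.0),
        PredictorSpec(name="PhastCons-100way", family=NS, direction=HI, optimal_cutoff=0.125),
        PredictorSpec(name="PhyloP-100way", family=NS, direction=HI, optimal_cutoff=0.475),
        PredictorSpec(name="CADDv1.3", family=NS, direction=HI, optimal_cutoff=21.950,
                      literature_cutoff=20.0, pass_if_missing=False),
        PredictorSpec(name="CADDv1.6", family=NS, direction=HI, optimal_cutoff=22.250,
                      literature_cutoff=20.0, pass_if_missing=False),
    ])
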