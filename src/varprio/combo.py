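"""Combinatorial predictor-filter models.

A combination model is a conjunction of single-predictor filters evaluated
with pass-if-missing semantics: a variant passes the model iff, for every
member, its score is either missing or beyond the member's cutoff.  Models
are scored on a labeled table by their true-positive rate (percent of
pathogenic-like variants passing), false-positive rate (percent of
benign-like variants passing) and missing rate (percent of rows where every
member score is absent), and selected under quality criteria
(TP >= 85%, FP <= 35%, missing <= 30% by default), preferring the lowest FP
rate among qualifying models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .registry import Direction, Family, PredictorSpec, Registry
from .roc import DegenerateInputError
from .scores import LabeledScores


@dataclass(frozen=True)
class ComboMember:
    predictor: str
    cutoff: float
    direction: Direction
    pass_if_missing: bool = True

    def passes(self, scores: np.ndarray) -> np.ndarray:
        """Vectorized member predicate (inclusive threshold)."""
        missing = np.isnan(scores)
        if self.direction is Direction.HIGHER:
            hit = scores >= self.cutoff
        else:
            hit = scores <= self.cutoff
        hit = np.where(missing, self.pass_if_missing, hit)
        return hit.astype(bool)


@dataclass
class ComboModel:
    members: tuple[ComboMember, ...]
    family: Family
    tp_rate: float = float("nan")
    fp_rate: float = float("nan")
    missing_rate: float = float("nan")
    meets_criteria: bool = False

    @property
    def label(self) -> str:
        return " + ".join(m.predictor for m in self.members) or "(empty)"


@dataclass(frozen=True)
class SelectionCriteria:
    """Quality criteria for combination models (percent scales)."""

    min_tp: float = 85.0
    max_fp: float = 35.0
    max_missing: float = 30.0

    def __post_init__(self) -> None:
        for v in (self.min_tp, self.max_fp, self.max_missing):
            if not (0.0 <= v <= 100.0):
                raise ValueError("criteria must be percentages in [0, 100]")

    def met_by(self, model: ComboModel) -> bool:
        return (
            model.tp_rate >= self.min_tp
            and model.fp_rate <= self.max_fp
            and model.missing_rate <= self.max_missing
        )


def _member_from_spec(spec: PredictorSpec) -> ComboMember:
    return ComboMember(
        predictor=spec.name,
        cutoff=spec.optimal_cutoff,
        direction=spec.direction,
        pass_if_missing=True,
    )


def enumerate_models(
    registry: Registry,
    model_file: Optional[str | Path] = None,
    *,
    cutoffs: Optional[dict[str, float]] = None,
    max_members: Optional[int] = None,
) -> list[ComboModel]:
    """Build the candidate model list.

    With ``model_file`` (a YAML list of predictor-name lists) the file drives
    membership; otherwise all non-empty subsets within each predictor family
    are generated, in deterministic order (by size, then lexicographic).
    ``cutoffs`` overrides registry cutoffs per predictor.
    """
    def make(names: Sequence[str]) -> ComboModel:
        specs = [registry[n] for n in names]
        fams = {s.family for s in specs}
        if len(fams) != 1:
            raise ValueError(f"model {list(names)} mixes predictor families")
        members = []
        for s in specs:
            m = _member_from_spec(s)
            if cutoffs and s.name in cutoffs:
                m = replace(m, cutoff=float(cutoffs[s.name]))
            members.append(m)
        return ComboModel(members=tuple(members), family=fams.pop())

    if model_file is not None:
        with open(model_file) as fh:
            raw = yaml.safe_load(fh)
        if not raw:
            raise ValueError("model file is empty")
        return [make(entry) for entry in raw]

    models: list[ComboModel] = []
    for fam in (Family.SPLICING, Family.NON_SPLICING):
        names = sorted(s.name for s in registry.family(fam))
        limit = max_members or len(names)
        for k in range(1, limit + 1):
            for subset in itertools.combinations(names, k):
                models.append(make(subset))
    return models


def evaluate_model(
    model: ComboModel,
    data: LabeledScores,
    *,
    restrict_family: bool = True,
) -> ComboModel:
    """Fill a model's TP/FP/missing rates on a labeled table.

    TP and FP rates are percentages over rows with at least one non-missing
    member score; the missing rate is the percentage of rows where *all*
    member scores are absent.  Splicing models are evaluated on the splicing
    subset.
    """
    frame = data.frame
    if restrict_family and model.family is Family.SPLICING:
        frame = frame[frame["splicing_subset"]]
    if len(frame) == 0:
        raise DegenerateInputError("no labeled rows for model family")
    y = (frame["label"] == "pathogenic-like").to_numpy()

    if model.members:
        score_mat = np.column_stack(
            [frame[m.predictor].to_numpy(dtype=float) for m in model.members]
        )
        passing = np.all(
            np.column_stack(
                [m.passes(score_mat[:, j]) for j, m in enumerate(model.members)]
            ),
            axis=1,
        )
        all_missing = np.all(np.isnan(score_mat), axis=1)
    else:
        passing = np.ones(len(frame), dtype=bool)
        all_missing = np.zeros(len(frame), dtype=bool)

    scored = ~all_missing
    n_pos = int((y & scored).sum())
    n_neg = int((~y & scored).sum())
    tp = 100.0 * (passing & y & scored).sum() / n_pos if n_pos else float("nan")
    fp = 100.0 * (passing & ~y & scored).sum() / n_neg if n_neg else float("nan")
    miss = 100.0 * all_missing.mean()
    out = replace(model, tp_rate=float(tp), fp_rate=float(fp), missing_rate=float(miss))
    out.meets_criteria = SelectionCriteria().met_by(out)
    return out


def select_models(
    models: Iterable[ComboModel],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> list[ComboModel]:
    """Filter by criteria and rank: lowest FP, then highest TP, then fewer members."""
    kept = [replace(m, meets_criteria=True) for m in models if criteria.met_by(m)]
    kept.sort(key=lambda m: (m.fp_rate, -m.tp_rate, len(m.members), m.label))
    return kept


def enrichment(model: ComboModel, validation: pd.DataFrame) -> float:
    """Percent of passing variants that are causal, on a validation table.

    ``validation`` needs a boolean ``causal`` column plus one score column
    per member.  Returns NaN when nothing passes (undefined ratio).
    """
    if "causal" not in validation.columns:
        raise ValueError("validation table needs a 'causal' column")
    if model.members:
        passing = np.all(
            np.column_stack(
                [m.passes(validation[m.predictor].to_numpy(dtype=float)) for m in model.members]
            ),
            axis=1,
        )
    else:
        passing = np.ones(len(validation), dtype=bool)
    total = int(passing.sum())
    if total == 0:
        return float("nan")
    causal = validation["causal"].to_numpy(dtype=bool)
    return 100.0 * int((passing & causal).sum()) / total


def bubble_plot_table(models: Iterable[ComboModel]) -> pd.DataFrame:
    """One row per criteria-passing model: fp, tp, missing, label.

    The bubble-plot convention: x = FP rate, y = TP rate, bubble size
    proportional to the missing rate.
    """
    rows = [
        {"fp_rate": m.fp_rate, "tp_rate": m.tp_rate,
         "missing_rate": m.missing_rate, "label": m.label}
        for m in models
        if m.meets_criteria
    ]
    return pd.DataFrame(rows, columns=["fp_rate", "tp_rate", "missing_rate", "label"])
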