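"""Labeled predictor-score tables and score harmonization.

Raw tool outputs differ in orientation (for SIFT and MAPP a *low* score is
deleterious) and in scale (splice-site strength tools report wild-type and
variant strengths; SpliceAI reports four delta scores).  This module
harmonizes everything to a single convention — higher harmonized score means
higher risk — so that ROC machinery downstream never needs per-tool logic,
while filter cutoffs stay on the familiar native scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .registry import Direction, PredictorSpec, Registry

#: Tokens interpreted as a missing score when parsing tables (case-insensitive).
DEFAULT_MISSING_TOKENS = ("", "na", "nan", ".")

LABEL_PATHOGENIC = "pathogenic-like"
LABEL_BENIGN = "benign-like"

#: Default mapping from free-text labels onto the binary classes.
DEFAULT_LABEL_MAP = {
    "pathogenic": LABEL_PATHOGENIC,
    "likely_pathogenic": LABEL_PATHOGENIC,
    "pathogenic-like": LABEL_PATHOGENIC,
    "p": LABEL_PATHOGENIC,
    "lp": LABEL_PATHOGENIC,
    "benign": LABEL_BENIGN,
    "likely_benign": LABEL_BENIGN,
    "benign-like": LABEL_BENIGN,
    "b": LABEL_BENIGN,
    "lb": LABEL_BENIGN,
}


def harmonize_for_roc(score: float | None, spec: PredictorSpec) -> float:
    """Map a native score to the higher-is-risk convention.

    Lower-is-risk predictors are negated, which reverses their ordering and
    leaves everything else untouched; the map is strictly monotone per
    predictor, so ranks (and therefore ROC and AUC) are preserved.  Missing
    stays missing (NaN).
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return math.nan
    if spec.direction is Direction.LOWER:
        return -float(score)
    return float(score)


def harmonize_array(scores: np.ndarray, spec: PredictorSpec) -> np.ndarray:
    """Vectorized :func:`harmonize_for_roc`; NaN marks missing."""
    arr = np.asarray(scores, dtype=float)
    return -arr if spec.direction is Direction.LOWER else arr.copy()


def native_from_harmonized(value: float, spec: PredictorSpec) -> float:
    """Invert harmonization, mapping a threshold back to the native scale."""
    return -value if spec.direction is Direction.LOWER else value


def splice_percent_delta(score_wt: float | None, score_var: float | None) -> float:
    """Percent loss of splice-site strength: ``100 * (wt - var) / wt``.

    Positive values mean the variant weakens the site.  Returns NaN when
    either input is missing or the wild-type strength is zero (undefined
    ratio).
    """
    if score_wt is None or score_var is None:
        return math.nan
    score_wt, score_var = float(score_wt), float(score_var)
    if math.isnan(score_wt) or math.isnan(score_var) or score_wt == 0.0:
        return math.nan
    return 100.0 * (score_wt - score_var) / score_wt


def spliceai_max_ds(
    ds_ag: float | None,
    ds_al: float | None,
    ds_dg: float | None,
    ds_dl: float | None,
) -> float:
    """Maximum of the four SpliceAI delta scores (acceptor/donor gain/loss).

    Each present value must lie in [0, 1]; all-missing yields NaN.
    """
    present = []
    for v in (ds_ag, ds_al, ds_dg, ds_dl):
        if v is None:
            continue
        v = float(v)
        if math.isnan(v):
            continue
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"SpliceAI delta score {v} outside [0, 1]")
        present.append(v)
    if not present:
        return math.nan
    return max(present)


@dataclass
class LabeledScores:
    """A benchmarking table: one row per variant, one column per predictor.

    Backed by a DataFrame with columns ``variant_id``, ``label``,
    ``splicing_subset`` plus one float column per predictor (NaN = missing).
    Labels are binary (variants of uncertain significance are excluded
    upstream of this container).
    """

    frame: pd.DataFrame
    predictors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"variant_id", "label", "splicing_subset"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"scores table lacks columns: {sorted(missing)}")
        if self.frame["variant_id"].duplicated().any():
            dups = self.frame.loc[self.frame["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicated variant_id(s): {sorted(set(dups))[:5]}")
        bad = set(self.frame["label"]) - {LABEL_PATHOGENIC, LABEL_BENIGN}
        if bad:
            raise ValueError(f"non-binary labels present: {sorted(bad)}")
        if not self.predictors:
            self.predictors = [c for c in self.frame.columns if c not in required]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def y(self) -> np.ndarray:
        """Binary class vector: 1 = pathogenic-like, 0 = benign-like."""
        return (self.frame["label"] == LABEL_PATHOGENIC).to_numpy(dtype=int)

    def subset_for(self, spec: PredictorSpec) -> "LabeledScores":
        """Rows relevant for a predictor's ROC: splicing tools are evaluated
        on the splicing subset only; other tools on the full table."""
        if spec.family.value == "splicing":
            sub = self.frame[self.frame["splicing_subset"]].reset_index(drop=True)
            return LabeledScores(sub, predictors=self.predictors)
        return self

    def scores_for(self, predictor: str) -> np.ndarray:
        if predictor not in self.frame.columns:
            raise KeyError(f"no score column for predictor {predictor!r}")
        return self.frame[predictor].to_numpy(dtype=float)

    def n_by_label(self) -> tuple[int, int]:
        y = self.y
        return int(y.sum()), int((1 - y).sum())


def load_scores_table(
    path: str | Path,
    *,
    label_column: str = "label",
    id_column: str = "variant_id",
    splicing_column: str = "splicing_subset",
    label_map: Optional[Mapping[str, str]] = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    predictors: Optional[list[str]] = None,
) -> LabeledScores:
    """Read a tab-delimited scores table into :class:`LabeledScores`.

    Blank cells and configured missing tokens become NaN; label strings are
    mapped onto the binary classes through ``label_map`` and unmapped labels
    raise with the offending rows listed.
    """
    tokens = {t.lower() for t in missing_tokens}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise ValueError(f"missing label column {label_column!r}")
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")

    lmap = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    labels = df[label_column].str.strip().str.lower().map(lmap)
    if labels.isna().any():
        rows = df.index[labels.isna()].tolist()
        bad = sorted(set(df.loc[labels.isna(), label_column]))
        raise ValueError(f"unmapped label strings {bad} in rows {rows[:10]}")

    if splicing_column in df.columns:
        spl = df[splicing_column].str.strip().str.lower().isin({"1", "true", "yes"})
    else:
        spl = pd.Series(False, index=df.index)

    score_cols = predictors or [
        c for c in df.columns if c not in {label_column, id_column, splicing_column}
    ]
    out = pd.DataFrame({
        "variant_id": df[id_column].str.strip(),
        "label": labels,
        "splicing_subset": spl,
    })
    for col in score_cols:
        raw = df[col].str.strip()
        out[col] = pd.to_numeric(
            raw.mask(raw.str.lower().isin(tokens)), errors="raise"
        )
    return LabeledScores(out, predictors=score_cols)


def save_scores_table(data: LabeledScores, path: str | Path) -> None:
    """Write a table readable back by :func:`load_scores_table`."""
    df = data.frame.copy()
    df["splicing_subset"] = df["splicing_subset"].map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index=False, na_rep="")
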