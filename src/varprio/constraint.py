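"""Gene-level constraint analysis with the LOEUF metric.

LOEUF (loss-of-function observed/expected upper-bound fraction) is low for
genes depleted of inactivating variation in the population.  Benchmarking a
disease gene set against an unconstrained control set (e.g. olfactory
receptor genes) yields a ROC in the lower-is-risk orientation, from which a
sensitivity-at-90% cutoff classifies query genes as constraint-compatible
or not.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .registry import Direction, Family, PredictorSpec, Transform
from .roc import CutoffEstimate, RocCurve, cutoff_at_sensitivity, roc_curve
from .scores import LABEL_BENIGN, LABEL_PATHOGENIC, LabeledScores


class GeneSet(str, enum.Enum):
    DISEASE = "disease"
    CONTROL = "control"
    QUERY = "query"


@dataclass(frozen=True)
class GeneConstraint:
    gene: str
    loeuf: float
    set: GeneSet = GeneSet.QUERY

    def __post_init__(self) -> None:
        if not self.loeuf > 0:
            raise ValueError("LOEUF must be a positive real")


LOEUF_SPEC = PredictorSpec(
    name="LOEUF",
    family=Family.NON_SPLICING,
    direction=Direction.LOWER,  # strong selection = low LOEUF = risk
    transform=Transform.NEGATE_FOR_ROC,
    optimal_cutoff=1.455,
)


def _as_scores(disease: Iterable[GeneConstraint], control: Iterable[GeneConstraint]) -> LabeledScores:
    rows = []
    for g in disease:
        rows.append({"variant_id": f"d:{g.gene}", "label": LABEL_PATHOGENIC,
                     "splicing_subset": False, "LOEUF": g.loeuf})
    for g in control:
        rows.append({"variant_id": f"c:{g.gene}", "label": LABEL_BENIGN,
                     "splicing_subset": False, "LOEUF": g.loeuf})
    if not rows:
        raise ValueError("both gene sets must be non-empty")
    return LabeledScores(pd.DataFrame(rows), predictors=["LOEUF"])


def loeuf_roc(
    disease: Iterable[GeneConstraint], control: Iterable[GeneConstraint]
) -> RocCurve:
    """ROC of LOEUF discriminating disease genes from unconstrained controls."""
    data = _as_scores(list(disease), list(control))
    return roc_curve(data, "LOEUF", LOEUF_SPEC)


def loeuf_cutoff(roc: RocCurve, target: float = 0.90) -> CutoffEstimate:
    """Strictest <=-cutoff keeping sensitivity over disease genes >= target."""
    return cutoff_at_sensitivity(roc, target)


def classify_gene(gene: GeneConstraint, cutoff: float) -> str:
    """'constraint-compatible' iff LOEUF <= cutoff (inclusive)."""
    return "constraint-compatible" if gene.loeuf <= cutoff else "not-supported"


def read_constraint_table(
    path: str | Path, gene_set: GeneSet = GeneSet.QUERY
) -> list[GeneConstraint]:
    """Read a gene-constraint TSV with columns ``gene`` and ``loeuf``."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "loeuf" not in cols:
        raise ValueError("constraint table needs 'gene' and 'loeuf' columns")
    out, seen = [], set()
    for row in df.itertuples(index=False):
        gene = str(getattr(row, cols["gene"]))
        key = gene.casefold()
        if key in seen:
            raise ValueError(f"duplicate gene symbol {gene!r}")
        seen.add(key)
        out.append(GeneConstraint(gene=gene, loeuf=float(getattr(row, cols["loeuf"])),
                                  set=gene_set))
    return out


def lookup_gene(
    genes: Iterable[GeneConstraint], symbol: str
) -> GeneConstraint:
    """Exact, case-insensitive gene symbol lookup."""
    for g in genes:
        if g.gene.casefold() == symbol.casefold():
            return g
    raise KeyError(f"gene {symbol!r} not in constraint table")
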