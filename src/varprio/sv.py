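"""Structural-variant prioritization.

CNVs are filtered on four pure predicates — copy-number genotype code,
cohort recurrence, population frequency, and exonic overlap — and mobile
element insertions (MEIs) on call quality plus the same recurrence bound.
All filters are idempotent and commute, so the pipeline result does not
depend on their order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from intervaltree import IntervalTree

#: Copy-number genotype codes retained by the genotype filter
#: (reference CN : patient CN); everything else is complex/multi-allelic
#: or copy-neutral.
ALLOWED_REFCN_CN = {
    "2:0",  # homozygous deletion
    "2:1",  # heterozygous deletion
    "2:3",  # heterozygous duplication
    "2:4",  # homozygous duplication
    "1:2",  # hemizygous duplication
    "1:0",  # hemizygous deletion
}

SV_TYPES = {"DEL", "DUP", "MEI:Alu", "MEI:L1", "MEI:SVA"}


@dataclass(frozen=True)
class SvCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    sv_type: str
    refcn_cn: str = "2:1"
    carriers: frozenset[str] = frozenset()
    af: float = float("nan")
    exonic_overlap: bool = False
    quality: str = "PASS"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end (1-based inclusive)")
        parts = self.refcn_cn.split(":")
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            raise ValueError(f"malformed REFCN:CN code {self.refcn_cn!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.sv_type)

    @property
    def is_mei(self) -> bool:
        return self.sv_type.startswith("MEI:")


def genotype_filter(svs: Iterable[SvCall]) -> list[SvCall]:
    """Keep simple deletion/duplication genotypes only (see ALLOWED_REFCN_CN)."""
    return [s for s in svs if s.refcn_cn in ALLOWED_REFCN_CN]


def sv_recurrence_filter(svs: Iterable[SvCall], max_individuals: int = 3) -> list[SvCall]:
    """Keep events carried by at most ``max_individuals`` cohort members.

    Identical events (same chrom/start/end/type) are merged before counting.
    """
    svs = list(svs)
    carriers: dict[tuple, set[str]] = {}
    for s in svs:
        carriers.setdefault(s.key, set()).update(s.carriers)
    return [s for s in svs if len(carriers[s.key]) <= max_individuals]


def sv_frequency_filter(svs: Iterable[SvCall], max_af: float = 0.01) -> list[SvCall]:
    """Keep rare events: AF <= ``max_af`` or absent from gnomAD."""
    return [s for s in svs if s.af != s.af or s.af <= max_af]


def build_exon_trees(exons: Iterable[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    """Index 1-based inclusive exon intervals per chromosome."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in exons:
        # IntervalTree is half-open; +1 makes the closed interval inclusive
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    return trees


def read_exon_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def sitetype_filter(
    svs: Iterable[SvCall],
    exons: Optional[Iterable[tuple[str, int, int]]] = None,
) -> list[SvCall]:
    """Keep events overlapping at least one exonic base.

    With ``exons`` given (1-based inclusive intervals) the overlap is
    computed; otherwise each call's ``exonic_overlap`` flag is trusted.
    """
    svs = list(svs)
    if exons is None:
        return [s for s in svs if s.exonic_overlap]
    trees = build_exon_trees(exons)
    out = []
    for s in svs:
        tree = trees.get(s.chrom)
        if tree is not None and tree.overlap(s.start, s.end + 1):
            out.append(s)
    return out


def mei_filter(meis: Iterable[SvCall], max_individuals: int = 3) -> list[SvCall]:
    """Quality (PASS) and recurrence filter for mobile element insertions."""
    passing = [m for m in meis if m.quality == "PASS"]
    return sv_recurrence_filter(passing, max_individuals)


def run_sv_pipeline(
    svs: Iterable[SvCall],
    exons: Optional[Iterable[tuple[str, int, int]]] = None,
    max_individuals: int = 3,
    max_af: float = 0.01,
) -> tuple[list[SvCall], list[tuple[str, int]]]:
    """CNV filters i–iv plus MEI filtering; returns (survivors, trace)."""
    svs = list(svs)
    cnvs = [s for s in svs if not s.is_mei]
    meis = [s for s in svs if s.is_mei]
    trace = [("input", len(svs))]
    cnvs = genotype_filter(cnvs)
    trace.append(("genotype", len(cnvs)))
    cnvs = sv_recurrence_filter(cnvs, max_individuals)
    trace.append(("recurrence", len(cnvs)))
    cnvs = sv_frequency_filter(cnvs, max_af)
    trace.append(("frequency", len(cnvs)))
    cnvs = sitetype_filter(cnvs, exons)
    trace.append(("sitetype", len(cnvs)))
    meis = mei_filter(meis, max_individuals)
    trace.append(("mei", len(meis)))
    out = cnvs + meis
    trace.append(("output", len(out)))
    return out, trace


def read_sv_table(path: str | Path) -> list[SvCall]:
    """Read an AnnotSV-style TSV of SV calls."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    calls = []
    for row in df.to_dict("records"):
        carriers = row.get("carriers", "")
        carrier_set = frozenset(
            c for c in str(carriers).split(",") if c and c != "nan"
        )
        calls.append(SvCall(
            chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
            sv_type=str(row["sv_type"]), refcn_cn=str(row.get("refcn_cn", "2:1")),
            carriers=carrier_set,
            af=float(row.get("af", float("nan"))),
            exonic_overlap=bool(row.get("exonic_overlap", False)),
            quality=str(row.get("quality", "PASS")),
        ))
    return calls


def sv_table(svs: Iterable[SvCall]) -> pd.DataFrame:
    rows = [{
        "chrom": s.chrom, "start": s.start, "end": s.end, "sv_type": s.sv_type,
        "refcn_cn": s.refcn_cn, "carriers": ",".join(sorted(s.carriers)),
        "af": s.af, "exonic_overlap": s.exonic_overlap, "quality": s.quality,
    } for s in svs]
    return pd.DataFrame(rows)
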