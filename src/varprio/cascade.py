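"""The SNV/indel discovery cascade.

Cohort-level filters (recurrence against pseudo-controls, multiallelic
sites, gnomAD frequency) feed two predictor branches — a non-splicing
branch gated on CADDv1.6 with lenient MAPP/Grantham/SIFT filters, and a
splicing branch gated on the SpliceAI maximum delta score with a lenient
NNSplice filter — plus a ClinVar rescue lane that retains (likely)
pathogenic entries regardless of predictor scores.  Branch survivors are
unioned and passed through a pedigree filter under an inheritance model;
every stage appends its survivor count to a :class:`FilterTrace`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd
import pysam

from .pedigree import Genotype, Pedigree, Sex
from .registry import Registry, default_registry

VariantKey = tuple[str, int, str, str]


class ClinvarClass(str, enum.Enum):
    PATHOGENIC = "P"
    LIKELY_PATHOGENIC = "LP"
    VUS = "VUS"
    LIKELY_BENIGN = "LB"
    BENIGN = "B"
    ABSENT = "absent"


class InheritanceMode(str, enum.Enum):
    AR_HOM = "AR-hom"
    AR_COMPHET = "AR-comphet"
    AD = "AD"
    XL = "XL"


@dataclass(frozen=True)
class InheritanceModel:
    mode: InheritanceMode
    consanguineous: bool = False


@dataclass
class VariantCall:
    """One annotated record of the multi-sample VCF."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    multiallelic: bool = False
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    gnomad_af: float = float("nan")
    gnomad_nhomalt: float = float("nan")
    gene: Optional[str] = None
    scores: dict[str, float] = field(default_factory=dict)
    clinvar_class: ClinvarClass = ClinvarClass.ABSENT
    provenance: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def score(self, predictor: str) -> float:
        return self.scores.get(predictor, float("nan"))


class FilterTrace:
    """Ordered (stage, surviving-count) audit of a cascade run."""

    def __init__(self) -> None:
        self.stages: list[tuple[str, int]] = []

    def record(self, stage: str, calls: list[VariantCall]) -> list[VariantCall]:
        self.stages.append((stage, len(calls)))
        return calls

    def as_dict(self) -> dict[str, int]:
        return dict(self.stages)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump([{"stage": s, "count": n} for s, n in self.stages], fh, indent=2)


class ConfigurationError(ValueError):
    pass


def _is_missing(value: float) -> bool:
    return value != value  # NaN


def _passes(value: float, cutoff: float, higher: bool, pass_if_missing: bool) -> bool:
    if _is_missing(value):
        return pass_if_missing
    return value >= cutoff if higher else value <= cutoff


# ---------------------------------------------------------------------------
# VCF / annotation I/O


def _genotype_from_gt(gt: tuple) -> Genotype:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Genotype.MISSING
    if len(alleles) == 1:
        return Genotype.HEMI if alleles[0] > 0 else Genotype.HOM_REF
    n_alt = sum(1 for a in alleles if a > 0)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(path: str | Path, annotations: Optional[pd.DataFrame] = None) -> list[VariantCall]:
    """Read a multi-sample VCF into :class:`VariantCall` records.

    Sites with more than one ALT allele are expanded per-allele and flagged
    multiallelic (genotype per allele: any copy of that allele counts).
    ``annotations`` is a table keyed by chrom/pos/ref/alt carrying predictor
    scores and gnomAD fields; see :func:`read_annotations`.
    """
    ann: dict[VariantKey, dict] = {}
    if annotations is not None:
        for row in annotations.to_dict("records"):
            key = (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
            ann[key] = row

    meta_cols = {"chrom", "pos", "ref", "alt", "gnomad_af", "gnomad_nhomalt", "gene"}
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            multi = len(alts) > 1
            for alt_idx, alt in enumerate(alts, start=1):
                genotypes: dict[str, Genotype] = {}
                for s in samples:
                    gt = rec.samples[s].get("GT", (None,))
                    alleles = [a for a in gt if a is not None]
                    if not alleles:
                        genotypes[s] = Genotype.MISSING
                        continue
                    # project onto this ALT allele
                    projected = tuple(1 if a == alt_idx else 0 for a in alleles)
                    genotypes[s] = _genotype_from_gt(projected)
                call = VariantCall(
                    chrom=str(rec.chrom), pos=rec.pos, ref=rec.ref, alt=alt,
                    multiallelic=multi, genotypes=genotypes,
                )
                row = ann.get(call.key)
                if row is not None:
                    call.gnomad_af = float(row.get("gnomad_af", float("nan")))
                    call.gnomad_nhomalt = float(row.get("gnomad_nhomalt", float("nan")))
                    gene = row.get("gene")
                    call.gene = None if gene is None or gene != gene else str(gene)
                    call.scores = {
                        k: float(v) for k, v in row.items()
                        if k not in meta_cols and isinstance(v, (int, float))
                    }
                calls.append(call)
    return calls


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Per-variant annotation TSV keyed by chrom/pos/ref/alt."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if missing := required - set(df.columns):
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    return df


def left_normalize(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal left-alignment: trim shared suffix, then shared prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


_CLNSIG_MAP = {
    "pathogenic": ClinvarClass.PATHOGENIC,
    "likely_pathogenic": ClinvarClass.LIKELY_PATHOGENIC,
    "pathogenic/likely_pathogenic": ClinvarClass.LIKELY_PATHOGENIC,
    "uncertain_significance": ClinvarClass.VUS,
    "likely_benign": ClinvarClass.LIKELY_BENIGN,
    "benign": ClinvarClass.BENIGN,
    "benign/likely_benign": ClinvarClass.LIKELY_BENIGN,
}

RESCUE_CLASSES = {ClinvarClass.PATHOGENIC, ClinvarClass.LIKELY_PATHOGENIC}


def read_clinvar(path: str | Path) -> dict[VariantKey, ClinvarClass]:
    """Load CLNSIG classifications from a ClinVar-style VCF, left-normalized."""
    table: dict[VariantKey, ClinvarClass] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            clnsig = rec.info.get("CLNSIG")
            if clnsig is None:
                continue
            if isinstance(clnsig, tuple):
                clnsig = clnsig[0]
            cls = _CLNSIG_MAP.get(str(clnsig).strip().lower())
            if cls is None:
                continue  # malformed/unsupported CLNSIG: skip record
            for alt in rec.alts or ():
                pos, ref, a = left_normalize(rec.pos, rec.ref, alt)
                table[(str(rec.chrom), pos, ref, a)] = cls
    return table


# ---------------------------------------------------------------------------
# Cohort-level filters


def recurrence_filter(
    calls: list[VariantCall],
    pedigree: Pedigree,
    trace: Optional[FilterTrace] = None,
) -> list[VariantCall]:
    """Drop variants homozygous/hemizygous-alt in any unaffected individual.

    Unaffected members across all families act as pseudo-controls;
    heterozygous carriage never disqualifies.
    """
    unaffected = [s.sample_id for s in pedigree if not s.affected]
    out = []
    for call in calls:
        for s in call.genotypes:
            if s not in pedigree:
                raise ConfigurationError(f"VCF sample {s!r} absent from pedigree")
        if any(call.genotypes.get(s, Genotype.MISSING).is_biallelic_alt for s in unaffected):
            continue
        out.append(call)
    if trace is not None:
        trace.record("recurrence", out)
    return out


def multiallelic_filter(
    calls: list[VariantCall], trace: Optional[FilterTrace] = None
) -> list[VariantCall]:
    """Drop records from sites carrying more than one ALT allele."""
    out = [c for c in calls if not c.multiallelic]
    if trace is not None:
        trace.record("multiallelic", out)
    return out


def frequency_filter(
    calls: list[VariantCall],
    max_af: float = 0.01,
    trace: Optional[FilterTrace] = None,
) -> list[VariantCall]:
    """Keep rare variants: gnomAD AF <= ``max_af`` or absent from gnomAD."""
    out = [c for c in calls if _is_missing(c.gnomad_af) or c.gnomad_af <= max_af]
    if trace is not None:
        trace.record("frequency", out)
    return out


# ---------------------------------------------------------------------------
# Predictor branches and ClinVar rescue


def nonsplicing_branch(
    calls: list[VariantCall],
    registry: Optional[Registry] = None,
    trace: Optional[FilterTrace] = None,
) -> list[VariantCall]:
    """CADDv1.6 gate (missing fails), then lenient MAPP/Grantham/SIFT."""
    reg = registry or default_registry()
    cadd, mapp = reg["CADDv1.6"], reg["MAPP"]
    grantham, sift = reg["Grantham"], reg["SIFT"]
    out = []
    for c in calls:
        if not _passes(c.score("CADDv1.6"), cadd.optimal_cutoff, True, False):
            continue
        if not _passes(c.score("MAPP"), mapp.optimal_cutoff, False, True):
            continue
        if not _passes(c.score("Grantham"), grantham.optimal_cutoff, True, True):
            continue
        if not _passes(c.score("SIFT"), sift.optimal_cutoff, False, True):
            continue
        kept = replace(c, provenance=c.provenance | {"nonsplicing"})
        out.append(kept)
    if trace is not None:
        trace.record("nonsplicing-branch", out)
    return out


def splicing_branch(
    calls: list[VariantCall],
    registry: Optional[Registry] = None,
    trace: Optional[FilterTrace] = None,
) -> list[VariantCall]:
    """SpliceAI max-DS gate (missing fails), then lenient NNSplice filter."""
    reg = registry or default_registry()
    spliceai, nns = reg["SpliceAI"], reg["NNS"]
    out = []
    for c in calls:
        if not _passes(c.score("SpliceAI"), spliceai.optimal_cutoff, True, False):
            continue
        if not _passes(c.score("NNS"), nns.optimal_cutoff, True, True):
            continue
        out.append(replace(c, provenance=c.provenance | {"splicing"}))
    if trace is not None:
        trace.record("splicing-branch", out)
    return out


def clinvar_rescue(
    calls: list[VariantCall],
    clinvar: dict[VariantKey, ClinvarClass],
    trace: Optional[FilterTrace] = None,
) -> list[VariantCall]:
    """Retain (likely) pathogenic ClinVar entries regardless of scores."""
    out = []
    for c in calls:
        pos, ref, alt = left_normalize(c.pos, c.ref, c.alt)
        cls = clinvar.get((c.chrom, pos, ref, alt), ClinvarClass.ABSENT)
        if cls in RESCUE_CLASSES:
            rescued = replace(c, provenance=c.provenance | {"clinvar"})
            rescued.clinvar_class = cls
            out.append(rescued)
    if trace is not None:
        trace.record("clinvar-rescue", out)
    return out


def merge_branches(*branches: list[VariantCall]) -> list[VariantCall]:
    """Union keyed by (chrom, pos, ref, alt) with provenance tags merged."""
    merged: dict[VariantKey, VariantCall] = {}
    for branch in branches:
        for c in branch:
            if c.key in merged:
                merged[c.key].provenance |= c.provenance
                if c.clinvar_class is not ClinvarClass.ABSENT:
                    merged[c.key].clinvar_class = c.clinvar_class
            else:
                merged[c.key] = replace(c, provenance=set(c.provenance))
    return list(merged.values())


# ---------------------------------------------------------------------------
# Pedigree filtering


def _gt(call: VariantCall, sample_id: str) -> Genotype:
    return call.genotypes.get(sample_id, Genotype.MISSING)


def pedigree_filter(
    calls: list[VariantCall],
    pedigree: Pedigree,
    model: InheritanceModel,
    family_id: str,
    trace: Optional[FilterTrace] = None,
) -> list[VariantCall]:
    """Keep variants whose genotypes across one family fit an inheritance model.

    AR-hom: biallelic-alt in every affected, not biallelic-alt in any
    unaffected member.  AR-comphet: >=2 heterozygous variants in the same
    gene in the index, no unaffected member carrying both of a qualifying
    pair (phase-unknown approximation).  AD: het in every affected, absent
    (hom-ref or missing) in unaffected.  XL: hemizygous-alt affected males /
    hom-alt affected females; unaffected males must not be hemizygous-alt,
    unaffected females may carry heterozygously.  For consanguineous
    families the output lists homozygous fits first.
    """
    members = pedigree.family(family_id)
    affected = [s for s in members if s.affected]
    unaffected = [s for s in members if not s.affected]
    if not affected:
        raise ConfigurationError(f"family {family_id!r} has no affected sample")

    def ar_hom(c: VariantCall) -> bool:
        return (
            all(_gt(c, s.sample_id).is_biallelic_alt for s in affected)
            and not any(_gt(c, s.sample_id).is_biallelic_alt for s in unaffected)
        )

    def ad(c: VariantCall) -> bool:
        if not all(_gt(c, s.sample_id) is Genotype.HET for s in affected):
            return False
        return all(
            _gt(c, s.sample_id) in (Genotype.HOM_REF, Genotype.MISSING)
            for s in unaffected
        )

    def xl(c: VariantCall) -> bool:
        for s in affected:
            g = _gt(c, s.sample_id)
            if s.sex is Sex.MALE:
                if g not in (Genotype.HEMI, Genotype.HOM_ALT):
                    return False
            else:
                if g is not Genotype.HOM_ALT:
                    return False
        for s in unaffected:
            g = _gt(c, s.sample_id)
            if s.sex is Sex.MALE and g in (Genotype.HEMI, Genotype.HOM_ALT):
                return False
            if s.sex is not Sex.MALE and g is Genotype.HOM_ALT:
                return False
        return True

    if model.mode is InheritanceMode.AR_COMPHET:
        out = _comphet(calls, affected, unaffected)
    else:
        predicate = {
            InheritanceMode.AR_HOM: ar_hom,
            InheritanceMode.AD: ad,
            InheritanceMode.XL: xl,
        }[model.mode]
        out = [c for c in calls if predicate(c)]

    if model.consanguineous:
        out.sort(key=lambda c: (not all(
            _gt(c, s.sample_id).is_biallelic_alt for s in affected
        ),))
    if trace is not None:
        trace.record(f"pedigree-{model.mode.value}", out)
    return out


def _comphet(calls, affected, unaffected) -> list[VariantCall]:
    index = affected[0]
    by_gene: dict[str, list[VariantCall]] = {}
    for c in calls:
        if c.gene and _gt(c, index.sample_id) is Genotype.HET:
            by_gene.setdefault(c.gene, []).append(c)
    kept: list[VariantCall] = []
    seen: set[VariantKey] = set()
    for gene, variants in by_gene.items():
        if len(variants) < 2:
            continue
        for i, a in enumerate(variants):
            for b in variants[i + 1:]:
                # phase-free rule: the pair must not co-occur in one unaffected
                if any(
                    _gt(a, u.sample_id).carries_alt and _gt(b, u.sample_id).carries_alt
                    for u in unaffected
                ):
                    continue
                # both variants het in every affected member
                if not all(
                    _gt(a, s.sample_id) is Genotype.HET
                    and _gt(b, s.sample_id) is Genotype.HET
                    for s in affected
                ):
                    continue
                for v in (a, b):
                    if v.key not in seen:
                        seen.add(v.key)
                        kept.append(v)
    return kept


def zero_homozygote_filter(
    calls: list[VariantCall], trace: Optional[FilterTrace] = None
) -> list[VariantCall]:
    """Keep variants never seen homozygous in population controls."""
    out = [
        c for c in calls
        if _is_missing(c.gnomad_nhomalt) or c.gnomad_nhomalt == 0
    ]
    if trace is not None:
        trace.record("zero-homozygote", out)
    return out


# ---------------------------------------------------------------------------
# Orchestration


def run_cascade(
    vcf: str | Path | list[VariantCall],
    pedigree: Pedigree,
    *,
    annotations: Optional[pd.DataFrame] = None,
    clinvar: Optional[dict[VariantKey, ClinvarClass] | str | Path] = None,
    registry: Optional[Registry] = None,
    family_id: Optional[str] = None,
    inheritance: Optional[InheritanceModel] = None,
    max_af: float = 0.01,
    apply_zero_homozygote: bool = False,
) -> tuple[list[VariantCall], FilterTrace]:
    """Execute the full discovery cascade and return (survivors, trace).

    Stages: recurrence -> multiallelic -> frequency -> {non-splicing branch,
    splicing branch} in parallel with ClinVar rescue (which hangs off the
    pre-frequency set) -> union -> optional pedigree filter -> optional
    population-homozygote filter.  Deterministic for fixed inputs; output
    ordered by genomic coordinate.
    """
    trace = FilterTrace()
    calls = read_vcf(vcf, annotations) if not isinstance(vcf, list) else vcf
    trace.record("input", calls)

    calls = recurrence_filter(calls, pedigree, trace)
    vcf1 = multiallelic_filter(calls, trace)
    vcf2 = frequency_filter(vcf1, max_af, trace)

    ns = nonsplicing_branch(vcf2, registry, trace)
    sp = splicing_branch(vcf2, registry, trace)
    if clinvar is not None:
        table = clinvar if isinstance(clinvar, dict) else read_clinvar(clinvar)
        cv = clinvar_rescue(vcf1, table, trace)
    else:
        cv = []
    merged = merge_branches(ns, sp, cv)
    merged.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    trace.record("merge", merged)

    if inheritance is not None:
        if family_id is None:
            raise ConfigurationError("pedigree filtering needs a family_id")
        merged = pedigree_filter(merged, pedigree, inheritance, family_id, trace)
    if apply_zero_homozygote:
        merged = zero_homozygote_filter(merged, trace)
    return merged, trace


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """Tabular report of cascade survivors."""
    rows = []
    for c in calls:
        rows.append({
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "gene": c.gene, "gnomad_af": c.gnomad_af,
            "gnomad_nhomalt": c.gnomad_nhomalt,
            "clinvar": c.clinvar_class.value,
            "provenance": ",".join(sorted(c.provenance)),
            **{f"score_{k}": v for k, v in sorted(c.scores.items())},
        })
    return pd.DataFrame(rows)
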