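"""Synthetic-data generators for every input the toolkit consumes.

All generators are pure functions of an explicit spec plus a seed (one
`numpy.random.default_rng` per call, no global state), so fixtures are
reproducible and carry known ground truth: labeled score tables with stated
class distributions and missing rates, multi-sample cohorts with causal
variants planted under an inheritance model, SV sets with known genotype
codes, and gene-constraint sets drawn from stated lognormals.

The default score-table spec emulates a curated benchmarking set of 942
rare SNVs (247 pathogenic-like / 695 benign-like, with a 99-variant
splicing subset of 34/65): each predictor's two class distributions are
Gaussians whose separation matches its reported discriminative ability and
whose pathogenic 10th percentile sits at the calibrated cutoff, with the
reported per-tool missing rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cascade import ClinvarClass
from .pedigree import Pedigree, PedigreeSample, Sex, write_ped
from .registry import Direction, Registry, default_registry
from .scores import LABEL_BENIGN, LABEL_PATHOGENIC, LabeledScores
from .sv import SvCall


# ---------------------------------------------------------------------------
# Labeled score tables

_Z90 = float(stats.norm.ppf(0.90))  # 1.2816: places the class-10% quantile


@dataclass(frozen=True)
class PredictorSim:
    """Two-component Gaussian score model for one predictor."""

    pathogenic_mean: float
    pathogenic_sd: float
    benign_mean: float
    benign_sd: float
    missing_prob: float = 0.0
    clip: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_prob <= 1.0):
            raise ValueError("missing_prob must be in [0, 1]")
        for sd in (self.pathogenic_sd, self.benign_sd):
            if not np.isfinite(sd) or sd < 0:
                raise ValueError("standard deviations must be finite and >= 0")


@dataclass(frozen=True)
class ScoreSimSpec:
    predictors: dict[str, PredictorSim]
    splicing: frozenset[str] = frozenset()
    n_pathogenic: int = 247
    n_benign: int = 695
    n_splicing_pathogenic: int = 34
    n_splicing_benign: int = 65
    seed: int = 0


#: (AUC-equivalent separation source, missing %) used by the default spec;
#: sigma is set per score scale.
_DEFAULT_SIM_TABLE: dict[str, tuple[float, float, float, Optional[tuple[float, float]]]] = {
    # name: (auc, missing_pct, sd, clip)
    "SPiCE": (0.968, 0.00, 0.15, (0.0, 1.0)),
    "SSF": (0.950, 0.11, 30.0, (None, 100.0)),
    "MaxEnt": (0.962, 0.74, 30.0, (None, 100.0)),
    "NNS": (0.971, 0.32, 30.0, (None, 100.0)),
    "SpliceAI": (0.968, 9.09, 0.25, (0.0, 1.0)),
    "PhastCons": (0.676, 8.28, 0.35, (0.0, 1.0)),
    "PhyloP": (0.744, 8.81, 1.5, None),
    "SIFT": (0.724, 44.48, 0.20, (0.0, 1.0)),
    "MAPP": (0.672, 54.78, 0.20, (0.0, 1.0)),
    "Grantham": (0.638, 44.48, 50.0, (0.0, 215.0)),
    "PhastCons-100way": (0.687, 8.49, 0.35, (0.0, 1.0)),
    "PhyloP-100way": (0.729, 8.49, 1.5, None),
    "CADDv1.3": (0.859, 8.49, 8.0, (0.0, None)),
    "CADDv1.6": (0.891, 0.00, 8.0, (0.0, None)),
}


def default_score_sim(seed: int = 0, registry: Optional[Registry] = None) -> ScoreSimSpec:
    """Per-predictor Gaussian models anchored to the calibrated cutoffs.

    For a higher-is-risk tool the pathogenic mean sits ``z90 * sd`` above the
    cutoff (so the pathogenic 10th percentile is the cutoff, matching a
    sensitivity-at-90% calibration) and the benign mean ``d * sd`` below the
    pathogenic mean with ``d = sqrt(2) * Phi^{-1}(AUC)``, the equal-variance
    Gaussian separation implied by the tool's AUC.  Orientation is mirrored
    for lower-is-risk tools.
    """
    reg = registry or default_registry()
    sims: dict[str, PredictorSim] = {}
    splicing = []
    for spec in reg:
        auc, miss_pct, sd, clip = _DEFAULT_SIM_TABLE[spec.name]
        d = float(np.sqrt(2.0) * stats.norm.ppf(auc))
        if spec.direction is Direction.HIGHER:
            mu_p = spec.optimal_cutoff + _Z90 * sd
            mu_b = mu_p - d * sd
        else:
            mu_p = spec.optimal_cutoff - _Z90 * sd
            mu_b = mu_p + d * sd
        lo, hi = clip if clip else (None, None)
        sims[spec.name] = PredictorSim(
            pathogenic_mean=mu_p, pathogenic_sd=sd,
            benign_mean=mu_b, benign_sd=sd,
            missing_prob=miss_pct / 100.0,
            clip=(lo if lo is not None else -np.inf, hi if hi is not None else np.inf),
        )
        if spec.family.value == "splicing":
            splicing.append(spec.name)
    return ScoreSimSpec(predictors=sims, splicing=frozenset(splicing), seed=seed)


def gen_labeled_scores(spec: ScoreSimSpec) -> LabeledScores:
    """Draw a labeled score table from a :class:`ScoreSimSpec`.

    Class counts are exact; missingness is Bernoulli per cell at the stated
    probability.  Splicing predictors are scored only on the splicing-subset
    rows (mirroring tools that only evaluate splice-region variants).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pathogenic + spec.n_benign
    labels = [LABEL_PATHOGENIC] * spec.n_pathogenic + [LABEL_BENIGN] * spec.n_benign

    spl = np.zeros(n, dtype=bool)
    spl[:spec.n_splicing_pathogenic] = True
    spl[spec.n_pathogenic:spec.n_pathogenic + spec.n_splicing_benign] = True

    frame = pd.DataFrame({
        "variant_id": [f"var{i:05d}" for i in range(n)],
        "label": labels,
        "splicing_subset": spl,
    })
    y = np.array([lab == LABEL_PATHOGENIC for lab in labels])
    for name, sim in spec.predictors.items():
        mean = np.where(y, sim.pathogenic_mean, sim.benign_mean)
        sd = np.where(y, sim.pathogenic_sd, sim.benign_sd)
        values = rng.normal(mean, sd)
        if sim.clip is not None:
            values = np.clip(values, sim.clip[0], sim.clip[1])
        missing = rng.random(n) < sim.missing_prob
        values[missing] = np.nan
        if name in spec.splicing:
            values[~spl] = np.nan
        frame[name] = values
    return LabeledScores(frame, predictors=list(spec.predictors))


# ---------------------------------------------------------------------------
# Cohorts with planted causal variants


@dataclass(frozen=True)
class PlantedVariant:
    """A causal variant with annotations under one inheritance model."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    mode: str  # AR-hom | AR-comphet | AD | XL
    scores: dict[str, float] = field(default_factory=dict)
    gnomad_af: float = float("nan")
    gnomad_nhomalt: float = 0.0
    clinvar: Optional[str] = None  # CLNSIG string for the ClinVar fixture
    comphet_partner_index: int = 0  # 0/1 within a comp-het pair


@dataclass(frozen=True)
class FamilySim:
    family_id: str
    members: tuple[PedigreeSample, ...]
    consanguineous: bool = False
    planted: tuple[PlantedVariant, ...] = ()


@dataclass(frozen=True)
class CohortSimSpec:
    families: tuple[FamilySim, ...]
    n_background: int = 500
    background_af_range: tuple[float, float] = (1e-5, 0.5)
    multiallelic_fraction: float = 0.05
    contigs: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)
    seed: int = 0


def default_cohort_spec(seed: int = 0, n_background: int = 500) -> CohortSimSpec:
    """A seven-family discovery cohort (14 genomes, 9 affected / 5 unaffected)
    with one AR-homozygous causal variant planted in the consanguineous
    index family, annotated to pass every cascade gate."""
    def fam(fid, members, cons=False, planted=()):
        return FamilySim(fid, tuple(members), cons, tuple(planted))

    def s(fid, iid, sex, aff, father=None, mother=None):
        return PedigreeSample(sample_id=iid, family_id=fid, father_id=father,
                              mother_id=mother, sex=sex, affected=aff)

    causal = PlantedVariant(
        chrom="16", pos=58_150_000, ref="C", alt="T", gene="CFAP20",
        mode="AR-hom",
        scores={"CADDv1.6": 29.5, "MAPP": 0.01, "Grantham": 101.0, "SIFT": 0.02},
        gnomad_af=1.21e-5, gnomad_nhomalt=0.0,
    )
    families = (
        fam("FamA", [s("FamA", "A-II1", Sex.FEMALE, True),
                     s("FamA", "A-II2", Sex.MALE, False)],
            cons=True, planted=(causal,)),
        fam("FamB", [s("FamB", "B-II1", Sex.MALE, True),
                     s("FamB", "B-II2", Sex.FEMALE, False)]),
        fam("FamC", [s("FamC", "C-II1", Sex.FEMALE, True),
                     s("FamC", "C-II2", Sex.MALE, False)]),
        fam("FamD", [s("FamD", "D-II1", Sex.MALE, True),
                     s("FamD", "D-II2", Sex.FEMALE, False)], cons=True),
        fam("FamE", [s("FamE", "E-II1", Sex.FEMALE, True)]),
        fam("FamF", [s("FamF", "F-II1", Sex.MALE, True),
                     s("FamF", "F-II2", Sex.FEMALE, True)], cons=True),
        fam("FamG", [s("FamG", "G-II1", Sex.FEMALE, True),
                     s("FamG", "G-II2", Sex.MALE, True),
                     s("FamG", "G-II3", Sex.FEMALE, False)]),
    )
    return CohortSimSpec(families=families, n_background=n_background, seed=seed)


def _planted_genotype(variant: PlantedVariant, member: PedigreeSample) -> str:
    """GT string for a planted variant in its own family."""
    mode = variant.mode
    if mode == "AR-hom":
        return "1/1" if member.affected else "0/1"
    if mode == "AD":
        return "0/1" if member.affected else "0/0"
    if mode == "XL":
        if member.sex is Sex.MALE:
            return "1" if member.affected else "0"
        return "1/1" if member.affected else "0/1"
    if mode == "AR-comphet":
        # each affected member is het for both pair members; an unaffected
        # member carries at most one
        if member.affected:
            return "0/1"
        return "0/1" if variant.comphet_partner_index == 0 else "0/0"
    raise ValueError(f"unknown inheritance mode {mode!r}")


def _hwe_genotype(rng: np.random.Generator, af: float, haploid: bool) -> str:
    if haploid:
        return "1" if rng.random() < af else "0"
    n_alt = int(rng.random() < af) + int(rng.random() < af)
    return {0: "0/0", 1: "0/1", 2: "1/1"}[n_alt]


def gen_cohort(spec: CohortSimSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF + PED + annotation TSV (+ ClinVar VCF) for a cohort spec.

    Planted variants receive genotypes consistent with their inheritance
    model inside their family and hom-ref genotypes elsewhere; background
    variants are drawn under Hardy-Weinberg at a log-uniform allele
    frequency, with benign-looking annotation scores.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    samples: list[PedigreeSample] = [m for fam in spec.families for m in fam.members]
    sample_ids = [m.sample_id for m in samples]
    ped = Pedigree(samples)

    rows = []  # (chrom, pos, ref, alt_field, genotypes, ann_row or None, clnsig)
    for fam in spec.families:
        for pv in fam.planted:
            genotypes = []
            for m in samples:
                if m.family_id == fam.family_id:
                    genotypes.append(_planted_genotype(pv, m))
                else:
                    haploid = pv.chrom == "X" and m.sex is Sex.MALE
                    genotypes.append("0" if haploid else "0/0")
            ann = {"chrom": pv.chrom, "pos": pv.pos, "ref": pv.ref, "alt": pv.alt,
                   "gene": pv.gene, "gnomad_af": pv.gnomad_af,
                   "gnomad_nhomalt": pv.gnomad_nhomalt, **pv.scores}
            rows.append((pv.chrom, pv.pos, pv.ref, pv.alt, genotypes, ann, pv.clinvar))

    lo, hi = spec.background_af_range
    bases = np.array(list("ACGT"))
    used = {(r[0], r[1]) for r in rows}
    while sum(1 for r in rows if r[5] is None or r[5].get("gene", "").startswith("BG")) < spec.n_background:
        chrom = str(rng.choice(spec.contigs[:22]))  # autosomal background
        pos = int(rng.integers(10_000, 5_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref, alt = rng.choice(bases, size=2, replace=False)
        af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        multi = rng.random() < spec.multiallelic_fraction
        alt_field = alt if not multi else f"{alt},{[b for b in 'ACGT' if b not in (ref, alt)][0]}"
        genotypes = [_hwe_genotype(rng, af, haploid=False) for _ in samples]
        ann = {
            "chrom": chrom, "pos": pos, "ref": str(ref), "alt": str(alt),
            "gene": f"BG{len(used):05d}",
            "gnomad_af": af, "gnomad_nhomalt": float(rng.integers(0, 5)) if af > 0.001 else 0.0,
            "CADDv1.6": float(np.clip(rng.normal(8.0, 6.0), 0, None)),
            "MAPP": float(np.clip(rng.normal(0.5, 0.25), 0, 1)),
            "Grantham": float(np.clip(rng.normal(60, 50), 5, 215)),
            "SIFT": float(np.clip(rng.normal(0.5, 0.3), 0, 1)),
            "SpliceAI": float(np.clip(rng.normal(0.02, 0.05), 0, 1)),
            "NNS": float(rng.normal(0.0, 15.0)),
        }
        rows.append((chrom, pos, str(ref), alt_field, genotypes, ann, None))

    order = {c: i for i, c in enumerate(spec.contigs)}
    rows.sort(key=lambda r: (order.get(r[0], 99), r[1]))

    vcf_path = out_dir / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in spec.contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for chrom, pos, ref, alt_field, genotypes, _, _ in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt_field}\t.\tPASS\t.\tGT\t"
                     + "\t".join(genotypes) + "\n")

    ped_path = out_dir / "cohort.ped"
    write_ped(ped, ped_path)

    ann_rows = [r[5] for r in rows if r[5] is not None]
    ann_path = out_dir / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(ann_path, sep="\t", index=False)

    clinvar_rows = [(r[0], r[1], r[2], r[3].split(",")[0], r[6]) for r in rows if r[6]]
    clinvar_path = out_dir / "clinvar.vcf"
    with open(clinvar_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in spec.contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, clnsig in clinvar_rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\tCLNSIG={clnsig}\n")

    return {"vcf": vcf_path, "ped": ped_path, "annotations": ann_path,
            "clinvar": clinvar_path}


# ---------------------------------------------------------------------------
# Validation-style fixtures (known pass/fail composition)


def gen_validation_scores(
    n_causal: int,
    n_causal_fail_cadd: int,
    n_noncausal: int = 0,
    n_noncausal_pass: int = 0,
    seed: int = 0,
    registry: Optional[Registry] = None,
) -> pd.DataFrame:
    """A validation table with a stated pass/fail composition.

    Emulates a cohort of previously solved cases re-filtered through the
    four-tool non-splicing combination: ``n_causal`` known causal variants of
    which ``n_causal_fail_cadd`` carry a CADD score below the gate (the
    failure mode observed for in-frame and non-canonical splicing changes),
    plus ``n_noncausal`` background variants of which ``n_noncausal_pass``
    survive every member filter.  Columns: ``causal`` plus the four member
    scores (NaN = missing).
    """
    if n_causal_fail_cadd > n_causal or n_noncausal_pass > n_noncausal:
        raise ValueError("failing/passing counts exceed group sizes")
    rng = np.random.default_rng(seed)
    reg = registry or default_registry()
    cadd_cut = reg["CADDv1.6"].optimal_cutoff

    def passing_row(causal: bool) -> dict:
        return {
            "causal": causal,
            "CADDv1.6": float(rng.uniform(cadd_cut + 0.5, cadd_cut + 20)),
            "MAPP": float(rng.uniform(0.0, 0.09)) if rng.random() < 0.5 else np.nan,
            "Grantham": float(rng.uniform(29, 215)) if rng.random() < 0.5 else np.nan,
            "SIFT": float(rng.uniform(0.0, 0.17)) if rng.random() < 0.5 else np.nan,
        }

    def cadd_fail_row(causal: bool) -> dict:
        row = passing_row(causal)
        row["CADDv1.6"] = float(rng.uniform(2.0, cadd_cut - 0.5))
        return row

    rows = [passing_row(True) for _ in range(n_causal - n_causal_fail_cadd)]
    rows += [cadd_fail_row(True) for _ in range(n_causal_fail_cadd)]
    rows += [passing_row(False) for _ in range(n_noncausal_pass)]
    rows += [cadd_fail_row(False) for _ in range(n_noncausal - n_noncausal_pass)]
    return pd.DataFrame(rows)


def nonsplicing_filter_members(registry: Optional[Registry] = None):
    """The four-tool combination with cascade semantics: CADD is a mandatory
    gate, MAPP/Grantham/SIFT are lenient on missing scores."""
    from .combo import ComboMember

    reg = registry or default_registry()
    return (
        ComboMember("CADDv1.6", reg["CADDv1.6"].optimal_cutoff,
                    reg["CADDv1.6"].direction, pass_if_missing=False),
        ComboMember("MAPP", reg["MAPP"].optimal_cutoff, reg["MAPP"].direction),
        ComboMember("Grantham", reg["Grantham"].optimal_cutoff,
                    reg["Grantham"].direction),
        ComboMember("SIFT", reg["SIFT"].optimal_cutoff, reg["SIFT"].direction),
    )


def gen_curation_cohort(
    n_literature_pass: int = 20,
    n_optimized_pass: int = 2,
    seed: int = 0,
) -> CohortSimSpec:
    """A consanguineous-family cohort contrasting calibrated vs literature
    cutoffs.

    Plants ``n_literature_pass`` rare homozygous candidate variants in the
    index family, all of which pass the literature-threshold filter (CADD >=
    20) while only ``n_optimized_pass`` also clear the re-calibrated gate
    (CADD >= 22.25); remaining member scores are chosen to pass under both
    registries.  Running the cascade under each registry then measures the
    manual-curation workload each leaves behind.
    """
    if n_optimized_pass > n_literature_pass:
        raise ValueError("optimized-pass count cannot exceed literature-pass count")
    rng = np.random.default_rng(seed)
    base = default_cohort_spec(seed=seed, n_background=0)
    fam_a = base.families[0]
    planted = []
    for i in range(n_literature_pass):
        strong = i < n_optimized_pass
        cadd = float(rng.uniform(23.0, 40.0)) if strong else float(rng.uniform(20.1, 22.0))
        planted.append(PlantedVariant(
            chrom=str(1 + i % 22), pos=1_000_000 + 1000 * i,
            ref="G", alt="A", gene=f"CAND{i:02d}", mode="AR-hom",
            scores={"CADDv1.6": cadd, "Grantham": 120.0},
            gnomad_af=float(rng.uniform(1e-6, 1e-4)), gnomad_nhomalt=0.0,
        ))
    fam_a = replace(fam_a, planted=fam_a.planted + tuple(planted))
    return replace(base, families=(fam_a,) + base.families[1:])


# ---------------------------------------------------------------------------
# Structural variants


def gen_sv_set(
    n: int,
    sample_ids: Sequence[str],
    exons: Sequence[tuple[str, int, int]],
    seed: int = 0,
    planted: Sequence[SvCall] = (),
) -> list[SvCall]:
    """Random SV calls with known genotype codes and overlap status.

    Draws event type, REFCN:CN code (including copy-neutral and complex
    codes that the genotype filter must remove), carrier count, frequency,
    and position either inside or away from the supplied exon intervals.
    ``planted`` events are appended unchanged.
    """
    rng = np.random.default_rng(seed)
    codes = ["2:0", "2:1", "2:2", "2:3", "2:4", "1:0", "1:2", "2:5", "3:1"]
    out: list[SvCall] = []
    for _ in range(n):
        exonic = bool(rng.random() < 0.5) and len(exons) > 0
        if exonic:
            chrom, estart, eend = exons[int(rng.integers(len(exons)))]
            start = max(1, int(estart - rng.integers(0, 500)))
            end = int(eend + rng.integers(0, 500))
        else:
            chrom = str(int(rng.integers(1, 23)))
            start = int(rng.integers(10_000_000, 20_000_000))
            end = start + int(rng.integers(100, 10_000))
        is_mei = rng.random() < 0.2
        sv_type = (
            str(rng.choice(["MEI:Alu", "MEI:L1", "MEI:SVA"]))
            if is_mei else str(rng.choice(["DEL", "DUP"]))
        )
        n_carriers = int(rng.integers(1, min(6, len(sample_ids)) + 1))
        carriers = frozenset(
            str(s) for s in rng.choice(sample_ids, size=n_carriers, replace=False)
        )
        out.append(SvCall(
            chrom=chrom, start=start, end=end, sv_type=sv_type,
            refcn_cn=str(rng.choice(codes)),
            carriers=carriers,
            af=float(10 ** rng.uniform(-5, -0.5)) if rng.random() < 0.8 else float("nan"),
            exonic_overlap=exonic,
            quality=str(rng.choice(["PASS", "LowQual"], p=[0.8, 0.2])),
        ))
    out.extend(planted)
    return out


# ---------------------------------------------------------------------------
# Gene-constraint sets


@dataclass(frozen=True)
class ConstraintSimSpec:
    """Lognormal LOEUF models for disease and control gene sets.

    Defaults emulate a benchmark of 207 recessive-disease genes against 374
    unconstrained (olfactory-receptor-like) genes with strong separation:
    the implied AUC is Phi((log m_c - log m_d) / sqrt(s_d^2 + s_c^2)) ~ 0.94
    and the disease-set 90th percentile sits near 1.3.
    """

    n_disease: int = 207
    n_control: int = 374
    disease_logmean: float = float(np.log(0.7))
    disease_logsd: float = 0.5
    control_logmean: float = float(np.log(1.8))
    control_logsd: float = 0.35
    seed: int = 0

    @property
    def analytic_auc(self) -> float:
        d = (self.control_logmean - self.disease_logmean) / np.sqrt(
            self.disease_logsd ** 2 + self.control_logsd ** 2
        )
        return float(stats.norm.cdf(d))


def gen_constraint_sets(spec: ConstraintSimSpec = ConstraintSimSpec()):
    """Draw (disease, control) gene lists with lognormal LOEUF scores."""
    from .constraint import GeneConstraint, GeneSet

    rng = np.random.default_rng(spec.seed)
    disease = [
        GeneConstraint(gene=f"DIS{i:04d}",
                       loeuf=float(rng.lognormal(spec.disease_logmean, spec.disease_logsd)),
                       set=GeneSet.DISEASE)
        for i in range(spec.n_disease)
    ]
    control = [
        GeneConstraint(gene=f"OR{i:04d}",
                       loeuf=float(rng.lognormal(spec.control_logmean, spec.control_logsd)),
                       set=GeneSet.CONTROL)
        for i in range(spec.n_control)
    ]
    return disease, control
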