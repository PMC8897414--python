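"""The SNV/indel discovery cascade: filters, branches, pedigree logic."""

import itertools

import numpy as np
import pandas as pd
import pytest

import varprio as v
from varprio.cascade import (
    ClinvarClass,
    ConfigurationError,
    FilterTrace,
    InheritanceMode,
    InheritanceModel,
    VariantCall,
    calls_to_frame,
    left_normalize,
    read_annotations,
    read_clinvar,
)
from varprio.pedigree import Genotype, Pedigree, PedigreeSample, Sex

GT = Genotype


def call(chrom="1", pos=100, ref="A", alt="T", **kw):
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def quartet():
    """Consanguineous family: affected index, unaffected sib, both parents."""
    return Pedigree([
        PedigreeSample("idx", "F1", "dad", "mom", Sex.FEMALE, True),
        PedigreeSample("sib", "F1", "dad", "mom", Sex.MALE, False),
        PedigreeSample("dad", "F1", sex=Sex.MALE, affected=False),
        PedigreeSample("mom", "F1", sex=Sex.FEMALE, affected=False),
    ])


class TestCohortFilters:
    def test_recurrence_drops_hom_in_unaffected(self):
        ped = quartet()
        bad = call(genotypes={"idx": GT.HOM_ALT, "sib": GT.HOM_ALT,
                              "dad": GT.HET, "mom": GT.HET})
        good = call(pos=200, genotypes={"idx": GT.HOM_ALT, "sib": GT.HET,
                                        "dad": GT.HET, "mom": GT.HET})
        out = v.recurrence_filter([bad, good], ped)
        assert [c.pos for c in out] == [200]

    def test_recurrence_hemi_counts_as_biallelic(self):
        ped = quartet()
        bad = call(chrom="X", genotypes={"idx": GT.HOM_ALT, "sib": GT.HEMI,
                                         "dad": GT.HOM_REF, "mom": GT.HET})
        assert v.recurrence_filter([bad], ped) == []

    def test_recurrence_unknown_sample_is_config_error(self):
        ped = quartet()
        with pytest.raises(ConfigurationError):
            v.recurrence_filter([call(genotypes={"ghost": GT.HET})], ped)

    def test_recurrence_identity_without_unaffected(self):
        ped = Pedigree([PedigreeSample("idx", "F1", affected=True)])
        calls = [call(genotypes={"idx": GT.HOM_ALT})]
        assert v.recurrence_filter(calls, ped) == calls

    def test_multiallelic_filter(self):
        multi = call(multiallelic=True)
        single = call(pos=200)
        assert v.multiallelic_filter([multi, single]) == [single]
        assert v.multiallelic_filter([]) == []

    @pytest.mark.parametrize("af,kept", [
        (0.009, True), (0.011, False), (0.01, True), (float("nan"), True),
    ])
    def test_frequency_filter_inclusive_and_missing_rare(self, af, kept):
        out = v.frequency_filter([call(gnomad_af=af)])
        assert bool(out) is kept


class TestBranches:
    def test_nonsplicing_pass_if_missing(self, registry):
        c = call(scores={"CADDv1.6": 30.0, "Grantham": 100.0, "SIFT": 0.01})
        out = v.nonsplicing_branch([c], registry)
        assert len(out) == 1 and out[0].provenance == {"nonsplicing"}

    def test_nonsplicing_cadd_gate_mandatory(self, registry):
        assert v.nonsplicing_branch([call(scores={})], registry) == []
        assert v.nonsplicing_branch(
            [call(scores={"MAPP": 0.01, "SIFT": 0.0})], registry) == []

    def test_nonsplicing_present_failing_score_removes(self, registry):
        c = call(scores={"CADDv1.6": 30.0, "SIFT": 0.5})
        assert v.nonsplicing_branch([c], registry) == []

    @pytest.mark.parametrize("scores,kept", [
        ({"SpliceAI": 0.5, "NNS": 70.0}, True),
        ({"SpliceAI": 0.5, "NNS": 10.0}, False),
        ({"SpliceAI": 0.3}, False),
        ({"SpliceAI": 0.5}, True),  # NNS missing passes
    ])
    def test_splicing_branch(self, registry, scores, kept):
        out = v.splicing_branch([call(scores=scores)], registry)
        assert bool(out) is kept
        if kept:
            assert out[0].provenance == {"splicing"}

    def test_clinvar_rescue_regardless_of_scores(self):
        table = {("1", 100, "A", "T"): ClinvarClass.PATHOGENIC,
                 ("1", 200, "G", "C"): ClinvarClass.VUS}
        failing_cadd = call(scores={"CADDv1.6": 2.0})
        vus = call(pos=200, ref="G", alt="C")
        unmatched = call(pos=300)
        out = v.clinvar_rescue([failing_cadd, vus, unmatched], table)
        assert [c.pos for c in out] == [100]
        assert out[0].provenance == {"clinvar"}

    def test_left_normalization_matches_representation(self):
        # "AT>AG" at pos 100 normalizes to T>G at 101
        assert left_normalize(100, "AT", "AG") == (101, "T", "G")
        table = {("1", 101, "T", "G"): ClinvarClass.LIKELY_PATHOGENIC}
        out = v.clinvar_rescue([call(pos=100, ref="AT", alt="AG")], table)
        assert len(out) == 1

    def test_merge_unions_and_tags(self):
        a = call(provenance={"nonsplicing"})
        b = call(provenance={"splicing"})
        c = call(pos=500, provenance={"clinvar"})
        merged = v.merge_branches([a], [b], [c])
        assert len(merged) == 2
        tags = {m.pos: m.provenance for m in merged}
        assert tags[100] == {"nonsplicing", "splicing"}
        assert v.merge_branches([], [], []) == []


def trio_genotypes():
    """All 27 genotype assignments for (affected index, 2 unaffected parents)."""
    opts = [GT.HOM_REF, GT.HET, GT.HOM_ALT]
    return list(itertools.product(opts, repeat=3))


class TestPedigreeFilter:
    def ped(self):
        return quartet()

    def test_ar_hom_segregation(self):
        ped = self.ped()
        keep = call(genotypes={"idx": GT.HOM_ALT, "sib": GT.HET,
                               "dad": GT.HET, "mom": GT.HET})
        drop = call(pos=200, genotypes={"idx": GT.HOM_ALT, "sib": GT.HOM_ALT,
                                        "dad": GT.HET, "mom": GT.HET})
        out = v.pedigree_filter([keep, drop], ped,
                                InheritanceModel(InheritanceMode.AR_HOM, True), "F1")
        assert [c.pos for c in out] == [100]

    def test_ar_hom_truth_table_oracle(self):
        """Agreement with direct enumeration over all trio configurations."""
        ped = Pedigree([
            PedigreeSample("idx", "F1", "dad", "mom", Sex.FEMALE, True),
            PedigreeSample("dad", "F1", sex=Sex.MALE, affected=False),
            PedigreeSample("mom", "F1", sex=Sex.FEMALE, affected=False),
        ])
        model = InheritanceModel(InheritanceMode.AR_HOM)
        for gi, gd, gm in trio_genotypes():
            c = call(genotypes={"idx": gi, "dad": gd, "mom": gm})
            got = bool(v.pedigree_filter([c], ped, model, "F1"))
            expected = (gi is GT.HOM_ALT) and gd is not GT.HOM_ALT and gm is not GT.HOM_ALT
            assert got == expected, (gi, gd, gm)

    def test_ad_truth_table_oracle(self):
        ped = Pedigree([
            PedigreeSample("idx", "F1", "dad", "mom", Sex.FEMALE, True),
            PedigreeSample("dad", "F1", sex=Sex.MALE, affected=False),
            PedigreeSample("mom", "F1", sex=Sex.FEMALE, affected=False),
        ])
        model = InheritanceModel(InheritanceMode.AD)
        for gi, gd, gm in trio_genotypes():
            c = call(genotypes={"idx": gi, "dad": gd, "mom": gm})
            got = bool(v.pedigree_filter([c], ped, model, "F1"))
            expected = gi is GT.HET and gd is GT.HOM_REF and gm is GT.HOM_REF
            assert got == expected, (gi, gd, gm)

    def test_xl_hemizygous_logic(self):
        ped = Pedigree([
            PedigreeSample("boy", "F1", None, "mom", Sex.MALE, True),
            PedigreeSample("mom", "F1", sex=Sex.FEMALE, affected=False),
            PedigreeSample("uncle", "F1", sex=Sex.MALE, affected=False),
        ])
        model = InheritanceModel(InheritanceMode.XL)
        keep = call(chrom="X", genotypes={"boy": GT.HEMI, "mom": GT.HET,
                                          "uncle": GT.HOM_REF})
        drop = call(chrom="X", pos=200,
                    genotypes={"boy": GT.HEMI, "mom": GT.HET, "uncle": GT.HEMI})
        out = v.pedigree_filter([keep, drop], ped, model, "F1")
        assert [c.pos for c in out] == [100]

    def test_comphet_pair_kept_and_unaffected_carrier_removes(self):
        ped = self.ped()
        model = InheritanceModel(InheritanceMode.AR_COMPHET)
        # valid pair: each parent carries one allele
        a = call(pos=100, gene="G1",
                 genotypes={"idx": GT.HET, "sib": GT.HOM_REF,
                            "dad": GT.HET, "mom": GT.HOM_REF})
        b = call(pos=200, gene="G1",
                 genotypes={"idx": GT.HET, "sib": GT.HOM_REF,
                            "dad": GT.HOM_REF, "mom": GT.HET})
        out = v.pedigree_filter([a, b], ped, model, "F1")
        assert sorted(c.pos for c in out) == [100, 200]

        # unaffected sib carries both: pair removed
        a2 = call(pos=100, gene="G1",
                  genotypes={"idx": GT.HET, "sib": GT.HET,
                             "dad": GT.HET, "mom": GT.HOM_REF})
        b2 = call(pos=200, gene="G1",
                  genotypes={"idx": GT.HET, "sib": GT.HET,
                             "dad": GT.HOM_REF, "mom": GT.HET})
        assert v.pedigree_filter([a2, b2], ped, model, "F1") == []

    def test_comphet_single_het_insufficient(self):
        ped = self.ped()
        a = call(gene="G1", genotypes={"idx": GT.HET, "sib": GT.HOM_REF,
                                       "dad": GT.HET, "mom": GT.HOM_REF})
        out = v.pedigree_filter([a], ped,
                                InheritanceModel(InheritanceMode.AR_COMPHET), "F1")
        assert out == []

    def test_unknown_family_is_config_error(self):
        with pytest.raises(KeyError):
            v.pedigree_filter([], self.ped(),
                              InheritanceModel(InheritanceMode.AR_HOM), "nope")

    def test_consanguineous_orders_hom_first(self):
        ped = self.ped()
        # both AR-hom consistent; ordering puts homozygous fits first under
        # a consanguineous model even if input order differs
        hom = call(pos=300, genotypes={"idx": GT.HOM_ALT, "sib": GT.HET,
                                       "dad": GT.HET, "mom": GT.HET})
        out = v.pedigree_filter([hom], ped,
                                InheritanceModel(InheritanceMode.AR_HOM, True), "F1")
        assert out[0].pos == 300


class TestZeroHomozygote:
    @pytest.mark.parametrize("nhom,kept", [(0, True), (3, False), (float("nan"), True)])
    def test_policy(self, nhom, kept):
        out = v.zero_homozygote_filter([call(gnomad_nhomalt=nhom)])
        assert bool(out) is kept


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    spec = v.default_cohort_spec(seed=5, n_background=300)
    paths = v.gen_cohort(spec, tmp_path_factory.mktemp("cohort"))
    ped = v.read_ped(paths["ped"])
    ann = read_annotations(paths["annotations"])
    return spec, paths, ped, ann


class TestRunCascade:
    def test_planted_variant_recovered_and_trace_monotone(self, cohort):
        spec, paths, ped, ann = cohort
        calls, trace = v.run_cascade(
            paths["vcf"], ped, annotations=ann, clinvar=paths["clinvar"],
            family_id="FamA",
            inheritance=InheritanceModel(InheritanceMode.AR_HOM, True),
        )
        keys = {c.key for c in calls}
        planted = spec.families[0].planted[0]
        assert (planted.chrom, planted.pos, planted.ref, planted.alt) in keys
        counts = dict(trace.stages)
        # linear cohort stages are non-increasing
        assert counts["input"] >= counts["recurrence"] >= counts["multiallelic"] \
            >= counts["frequency"]
        assert counts["merge"] <= (counts["nonsplicing-branch"]
                                   + counts["splicing-branch"]
                                   + counts["clinvar-rescue"])
        assert all(c.provenance for c in calls)

    def test_rerun_is_identical(self, cohort):
        _, paths, ped, ann = cohort
        out1, t1 = v.run_cascade(paths["vcf"], ped, annotations=ann)
        out2, t2 = v.run_cascade(paths["vcf"], ped, annotations=ann)
        assert t1.stages == t2.stages
        pd.testing.assert_frame_equal(calls_to_frame(out1), calls_to_frame(out2))

    def test_trace_counts_match_independent_enumeration(self, cohort):
        """Stage survivor counts equal a direct per-variant predicate count."""
        _, paths, ped, ann = cohort
        calls = v.cascade.read_vcf(paths["vcf"], ann) if hasattr(v, "cascade") else None
        from varprio.cascade import read_vcf
        calls = read_vcf(paths["vcf"], ann)
        _, trace = v.run_cascade(paths["vcf"], ped, annotations=ann)
        counts = dict(trace.stages)
        unaff = [s.sample_id for s in ped if not s.affected]
        lvl1 = [c for c in calls if not any(
            c.genotypes[s].is_biallelic_alt for s in unaff)]
        assert counts["recurrence"] == len(lvl1)
        lvl2 = [c for c in lvl1 if not c.multiallelic]
        assert counts["multiallelic"] == len(lvl2)
        lvl3 = [c for c in lvl2 if not (c.gnomad_af == c.gnomad_af and c.gnomad_af > 0.01)]
        assert counts["frequency"] == len(lvl3)

    def test_empty_vcf(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tidx\n"
        )
        ped = Pedigree([PedigreeSample("idx", "F1", affected=True)])
        out, trace = v.run_cascade(vcf, ped)
        assert out == [] and all(n == 0 for _, n in trace.stages)

    def test_gate_violating_plant_absent(self, tmp_path):
        """A planted causal variant with CADD below the gate and no ClinVar
        entry must not survive the cascade."""
        spec = v.default_cohort_spec(seed=9, n_background=0)
        weak = v.PlantedVariant(
            chrom="2", pos=1000, ref="G", alt="A", gene="WEAK", mode="AR-hom",
            scores={"CADDv1.6": 10.0},
        )
        fam0 = spec.families[0]
        from dataclasses import replace
        spec = replace(spec, families=(replace(fam0, planted=fam0.planted + (weak,)),)
                       + spec.families[1:])
        paths = v.gen_cohort(spec, tmp_path)
        ped = v.read_ped(paths["ped"])
        ann = read_annotations(paths["annotations"])
        out, _ = v.run_cascade(paths["vcf"], ped, annotations=ann,
                               clinvar=paths["clinvar"])
        keys = {c.key for c in out}
        assert ("2", 1000, "G", "A") not in keys
        assert ("16", 58_150_000, "C", "T") in keys
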