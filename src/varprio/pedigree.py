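"""Six-column PED pedigrees and genotype vocabulary."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd


class Genotype(str, enum.Enum):
    HOM_REF = "hom-ref"
    HET = "het"
    HOM_ALT = "hom-alt"
    HEMI = "hemi"  # hemizygous for the ALT allele (haploid genotype)
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI)

    @property
    def is_biallelic_alt(self) -> bool:
        """Homozygous or hemizygous for the ALT allele."""
        return self in (Genotype.HOM_ALT, Genotype.HEMI)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PedigreeSample:
    sample_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: bool = False


class Pedigree:
    """A cohort pedigree; unaffected members of *other* families serve as
    pseudo-controls when analyzing one family."""

    def __init__(self, samples: list[PedigreeSample]):
        self._samples = {s.sample_id: s for s in samples}
        if len(self._samples) != len(samples):
            raise ValueError("duplicate sample ids in pedigree")
        for s in samples:
            for parent in (s.father_id, s.mother_id):
                if parent is not None and parent in self._samples:
                    if self._samples[parent].family_id != s.family_id:
                        raise ValueError(
                            f"parent {parent} of {s.sample_id} belongs to another family"
                        )

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._samples

    def __getitem__(self, sample_id: str) -> PedigreeSample:
        return self._samples[sample_id]

    def __iter__(self):
        return iter(self._samples.values())

    def __len__(self) -> int:
        return len(self._samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._samples)

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self:
            seen.setdefault(s.family_id, None)
        return list(seen)

    def family(self, family_id: str) -> list[PedigreeSample]:
        members = [s for s in self if s.family_id == family_id]
        if not members:
            raise KeyError(f"unknown family id {family_id!r}")
        return members

    def unaffected(self, family_id: Optional[str] = None) -> list[PedigreeSample]:
        """Unaffected samples, optionally restricted to one family."""
        return [
            s for s in self
            if not s.affected and (family_id is None or s.family_id == family_id)
        ]

    def pseudo_controls(self, family_id: str) -> list[PedigreeSample]:
        """Unaffected individuals outside the analysis family."""
        return [s for s in self if not s.affected and s.family_id != family_id]


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFFECTED_CODES = {"2": True, "1": False, "0": False, "-9": False}


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (FID IID PAT MAT SEX PHENO, 0 = absent)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str, comment="#",
        names=["family_id", "sample_id", "father_id", "mother_id", "sex", "phenotype"],
    )
    samples = []
    for row in df.itertuples(index=False):
        samples.append(PedigreeSample(
            sample_id=row.sample_id,
            family_id=row.family_id,
            father_id=None if row.father_id in ("0", ".") else row.father_id,
            mother_id=None if row.mother_id in ("0", ".") else row.mother_id,
            sex=_SEX_CODES.get(row.sex, Sex.UNKNOWN),
            affected=_AFFECTED_CODES.get(row.phenotype, False),
        ))
    return Pedigree(samples)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in ped:
            sex = {"male": "1", "female": "2"}.get(s.sex.value, "0")
            fh.write("\t".join([
                s.family_id, s.sample_id,
                s.father_id or "0", s.mother_id or "0",
                sex, "2" if s.affected else "1",
            ]) + "\n")
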