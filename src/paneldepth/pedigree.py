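"""Pedigrees, Mendelian transmission checks and PED-style I/O.

A pedigree carries its assumed inheritance model (autosomal recessive or
autosomal dominant) and a penetrance: the probability that a
genotype-positive individual manifests disease.  Penetrance below 1 is only
meaningful under the dominant model here, where unaffected carriers are a
documented clinical reality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import pandas as pd

from ._util import InvalidParameterError
from .variants import GT_HET, GT_HOM_ALT, GT_HOM_REF

AFFECTED = "yes"
UNAFFECTED = "no"
UNKNOWN = "unknown"

_ALLELES = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1)}
_GAMETES = {GT_HOM_REF: {0}, GT_HET: {0, 1}, GT_HOM_ALT: {1}}


@dataclass
class Member:
    member_id: str
    sex: str  # 'male' | 'female' | 'unknown'
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    affected: str = UNKNOWN


@dataclass
class Pedigree:
    members: List[Member]
    inheritance_model: str = "AR"  # 'AR' | 'AD'
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.inheritance_model not in ("AR", "AD"):
            raise InvalidParameterError(f"inheritance_model must be AR or AD, got {self.inheritance_model!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise InvalidParameterError("penetrance must lie in [0, 1]")
        if self.inheritance_model != "AD" and self.penetrance != 1.0:
            raise InvalidParameterError("penetrance < 1 is only supported under the AD model")
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("duplicate member ids in pedigree")
        byid = self.by_id
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in byid:
                    raise InvalidParameterError(f"parent {pid!r} of {m.member_id!r} not in pedigree")
        self._check_acyclic()

    @property
    def by_id(self) -> Dict[str, Member]:
        return {m.member_id: m for m in self.members}

    def _check_acyclic(self) -> None:
        byid = self.by_id
        state: Dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 1:
                raise InvalidParameterError(f"member {mid!r} is its own ancestor")
            if state.get(mid) == 2:
                return
            state[mid] = 1
            m = byid[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            state[mid] = 2

        for m in self.members:
            visit(m.member_id)

    def topological(self) -> List[Member]:
        """Members ordered parents-before-children."""
        byid = self.by_id
        seen: Dict[str, bool] = {}
        out: List[Member] = []

        def visit(mid: str) -> None:
            if seen.get(mid):
                return
            seen[mid] = True
            m = byid[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            out.append(m)

        for m in self.members:
            visit(m.member_id)
        return out

    def founders(self) -> List[Member]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]


def transmission_consistent(genotypes: Dict[str, str], pedigree: Pedigree) -> bool:
    """True iff every child genotype is producible from its parents' gametes.

    A missing parent (or a member without a genotype) is unconstrained.
    """
    byid = pedigree.by_id
    for mid, gt in genotypes.items():
        m = byid.get(mid)
        if m is None:
            continue
        child_count = sum(_ALLELES[gt])
        gf = _GAMETES[genotypes[m.father_id]] if m.father_id in genotypes else {0, 1}
        gm = _GAMETES[genotypes[m.mother_id]] if m.mother_id in genotypes else {0, 1}
        if not any(f + g == child_count for f in gf for g in gm):
            return False
    return True


def write_ped(pedigree: Pedigree, path, family_id: str = "FAM1") -> None:
    """Write a PED-style TSV (FID IID FATHER MOTHER SEX PHENOTYPE)."""
    sex_code = {"male": 1, "female": 2, "unknown": 0}
    pheno = {UNAFFECTED: 1, AFFECTED: 2, UNKNOWN: 0}
    rows = [
        (family_id, m.member_id, m.father_id or "0", m.mother_id or "0",
         sex_code[m.sex], pheno[m.affected])
        for m in pedigree.members
    ]
    df = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"])
    df.to_csv(path, sep="\t", index=False, header=False)


def read_ped(path, inheritance_model: str = "AR", penetrance: float = 1.0) -> Pedigree:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["fid", "iid", "father", "mother", "sex", "phenotype"],
                     dtype=str)
    sex_name = {"1": "male", "2": "female"}
    pheno_name = {"1": UNAFFECTED, "2": AFFECTED}
    members = [
        Member(
            member_id=r.iid,
            sex=sex_name.get(r.sex, "unknown"),
            father_id=None if r.father == "0" else r.father,
            mother_id=None if r.mother == "0" else r.mother,
            affected=pheno_name.get(r.phenotype, UNKNOWN),
        )
        for r in df.itertuples()
    ]
    return Pedigree(members, inheritance_model=inheritance_model, penetrance=penetrance)
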