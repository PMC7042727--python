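"""Pedigree data model, validation, Mendelian checks and relationship estimation.

The pedigree is a directed parent->child graph.  Founders have neither parent
set; every non-founder must have both.  Individuals carry an affection status
and a flag saying whether genotype data is available for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

AFFECTED = "affected"
UNAFFECTED = "unaffected"

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_AFF_CODES = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN}


@dataclass(frozen=True)
class Individual:
    """One pedigree member."""

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = UNKNOWN
    affection: str = UNKNOWN
    genotyped: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class GenotypeCall:
    """A biallelic genotype call with a per-genotype quality flag.

    Alleles are 0 (reference), 1 (alternate) or ``None`` (missing).  The
    quality flag follows the Complete-Genomics-style convention: ``VQHIGH``
    marks a high-confidence call, ``low`` anything below that, and ``nocall``
    a site where both alleles are missing.
    """

    allele1: Optional[int] = None
    allele2: Optional[int] = None
    quality: str = "nocall"

    def __post_init__(self) -> None:
        both_missing = self.allele1 is None and self.allele2 is None
        if (self.quality == "nocall") != both_missing:
            raise ValueError(
                "quality='nocall' if and only if both alleles are missing; "
                f"got alleles=({self.allele1}, {self.allele2}), quality={self.quality!r}"
            )

    @property
    def is_nocall(self) -> bool:
        return self.quality == "nocall"

    @property
    def alleles(self) -> tuple[Optional[int], Optional[int]]:
        return (self.allele1, self.allele2)

    @property
    def is_het(self) -> bool:
        return {self.allele1, self.allele2} == {0, 1}

    @property
    def is_hom_ref(self) -> bool:
        return self.allele1 == 0 and self.allele2 == 0

    @property
    def is_hom_alt(self) -> bool:
        return self.allele1 == 1 and self.allele2 == 1

    def dosage(self) -> Optional[int]:
        """Alt-allele count, or None if any allele is missing."""
        if self.allele1 is None or self.allele2 is None:
            return None
        return int(self.allele1 != 0) + int(self.allele2 != 0)


NOCALL = GenotypeCall(None, None, "nocall")

HET = GenotypeCall(0, 1, "VQHIGH")
HOM_REF = GenotypeCall(0, 0, "VQHIGH")
HOM_ALT = GenotypeCall(1, 1, "VQHIGH")


@dataclass(frozen=True)
class Violation:
    individual_id: str
    rule: str
    message: str


class Pedigree:
    """An ordered collection of individuals forming one family."""

    def __init__(self, individuals: Iterable[Individual], name: str = "FAM"):
        self.name = name
        self.individuals: list[Individual] = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __iter__(self):
        return iter(self.individuals)

    def get(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    def children_of(self, iid: str) -> list[Individual]:
        return [
            ind
            for ind in self.individuals
            if ind.father_id == iid or ind.mother_id == iid
        ]

    def nuclear_families(self) -> list[tuple[str, str, list[str]]]:
        """(father, mother, children) triples for every mating in the pedigree."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self.individuals:
            if ind.father_id is not None and ind.mother_id is not None:
                fams.setdefault((ind.father_id, ind.mother_id), []).append(ind.id)
        return [(f, m, ch) for (f, m), ch in fams.items()]

    def topological_order(self) -> list[Individual]:
        """Parents before children.  Raises on parent-child cycles."""
        order: list[Individual] = []
        placed: set[str] = set()
        pending = list(self.individuals)
        while pending:
            progressed = False
            remaining = []
            for ind in pending:
                ready = all(
                    pid is None or pid not in self._by_id or pid in placed
                    for pid in (ind.father_id, ind.mother_id)
                )
                if ready:
                    order.append(ind)
                    placed.add(ind.id)
                    progressed = True
                else:
                    remaining.append(ind)
            if not progressed:
                raise ValueError("pedigree contains a parent-child cycle")
            pending = remaining
        return order

    def with_affection(self, affection: Mapping[str, str]) -> "Pedigree":
        """A copy with the given individuals' affection statuses replaced."""
        return Pedigree(
            [
                replace(ind, affection=affection.get(ind.id, ind.affection))
                for ind in self.individuals
            ],
            name=self.name,
        )

    def with_genotyped(self, typed_ids: Iterable[str]) -> "Pedigree":
        """A copy where exactly ``typed_ids`` are flagged as genotyped."""
        typed = set(typed_ids)
        unknown = typed - set(self._by_id)
        if unknown:
            raise KeyError(f"unknown individual ids: {sorted(unknown)}")
        return Pedigree(
            [replace(ind, genotyped=ind.id in typed) for ind in self.individuals],
            name=self.name,
        )


def validate_pedigree(ped: Pedigree) -> list[Violation]:
    """Check the structural invariants; violations are data, not exceptions."""
    violations: list[Violation] = []
    ids = set(ped.ids)
    for ind in ped.individuals:
        has_f, has_m = ind.father_id is not None, ind.mother_id is not None
        if has_f != has_m:
            violations.append(
                Violation(ind.id, "missing-parent",
                          "non-founder must have both parents set")
            )
        for pid, role, want_sex in (
            (ind.father_id, "father", MALE),
            (ind.mother_id, "mother", FEMALE),
        ):
            if pid is None:
                continue
            if pid not in ids:
                violations.append(
                    Violation(ind.id, "unknown-parent",
                              f"{role} {pid!r} not in pedigree")
                )
            else:
                parent = ped.get(pid)
                if parent.sex not in (want_sex, UNKNOWN):
                    violations.append(
                        Violation(ind.id, "parent-sex",
                                  f"{role} {pid!r} has sex {parent.sex}")
                    )

    # flag each individual that is its own ancestor
    for iid in _individuals_on_cycles(ped):
        violations.append(
            Violation(iid, "cycle", "individual is its own ancestor")
        )

    if not any(ind.is_founder for ind in ped.individuals):
        violations.append(Violation("", "no-founder", "pedigree has no founder"))
    return violations


def _individuals_on_cycles(ped: Pedigree) -> list[str]:
    ids = set(ped.ids)
    out = []
    for iid in ped.ids:
        seen: set[str] = set()
        frontier = [iid]
        hit = False
        while frontier:
            cur = frontier.pop()
            ind = ped.get(cur)
            for pid in (ind.father_id, ind.mother_id):
                if pid is None or pid not in ids:
                    continue
                if pid == iid:
                    hit = True
                    frontier = []
                    break
                if pid not in seen:
                    seen.add(pid)
                    frontier.append(pid)
        if hit:
            out.append(iid)
    return out


def mendelian_check(
    ped: Pedigree, genotypes: Mapping[str, GenotypeCall]
) -> set[str]:
    """Ids of children whose genotype is Mendelian-impossible given both parents.

    Missing alleles (half-calls and no-calls) are compatible with anything.
    """
    for iid in genotypes:
        if iid not in ped:
            raise KeyError(f"unknown individual id {iid!r} in genotypes")

    def transmittable(call: Optional[GenotypeCall]) -> set[Optional[int]]:
        if call is None:
            return {0, 1}
        out: set[Optional[int]] = set()
        for a in call.alleles:
            if a is None:
                return {0, 1}
            out.add(a)
        return out

    flagged: set[str] = set()
    for ind in ped.nonfounders():
        child = genotypes.get(ind.id)
        if child is None or child.is_nocall:
            continue
        fa = transmittable(genotypes.get(ind.father_id))
        mo = transmittable(genotypes.get(ind.mother_id))
        a1, a2 = child.alleles
        ok = False
        for x, y in ((a1, a2), (a2, a1)):
            if (x is None or x in fa) and (y is None or y in mo):
                ok = True
                break
        if not ok:
            flagged.add(ind.id)
    return flagged


def kinship_estimate(
    genotypes: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Method-of-moments kinship from a (individuals x sites) dosage matrix.

    ``genotypes`` holds alt-allele dosages 0/1/2 with ``np.nan`` for missing
    (half-called genotypes should be encoded as missing).  ``freqs`` are the
    per-site alt allele frequencies, required to lie strictly in (0, 1).
    The estimator is the standardized-genotype cross-product averaged over
    sites; its expectation is the kinship coefficient (0.5 on the diagonal
    for a non-inbred individual, 0.25 for parent-offspring, 0 for unrelated).
    """
    genotypes = np.asarray(genotypes, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if genotypes.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (individuals x sites)")
    if genotypes.shape[1] != freqs.shape[0]:
        raise ValueError("freqs length must match number of sites")
    poly = (freqs > 0.0) & (freqs < 1.0)
    if not poly.any():
        raise ValueError("kinship estimator undefined: no polymorphic site")
    g = genotypes[:, poly]
    p = freqs[poly]
    centred = g - 2.0 * p
    denom = 4.0 * p * (1.0 - p)
    weighted = centred / denom  # (n, s)
    mask = ~np.isnan(g)
    weighted = np.where(mask, weighted, 0.0)
    centred = np.where(mask, centred, 0.0)
    num = weighted @ centred.T
    counts = mask.astype(float) @ mask.astype(float).T
    if np.any(counts == 0):
        raise ValueError("some individual pair shares no called site")
    phi = num / counts
    return (phi + phi.T) / 2.0


def informative_meioses(
    ped: Pedigree, carriers: set[str], typed: set[str]
) -> int:
    """Number of phase-resolvable carrier transmissions in the pedigree.

    A meiosis from a determined carrier parent is scoreable when the child's
    carrier status is determined (affected => carrier, unaffected =>
    non-carrier under a near-fully-penetrant dominant model) and the marker
    allele the parent transmitted is observable -- either because the child
    itself is genotyped, or because the child is a carrier whose transmitted
    haplotype is revealed through an unbroken chain of carrier descendants
    ending in a genotyped carrier.  One meiosis is lost to the unknown phase
    of the top carrier, so each additional non-recombinant meiosis adds
    log10(2) to the maximal attainable LOD.
    """
    unknown = carriers - set(ped.ids)
    if unknown:
        raise KeyError(f"carrier ids not in pedigree: {sorted(unknown)}")

    def status(ind: Individual) -> str:
        if ind.id in carriers or ind.affection == AFFECTED:
            return "C"
        if ind.affection == UNAFFECTED:
            return "N"
        return "U"

    stat = {ind.id: status(ind) for ind in ped.individuals}

    def carrier_chain_typed(iid: str, seen: frozenset = frozenset()) -> bool:
        """True if iid (a carrier) is genotyped or has a genotyped carrier
        descendant reachable through carriers only."""
        if iid in typed:
            return True
        for child in ped.children_of(iid):
            if child.id in seen:
                continue
            if stat[child.id] == "C" and carrier_chain_typed(
                child.id, seen | {iid}
            ):
                return True
        return False

    scoreable = 0
    scoring_parents: set[str] = set()
    for ind in ped.individuals:
        if stat[ind.id] not in ("C", "N"):
            continue
        for pid in (ind.father_id, ind.mother_id):
            if pid is None or pid not in ped:
                continue
            if stat[pid] != "C":
                continue
            observable = ind.id in typed or (
                stat[ind.id] == "C" and carrier_chain_typed(ind.id)
            )
            if observable:
                scoreable += 1
                scoring_parents.add(pid)
    if scoreable == 0:
        return 0

    # one meiosis is lost to the top carrier's unknown phase; a second is
    # lost when the top carrier and its spouse are both untyped, because the
    # parental origin of the children's alleles is then ambiguous as well
    # (verified against the exact-likelihood engine)
    def top_carrier() -> str:
        cur = next(iter(scoring_parents))
        while True:
            ind = ped.get(cur)
            parent_c = [
                p
                for p in (ind.father_id, ind.mother_id)
                if p is not None and p in ped and stat[p] == "C"
            ]
            if not parent_c:
                return cur
            cur = parent_c[0]

    top = top_carrier()
    penalty = 1
    spouses = {
        other
        for c in ped.children_of(top)
        for other in (c.father_id, c.mother_id)
        if other is not None and other != top
    }
    if top not in typed and not (spouses & typed):
        penalty = 2
    return max(scoreable - penalty, 0)
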