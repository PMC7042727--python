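"""Shared fixtures: pedigree builders and a random loop-free pedigree generator."""

from __future__ import annotations

import numpy as np
import pytest

from famvar.linkage import DiseaseModel, MarkerLocus
from famvar.pedigree import AFFECTED, FEMALE, MALE, UNAFFECTED, Individual, Pedigree


def make_individual(iid, fa=None, mo=None, sex="unknown", aff="unknown", typed=False):
    return Individual(iid, fa, mo, sex, aff, typed)


@pytest.fixture
def study_ped():
    from famvar.datasets import load_study_pedigree

    return load_study_pedigree()


@pytest.fixture
def nuclear_ped():
    """Two parents, two children; father affected."""
    return Pedigree(
        [
            make_individual("F", sex=MALE, aff=AFFECTED),
            make_individual("M", sex=FEMALE, aff=UNAFFECTED),
            make_individual("C1", "F", "M", MALE, AFFECTED),
            make_individual("C2", "F", "M", FEMALE, UNAFFECTED),
        ],
        name="NUC",
    )


def random_pedigree(rng: np.random.Generator, max_members: int = 8) -> Pedigree:
    """A random loop-free pedigree built by adding spouses and children."""
    n = int(rng.integers(1, max_members + 1))
    inds = [make_individual("I0", sex=MALE)]
    couples: list[tuple[str, str]] = []
    k = 1
    while k < n:
        if couples and rng.random() < 0.6:
            fa, mo = couples[int(rng.integers(len(couples)))]
            inds.append(make_individual(f"I{k}", fa, mo, sex=_rand_sex(rng)))
        else:
            # marry a new founder to a random existing individual
            partner = inds[int(rng.integers(len(inds)))]
            spouse_sex = FEMALE if partner.sex == MALE else MALE
            spouse = make_individual(f"I{k}", sex=spouse_sex)
            inds.append(spouse)
            if partner.sex == MALE:
                couples.append((partner.id, spouse.id))
            else:
                couples.append((spouse.id, partner.id))
        k += 1
    out = []
    for ind in inds:
        aff = ["unknown", AFFECTED, UNAFFECTED][int(rng.integers(3))]
        out.append(
            Individual(ind.id, ind.father_id, ind.mother_id, ind.sex, aff, False)
        )
    return Pedigree(out, name="RND")


def _rand_sex(rng):
    return MALE if rng.random() < 0.5 else FEMALE


def random_model(rng: np.random.Generator) -> DiseaseModel:
    return DiseaseModel(
        float(rng.uniform(0.001, 0.5)),
        tuple(sorted(rng.uniform(0.0, 1.0, size=3))),
    )


def random_marker(
    ped: Pedigree, rng: np.random.Generator, typed_prob: float = 0.75
) -> MarkerLocus:
    f = float(rng.uniform(0.1, 0.9))
    genos = {}
    for ind in ped.individuals:
        if rng.random() < typed_prob:
            genos[ind.id] = tuple(sorted(rng.integers(0, 2, size=2)))
        else:
            genos[ind.id] = None
    return MarkerLocus(("A", "B"), np.array([f, 1 - f]), genos)


def enumeration_cells(ped: Pedigree, marker: MarkerLocus) -> float:
    """Upper bound on the oracle's joint-table size."""
    total = 1.0
    for ind in ped.individuals:
        g = marker.genotypes.get(ind.id)
        total *= 16 if g is None else (4 if g[0] == g[1] else 8)
    return total
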