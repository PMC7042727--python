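"""Bundled study fixtures.

The family pedigree ships as an editable PED file transcribed from the
published pedigree chart: an affected founder couple member (100, no DNA
available) with five children -- three affected (102, 121, 124) and two
elderly unaffected (122, 123) -- an affected grandchild (200) with two
younger unaffected children (201, 202), and two younger unaffected
grandchildren (221, 222) of individual 122.  Married-in spouses (101, 103,
203, 126) carry unknown affection and were never sampled.
"""

from __future__ import annotations

from importlib import resources

from .io import read_ped
from .pedigree import Pedigree

#: The six whole-genome-sequenced members (two affected, four unaffected).
WGS_TYPED = frozenset({"102", "122", "123", "200", "201", "202"})

#: The four additional Sanger-genotyped members.
SANGER_TYPED = frozenset({"121", "124", "221", "222"})

#: WGS segregation cases and the elderly unaffected controls.
WGS_CASES = frozenset({"102", "200"})
WGS_CONTROLS = frozenset({"122", "123"})


def load_study_pedigree() -> Pedigree:
    """The ten-member AD family (plus unsampled spouses/founders)."""
    ref = resources.files("famvar.data").joinpath("family.ped")
    with resources.as_file(ref) as path:
        peds = read_ped(path)
    return peds["AD1"]
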