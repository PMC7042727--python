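"""Ordered variant-prioritization funnel for a dominant family design.

Raw per-genome call sets are merged, quality-filtered, restricted to
haplotype regions shared by the two cases, segregation-filtered under a
dominant model, and then narrowed by population frequency, functional class,
gene lists and a pathogenicity/conservation vote.  Every stage records the
surviving variant keys so the whole funnel is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .pedigree import NOCALL, GenotypeCall

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

#: The eight pathogenicity predictors consumed from the annotation table.
PATHO_PREDICTORS = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "PROVEAN",
    "MetaSVM",
    "FATHMM-MKL",
)

#: The four conservation scores.
CONS_SCORES = ("DAMN", "CADD", "GERP", "SiPhy")

FUNC_CLASSES = frozenset(
    {
        "nonsynonymous",
        "synonymous",
        "stopgain",
        "splice",
        "frameshift_indel",
        "nonframeshift_indel",
        "other_exonic",
        "non_exonic",
    }
)

#: Exonic, non-synonymous classes retained by the functional filter.
EXONIC_DAMAGE_CLASSES = frozenset(
    {
        "nonsynonymous",
        "stopgain",
        "splice",
        "frameshift_indel",
        "nonframeshift_indel",
        "other_exonic",
    }
)

#: Classes treated as loss-of-function by the pathogenicity vote.
LOF_CLASSES = frozenset({"stopgain", "splice", "frameshift_indel"})

DELETERIOUS = "deleterious"
CONSERVED = "conserved"

FUNNEL_STAGES = (
    "union",
    "quality",
    "shared_region",
    "dominant",
    "rare",
    "functional",
    "cmd_excluded",
    "brain_expressed",
    "pathogenic",
    "candidates",
)


@dataclass
class VariantRecord:
    """A site plus per-individual genotype calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def call(self, iid: str) -> GenotypeCall:
        return self.calls.get(iid, NOCALL)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class AnnotationRecord:
    """Functional/frequency/score annotation for one variant."""

    key: VariantKey
    gene: Optional[str]
    func_class: str
    pop_freqs: dict[str, float] = field(default_factory=dict)
    patho_calls: dict[str, str] = field(default_factory=dict)
    cons_calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown functional class {self.func_class!r}")
        for src, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"population frequency {src}={f} outside [0,1]")

    @property
    def n_deleterious(self) -> int:
        return sum(1 for v in self.patho_calls.values() if v == DELETERIOUS)

    @property
    def n_conserved(self) -> int:
        return sum(1 for v in self.cons_calls.values() if v == CONSERVED)


@dataclass
class FunnelConfig:
    case_ids: frozenset[str] = frozenset()
    control_ids: frozenset[str] = frozenset()
    max_pop_freq: float = 0.01
    min_deleterious: int = 5
    min_conserved: int = 2
    window_size: int = 100
    max_mismatch_frac: float = 0.02
    # strict reading: controls must be explicitly called homozygous-reference;
    # the laxer reading also accepts control no-calls
    require_hom_ref_controls: bool = True
    apply_shared_regions: bool = True
    max_indel_size: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.max_pop_freq <= 1.0:
            raise ValueError("max_pop_freq must be in (0, 1]")
        if self.min_deleterious > len(PATHO_PREDICTORS):
            raise ValueError("min_deleterious exceeds number of predictors")
        if self.min_conserved > len(CONS_SCORES):
            raise ValueError("min_conserved exceeds number of conservation scores")
        if self.case_ids & self.control_ids:
            raise ValueError("case and control sets overlap")


@dataclass(frozen=True)
class SharedRegion:
    chrom: str
    start: int
    end: int
    n_sites: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")


@dataclass
class FunnelStage:
    name: str
    survivors: list[VariantKey]
    n_removed: int

    @property
    def n(self) -> int:
        return len(self.survivors)


@dataclass
class FunnelReport:
    stages: list[FunnelStage] = field(default_factory=list)
    candidate_flags: dict[VariantKey, str] = field(default_factory=dict)
    shared_regions: list[SharedRegion] = field(default_factory=list)

    def add(self, name: str, survivors: Iterable[VariantKey], previous: int) -> None:
        surv = sorted(survivors)
        self.stages.append(FunnelStage(name, surv, previous - len(surv)))

    def counts(self) -> dict[str, int]:
        return {s.name: s.n for s in self.stages}

    def removed(self) -> dict[str, int]:
        return {s.name: s.n_removed for s in self.stages}

    @property
    def final(self) -> list[VariantKey]:
        return self.stages[-1].survivors if self.stages else []


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def union_variants(
    per_genome: Mapping[str, Iterable[VariantRecord]]
) -> list[VariantRecord]:
    """Merge per-genome call lists into one record per (chrom,pos,ref,alt).

    Individuals without a call at a merged site are left as no-calls.
    Conflicting REF alleles at the same position are an input error.
    """
    merged: dict[VariantKey, VariantRecord] = {}
    ref_at: dict[tuple[str, int], str] = {}
    for iid, records in per_genome.items():
        for rec in records:
            prev_ref = ref_at.setdefault((rec.chrom, rec.pos), rec.ref)
            if prev_ref != rec.ref:
                raise ValueError(
                    f"conflicting REF at {rec.chrom}:{rec.pos}: "
                    f"{prev_ref!r} vs {rec.ref!r}"
                )
            out = merged.setdefault(
                rec.key, VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt, {})
            )
            for sample, call in rec.calls.items():
                out.calls[sample] = call
    return sorted(merged.values(), key=lambda v: v.key)


def quality_filter(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep variants with a VQHIGH call in at least one individual."""
    return [
        v
        for v in variants
        if any(c.quality == "VQHIGH" for c in v.calls.values())
    ]


def _zero_ibs(a: GenotypeCall, b: GenotypeCall) -> bool:
    sa = {x for x in a.alleles if x is not None}
    sb = {x for x in b.alleles if x is not None}
    return bool(sa) and bool(sb) and not (sa & sb)


def shared_regions(
    variants: Iterable[VariantRecord],
    case_pair: Sequence[str],
    config: FunnelConfig,
) -> list[SharedRegion]:
    """IBS-window scan for haplotype blocks shared by the two cases.

    Sliding windows of ``window_size`` consecutive mutually-called sites in
    which the fraction of zero-IBS sites is at most ``max_mismatch_frac``
    are merged into maximal regions.
    """
    if len(case_pair) != 2:
        raise ValueError("shared_regions requires exactly two case ids")
    a, b = case_pair
    by_chrom: dict[str, list[tuple[int, bool]]] = {}
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        ca, cb = v.call(a), v.call(b)
        if ca.is_nocall or cb.is_nocall:
            continue
        by_chrom.setdefault(v.chrom, []).append((v.pos, _zero_ibs(ca, cb)))

    w = config.window_size
    out: list[SharedRegion] = []
    for chrom, sites in sorted(by_chrom.items()):
        if len(sites) < w:
            logger.warning(
                "chromosome %s has %d informative sites (< window %d); no regions",
                chrom, len(sites), w,
            )
            continue
        mism = [int(z) for _, z in sites]
        prefix = [0]
        for z in mism:
            prefix.append(prefix[-1] + z)
        max_bad = config.max_mismatch_frac * w
        in_run, run_start = False, 0
        runs: list[tuple[int, int]] = []  # [start_site, end_site] inclusive
        for i in range(len(sites) - w + 1):
            ok = (prefix[i + w] - prefix[i]) <= max_bad
            if ok and not in_run:
                in_run, run_start = True, i
            elif not ok and in_run:
                runs.append((run_start, i + w - 2))
                in_run = False
        if in_run:
            runs.append((run_start, len(sites) - 1))
        for s, e in runs:
            out.append(
                SharedRegion(chrom, sites[s][0], sites[e][0], e - s + 1)
            )
    return out


def region_filter(
    variants: Iterable[VariantRecord], regions: Sequence[SharedRegion]
) -> list[VariantRecord]:
    """Variants positioned inside any region (1-based inclusive)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    return [
        v
        for v in variants
        if any(s <= v.pos <= e for s, e in by_chrom.get(v.chrom, []))
    ]


def dominant_filter(
    variants: Iterable[VariantRecord],
    case_ids: Iterable[str],
    control_ids: Iterable[str],
    require_hom_ref_controls: bool = True,
) -> list[VariantRecord]:
    """Dominant-model segregation filter.

    A variant survives iff every case is heterozygous or no-call, at least
    one case is actually called heterozygous, and every control is called
    homozygous-reference (with ``require_hom_ref_controls=False``, control
    no-calls are also tolerated).
    """
    cases, controls = set(case_ids), set(control_ids)
    if cases & controls:
        raise ValueError("an individual is in both the case and control sets")
    if not cases or not controls:
        raise ValueError("case and control sets must be non-empty")
    out = []
    for v in variants:
        case_calls = [v.call(i) for i in cases]
        if not all(c.is_het or c.is_nocall for c in case_calls):
            continue
        if not any(c.is_het for c in case_calls):
            continue
        ctrl_calls = [v.call(i) for i in controls]
        if require_hom_ref_controls:
            if not all(c.is_hom_ref for c in ctrl_calls):
                continue
        else:
            if not all(c.is_hom_ref or c.is_nocall for c in ctrl_calls):
                continue
        out.append(v)
    return out


def rarity_filter(
    variants: Iterable[VariantRecord],
    annotations: Mapping[VariantKey, AnnotationRecord],
    config: FunnelConfig,
) -> list[VariantRecord]:
    """Keep variants rare (<= max_pop_freq) in every available population.

    Variants without any frequency entry are treated as novel and kept.
    """
    out = []
    for v in variants:
        ann = annotations.get(v.key)
        freqs = ann.pop_freqs.values() if ann is not None else ()
        if all(f <= config.max_pop_freq for f in freqs):
            out.append(v)
    return out


def functional_filter(
    variants: Iterable[VariantRecord],
    annotations: Mapping[VariantKey, AnnotationRecord],
) -> list[VariantRecord]:
    """Keep exonic, non-synonymous variant classes; unannotated are dropped."""
    out = []
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None:
            logger.info("variant %s lacks annotation; removed", v.key)
            continue
        if ann.func_class in EXONIC_DAMAGE_CLASSES:
            out.append(v)
    return out


def gene_list_filters(
    variants: Iterable[VariantRecord],
    annotations: Mapping[VariantKey, AnnotationRecord],
    cmd_genes: set[str],
    brain_genes: set[str],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Two sequential stages: drop commonly-mutated genes, keep brain-expressed.

    Returns (after CMD exclusion, after brain-expression filter).  Variants
    without a gene symbol are removed at the brain-expression stage.
    """
    after_cmd = []
    for v in variants:
        ann = annotations.get(v.key)
        gene = ann.gene if ann is not None else None
        if gene is not None and gene in cmd_genes:
            continue
        after_cmd.append(v)
    after_brain = []
    for v in after_cmd:
        ann = annotations.get(v.key)
        gene = ann.gene if ann is not None else None
        if gene is None:
            logger.info("variant %s has no gene symbol; removed at brain stage", v.key)
            continue
        if gene in brain_genes:
            after_brain.append(v)
    return after_cmd, after_brain


def pathogenicity_vote(ann: AnnotationRecord, config: FunnelConfig) -> bool:
    """Loss-of-function, or >= min_deleterious predictor and >= min_conserved
    conservation votes.  Missing calls count against the vote."""
    if ann.func_class in LOF_CLASSES:
        return True
    return (
        ann.n_deleterious >= config.min_deleterious
        and ann.n_conserved >= config.min_conserved
    )


def candidate_prioritize(
    variants: Iterable[VariantRecord],
    annotations: Mapping[VariantKey, AnnotationRecord],
    nd_genes: set[str],
    network_edges: Iterable[tuple[str, str]],
) -> dict[VariantKey, str]:
    """Flag each variant as known_candidate / network_linked / neither."""
    neighbours: dict[str, set[str]] = {}
    for a, b in network_edges:
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)
    flags: dict[VariantKey, str] = {}
    for v in variants:
        ann = annotations.get(v.key)
        gene = ann.gene if ann is not None else None
        if gene is not None and gene in nd_genes:
            flags[v.key] = "known_candidate"
        elif gene is not None and neighbours.get(gene, set()) & nd_genes:
            flags[v.key] = "network_linked"
        else:
            flags[v.key] = "neither"
    return flags


def run_funnel(
    per_genome: Mapping[str, Iterable[VariantRecord]],
    annotations: Mapping[VariantKey, AnnotationRecord],
    cmd_genes: set[str],
    brain_genes: set[str],
    nd_genes: set[str],
    network_edges: Iterable[tuple[str, str]],
    config: FunnelConfig,
) -> FunnelReport:
    """Run every funnel stage in order and assemble the audit report."""
    report = FunnelReport()

    variants = union_variants(per_genome)
    report.add("union", [v.key for v in variants], len(variants))

    variants = quality_filter(variants)
    report.add("quality", [v.key for v in variants], report.stages[-1].n)

    if config.apply_shared_regions and len(config.case_ids) == 2:
        regions = shared_regions(variants, sorted(config.case_ids), config)
        report.shared_regions = regions
        variants = region_filter(variants, regions)
    report.add("shared_region", [v.key for v in variants], report.stages[-1].n)

    variants = dominant_filter(
        variants,
        config.case_ids,
        config.control_ids,
        config.require_hom_ref_controls,
    )
    report.add("dominant", [v.key for v in variants], report.stages[-1].n)

    variants = rarity_filter(variants, annotations, config)
    report.add("rare", [v.key for v in variants], report.stages[-1].n)

    variants = functional_filter(variants, annotations)
    report.add("functional", [v.key for v in variants], report.stages[-1].n)

    after_cmd, after_brain = gene_list_filters(
        variants, annotations, cmd_genes, brain_genes
    )
    report.add("cmd_excluded", [v.key for v in after_cmd], report.stages[-1].n)
    report.add("brain_expressed", [v.key for v in after_brain], report.stages[-1].n)

    variants = [
        v
        for v in after_brain
        if v.key in annotations and pathogenicity_vote(annotations[v.key], config)
    ]
    report.add("pathogenic", [v.key for v in variants], report.stages[-1].n)

    report.candidate_flags = candidate_prioritize(
        variants, annotations, nd_genes, network_edges
    )
    report.add("candidates", [v.key for v in variants], report.stages[-1].n)
    return report


# ---------------------------------------------------------------------------
# Population-frequency arithmetic
# ---------------------------------------------------------------------------


def carrier_allele_freq(n_het_carriers: int, n_individuals: int) -> float:
    """Allele frequency implied by heterozygous carriers among diploids."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return n_het_carriers / (2 * n_individuals)


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)
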