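"""Synthetic-data generators emulating the study's inputs.

Three generators, all reproducible from a single seed: ``gene_drop`` produces
pedigree genotypes with a planted fully-penetrant dominant variant and a
truth record of every transmission, ``make_annotations`` builds annotation
tables with configurable per-stage funnel retention, and ``make_expression``
produces probe-level matrices with specified gene-gene correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .expression import AD_GROUP, CONTROL_GROUP, ExpressionMatrix
from .funnel import (
    CONS_SCORES,
    PATHO_PREDICTORS,
    AnnotationRecord,
    VariantKey,
    VariantRecord,
)
from .pedigree import AFFECTED, UNAFFECTED, GenotypeCall, Pedigree

_STREAMS = {
    "founders": 1,
    "transmissions": 2,
    "quality": 3,
    "annotations": 4,
    "expression": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Counter-based substream so adding a generator never perturbs others."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream]]))


@dataclass
class PlantedVariant:
    chrom: str = "chr2"
    pos: int = 9_630_000
    ref: str = "C"
    alt: str = "A"
    founder_id: str = ""
    gene: str = "ADAM17"

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_background_variants: int = 1000
    chrom_sites: dict[str, int] = field(
        default_factory=lambda: {"chr1": 500, "chr2": 500}
    )
    site_spacing: int = 10_000
    planted: Optional[PlantedVariant] = None
    nocall_rate: float = 0.0
    lowq_rate: float = 0.0
    freq_range: tuple[float, float] = (0.1, 0.5)
    crossovers_per_meiosis: int = 1

    def __post_init__(self) -> None:
        for r in (self.nocall_rate, self.lowq_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0,1]")
        total = sum(self.chrom_sites.values())
        if total != self.n_background_variants:
            # distribute evenly if the defaults were overridden inconsistently
            chroms = list(self.chrom_sites)
            base = self.n_background_variants // len(chroms)
            self.chrom_sites = {c: base for c in chroms}
            self.chrom_sites[chroms[-1]] += self.n_background_variants - base * len(
                chroms
            )


@dataclass
class TruthRecord:
    """Ground truth for one gene-drop: origins, carriers and parameters."""

    #: individual id -> chrom -> (2, n_sites) founder-haplotype labels
    origins: dict[str, dict[str, np.ndarray]]
    #: chrom -> per-site 1-based positions
    positions: dict[str, np.ndarray]
    #: chrom -> per-site population alt-allele frequency
    site_freqs: dict[str, np.ndarray]
    #: ids heterozygous for the planted variant
    planted_carriers: set[str]
    planted: Optional[PlantedVariant]
    #: gene-pair -> configured correlation (filled by make_expression)
    pair_correlations: dict[tuple[str, str], float] = field(default_factory=dict)

    def ibd_segments(self, id1: str, id2: str) -> list[tuple[str, int, int]]:
        """Maximal runs of sites where the pair shares >= 1 founder haplotype."""
        out = []
        for chrom, pos in self.positions.items():
            o1 = self.origins[id1][chrom]
            o2 = self.origins[id2][chrom]
            share = (
                (o1[0] == o2[0])
                | (o1[0] == o2[1])
                | (o1[1] == o2[0])
                | (o1[1] == o2[1])
            )
            start = None
            for i, s in enumerate(share):
                if s and start is None:
                    start = i
                elif not s and start is not None:
                    out.append((chrom, int(pos[start]), int(pos[i - 1])))
                    start = None
            if start is not None:
                out.append((chrom, int(pos[start]), int(pos[-1])))
        return out


def _carrier_closure(ped: Pedigree, founder_id: str) -> set[str]:
    """The planted variant's carriers: the founder plus every affected that
    connects to it through an unbroken chain of affected ancestors."""
    if founder_id not in ped or not ped.get(founder_id).is_founder:
        raise ValueError(f"planted carrier {founder_id!r} is not a founder")
    carriers = {founder_id}
    changed = True
    while changed:
        changed = False
        for ind in ped.individuals:
            if ind.id in carriers or ind.affection != AFFECTED:
                continue
            if ind.father_id in carriers or ind.mother_id in carriers:
                carriers.add(ind.id)
                changed = True
    affected = {i.id for i in ped.individuals if i.affection == AFFECTED}
    unreachable = affected - carriers
    if unreachable == affected:
        raise ValueError(
            f"planted carrier {founder_id!r} is not an ancestor of any affected"
        )
    if unreachable:
        raise ValueError(
            "affected individuals unreachable through affected chains: "
            f"{sorted(unreachable)}"
        )
    return carriers


def gene_drop(
    ped: Pedigree, config: SimulationConfig
) -> tuple[dict[str, list[VariantRecord]], TruthRecord]:
    """Drop founder haplotypes through the pedigree.

    Returns per-genome call lists (every site, including explicit
    homozygous-reference calls, as a testvariant-style call set) and the
    truth record.  Background sites are linked within a chromosome with
    ``crossovers_per_meiosis`` crossovers per transmission.
    """
    rng_f = stream_rng(config.seed, "founders")
    rng_t = stream_rng(config.seed, "transmissions")
    rng_q = stream_rng(config.seed, "quality")

    founders = ped.founders()
    hap_label = {}
    for k, f in enumerate(founders):
        hap_label[f.id] = (2 * k, 2 * k + 1)

    positions = {
        chrom: np.arange(1, n + 1) * config.site_spacing
        for chrom, n in config.chrom_sites.items()
    }
    site_freqs = {
        chrom: rng_f.uniform(*config.freq_range, size=n)
        for chrom, n in config.chrom_sites.items()
    }

    # founder haplotype alleles per chromosome: (2F, n_sites) of 0/1
    founder_alleles = {
        chrom: (rng_f.random((2 * len(founders), n)) < site_freqs[chrom]).astype(
            np.int8
        )
        for chrom, n in config.chrom_sites.items()
    }

    planted = config.planted
    carriers: set[str] = set()
    if planted is not None:
        if planted.chrom not in positions:
            raise ValueError(f"planted chromosome {planted.chrom!r} not simulated")
        carriers = _carrier_closure(ped, planted.founder_id)

    origins: dict[str, dict[str, np.ndarray]] = {}
    order = ped.topological_order()
    for ind in order:
        origins[ind.id] = {}
        for chrom, n in config.chrom_sites.items():
            if ind.is_founder:
                labels = hap_label[ind.id]
                origins[ind.id][chrom] = np.vstack(
                    [np.full(n, labels[0]), np.full(n, labels[1])]
                )
            else:
                rows = []
                for pid in (ind.father_id, ind.mother_id):
                    parent = origins[pid][chrom]
                    which = _transmit_rows(config.crossovers_per_meiosis, n, rng_t)
                    if (
                        planted is not None
                        and chrom == planted.chrom
                        and pid in carriers
                    ):
                        site = _planted_site(positions[chrom], planted.pos)
                        disease_hap = _disease_hap_row(
                            origins, ped, pid, chrom, site, carriers
                        )
                        want = ind.id in carriers
                        if (which[site] == disease_hap) != want:
                            # mirror the whole meiosis; by symmetry this is
                            # exact conditioning on the planted transmission
                            which = 1 - which
                    rows.append(parent[which, np.arange(n)])
                origins[ind.id][chrom] = np.vstack(rows)

    truth = TruthRecord(
        origins=origins,
        positions=positions,
        site_freqs=site_freqs,
        planted_carriers={c for c in carriers},
        planted=planted,
    )

    per_genome: dict[str, list[VariantRecord]] = {}
    for ind in ped.individuals:
        records: list[VariantRecord] = []
        for chrom, n in config.chrom_sites.items():
            ori = origins[ind.id][chrom]
            alleles = np.vstack(
                [founder_alleles[chrom][ori[0], np.arange(n)],
                 founder_alleles[chrom][ori[1], np.arange(n)]]
            )
            nocall = rng_q.random(n) < config.nocall_rate
            lowq = rng_q.random(n) < config.lowq_rate
            for i in range(n):
                pos = int(positions[chrom][i])
                if planted is not None and chrom == planted.chrom and pos == planted.pos:
                    continue  # reserved coordinate
                if nocall[i]:
                    call = GenotypeCall(None, None, "nocall")
                else:
                    q = "low" if lowq[i] else "VQHIGH"
                    call = GenotypeCall(int(alleles[0, i]), int(alleles[1, i]), q)
                records.append(
                    VariantRecord(chrom, pos, "A", "G", {ind.id: call})
                )
            if planted is not None and chrom == planted.chrom:
                het = ind.id in carriers
                call = GenotypeCall(0, 1, "VQHIGH") if het else GenotypeCall(0, 0, "VQHIGH")
                records.append(
                    VariantRecord(
                        planted.chrom, planted.pos, planted.ref, planted.alt,
                        {ind.id: call},
                    )
                )
        per_genome[ind.id] = records
    return per_genome, truth


def _planted_site(positions: np.ndarray, pos: int) -> int:
    """Index of the background site nearest the planted coordinate."""
    return int(np.argmin(np.abs(positions - pos)))


def _disease_hap_row(
    origins, ped: Pedigree, iid: str, chrom: str, site: int, carriers
) -> int:
    """Which of iid's two haplotype rows carries the planted allele at site.

    The disease haplotype of the planted founder is its first haplotype; for
    descendants it is whichever row originates from a carrier chain.
    """
    if ped.get(iid).is_founder:
        return 0
    ind = ped.get(iid)
    for row, pid in ((0, ind.father_id), (1, ind.mother_id)):
        if pid in carriers:
            parent_row = _disease_hap_row(origins, ped, pid, chrom, site, carriers)
            if origins[iid][chrom][row, site] == origins[pid][chrom][parent_row, site]:
                return row
    # carrier status is enforced during transmission, so this is unreachable
    # unless called on a non-carrier
    raise ValueError(f"{iid} does not carry the planted haplotype")


def _transmit_rows(
    n_crossovers: int, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """One meiosis as a 0/1 parental-row indicator per site: a random
    starting haplotype with ``n_crossovers`` uniform switch points."""
    current = int(rng.integers(0, 2))
    cuts = (
        np.sort(rng.integers(1, n_sites, size=n_crossovers))
        if n_sites > 1
        else np.array([], dtype=int)
    )
    out = np.empty(n_sites, dtype=np.int64)
    prev = 0
    for cut in [*cuts, n_sites]:
        out[prev:cut] = current
        current = 1 - current
        prev = cut
    return out


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSimConfig:
    """Per-stage retention probabilities for background variants."""

    retention: dict[str, float] = field(
        default_factory=lambda: {
            "rare": 0.5,
            "functional": 0.5,
            "cmd": 0.9,
            "brain": 0.5,
            "patho": 0.5,
        }
    )
    nd_gene: str = "APP"
    freq_sources: tuple[str, ...] = ("G1000_eur", "ESP6500_ea", "ExAC_NFE")


@dataclass
class GeneLists:
    cmd_genes: set[str]
    brain_genes: set[str]
    nd_genes: set[str]
    network_edges: list[tuple[str, str]]


def make_annotations(
    variant_keys: Iterable[VariantKey],
    truth: TruthRecord,
    config: AnnotationSimConfig,
    seed: int,
) -> tuple[dict[VariantKey, AnnotationRecord], GeneLists]:
    """Annotation table plus gene lists with configured funnel retention.

    The planted variant is annotated to satisfy every funnel rule and its
    gene is a known neurodegeneration candidate; each background variant
    passes each annotation-driven stage independently with the configured
    retention probability.
    """
    rng = stream_rng(seed, "annotations")
    ret = config.retention
    planted_key = truth.planted.key if truth.planted is not None else None

    annotations: dict[VariantKey, AnnotationRecord] = {}
    cmd_genes: set[str] = set()
    brain_genes: set[str] = set()
    nd_genes = {config.nd_gene}
    edges: list[tuple[str, str]] = []

    for i, key in enumerate(sorted(set(variant_keys))):
        if key == planted_key:
            gene = truth.planted.gene
            nd_genes.add(gene)
            brain_genes.add(gene)
            annotations[key] = AnnotationRecord(
                key=key,
                gene=gene,
                func_class="nonsynonymous",
                pop_freqs={s: 0.0001 for s in config.freq_sources},
                patho_calls={p: "deleterious" for p in PATHO_PREDICTORS[:7]}
                | {PATHO_PREDICTORS[7]: "tolerated"},
                cons_calls={c: "conserved" for c in CONS_SCORES[:3]}
                | {CONS_SCORES[3]: "not_conserved"},
            )
            continue
        gene = f"GENE{i:05d}"
        rare = rng.random() < ret["rare"]
        functional = rng.random() < ret["functional"]
        keep_cmd = rng.random() < ret["cmd"]
        brain = rng.random() < ret["brain"]
        patho = rng.random() < ret["patho"]

        if not keep_cmd:
            cmd_genes.add(gene)
        if brain:
            brain_genes.add(gene)
        freq = rng.uniform(0.0, 0.01) if rare else rng.uniform(0.011, 0.5)
        n_del = int(rng.integers(5, 9)) if patho else int(rng.integers(0, 5))
        n_cons = int(rng.integers(2, 5)) if patho else int(rng.integers(0, 2))
        annotations[key] = AnnotationRecord(
            key=key,
            gene=gene,
            func_class="nonsynonymous" if functional else "synonymous",
            pop_freqs={s: freq for s in config.freq_sources},
            patho_calls={
                p: ("deleterious" if j < n_del else "tolerated")
                for j, p in enumerate(PATHO_PREDICTORS)
            },
            cons_calls={
                c: ("conserved" if j < n_cons else "not_conserved")
                for j, c in enumerate(CONS_SCORES)
            },
        )
    return annotations, GeneLists(cmd_genes, brain_genes, nd_genes, edges)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimConfig:
    #: (gene_a, gene_b, population correlation); gene_a values are shared
    #: across pairs with a common first gene (the anchor)
    pairs: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("ADAM17", "APP", -0.742)]
    )
    n_ad: int = 201
    n_control: int = 83
    probes_per_gene: int = 2
    probe_noise_sd: float = 0.1
    mean: float = 8.0
    sd: float = 1.0
    call_rate: float = 1.0
    raw_scale: bool = True

    def __post_init__(self) -> None:
        for _, _, r in self.pairs:
            if not -1.0 < r < 1.0:
                raise ValueError("pair correlations must satisfy |r| < 1")


def make_expression(
    config: ExpressionSimConfig, seed: int
) -> tuple[ExpressionMatrix, dict[tuple[str, str], float]]:
    """Bivariate-normal latent gene values measured by noisy probes.

    Detection p-values are Uniform(0, 0.04) for called cells and
    Uniform(0.05, 1) for no-call cells, keeping the 0.05 threshold exact.
    """
    rng = stream_rng(seed, "expression")
    n = config.n_ad + config.n_control
    samples = [f"S{i:04d}" for i in range(n)]
    groups = pd.Series(
        [AD_GROUP] * config.n_ad + [CONTROL_GROUP] * config.n_control,
        index=samples,
    )

    anchors: dict[str, np.ndarray] = {}
    gene_values: dict[str, np.ndarray] = {}
    for gene_a, gene_b, r in config.pairs:
        if gene_a not in anchors:
            anchors[gene_a] = rng.normal(0.0, 1.0, n)
            gene_values[gene_a] = config.mean + config.sd * anchors[gene_a]
        za = anchors[gene_a]
        zb = r * za + np.sqrt(1.0 - r * r) * rng.normal(0.0, 1.0, n)
        gene_values[gene_b] = config.mean + config.sd * zb

    probe_rows = []
    probe_names = []
    probe_gene = {}
    for gene, values in gene_values.items():
        for k in range(config.probes_per_gene):
            name = f"ILMN_{gene}_{k}"
            probe_names.append(name)
            probe_gene[name] = gene
            probe_rows.append(values + rng.normal(0, config.probe_noise_sd, n))
    log2_values = pd.DataFrame(probe_rows, index=probe_names, columns=samples)

    called = rng.random(log2_values.shape) < config.call_rate
    detp = np.where(
        called,
        rng.uniform(0.0, 0.04, log2_values.shape),
        rng.uniform(0.05, 1.0, log2_values.shape),
    )
    detp = pd.DataFrame(detp, index=probe_names, columns=samples)

    if config.raw_scale:
        matrix = ExpressionMatrix(
            np.power(2.0, log2_values), detp, groups, pd.Series(probe_gene),
            log2_transformed=False,
        )
    else:
        matrix = ExpressionMatrix(
            log2_values, detp, groups, pd.Series(probe_gene), log2_transformed=True
        )
    return matrix, {(a, b): r for a, b, r in config.pairs}
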