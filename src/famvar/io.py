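"""Readers/writers for the pipeline's plain-text formats plus run orchestration.

Formats: 6-column PED, a small VCF 4.2 subset (GT plus a VQ quality flag),
annotation/marker/network/expression TSV tables and one-symbol-per-line gene
lists.  All writers use stable ordering and fixed float formatting so a run
is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .expression import ExpressionMatrix, call_rate_filter, fit_pair, gene_signal, pearson_screen
from .funnel import (
    CONS_SCORES,
    PATHO_PREDICTORS,
    AnnotationRecord,
    FunnelConfig,
    FunnelReport,
    VariantKey,
    VariantRecord,
    run_funnel,
)
from .linkage import DiseaseModel, MarkerLocus, max_lod_power
from .pedigree import (
    _AFF_CODES,
    _SEX_CODES,
    GenotypeCall,
    Individual,
    Pedigree,
)

logger = logging.getLogger(__name__)

_SEX_TO_CODE = {v: k for k, v in _SEX_CODES.items()}
_AFF_TO_CODE = {v: k for k, v in _AFF_CODES.items()}

FLOAT_FMT = "%.6g"
LOD_FMT = "%.5f"


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------


def read_ped(path: str | Path) -> dict[str, Pedigree]:
    """Whitespace-delimited 6-column PED; returns one Pedigree per family."""
    families: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            fam, iid, fa, mo, sex, aff = parts[:6]
            families.setdefault(fam, []).append(
                Individual(
                    id=iid,
                    father_id=None if fa == "0" else fa,
                    mother_id=None if mo == "0" else mo,
                    sex=_SEX_CODES.get(sex, "unknown"),
                    affection=_AFF_CODES.get(aff, "unknown"),
                )
            )
    return {fam: Pedigree(inds, name=fam) for fam, inds in families.items()}


def write_ped(path: str | Path, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                "\t".join(
                    [
                        ped.name,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        _AFF_TO_CODE[ind.affection],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

_QUAL_TO_VQ = {"VQHIGH": "VQHIGH", "low": "VQLOW", "nocall": "NOCALL"}
_VQ_TO_QUAL = {v: k for k, v in _QUAL_TO_VQ.items()}


def write_vcf(
    path: str | Path, variants: Sequence[VariantRecord], samples: Sequence[str]
) -> None:
    """Multi-sample uncompressed VCF with GT and the VQ quality flag."""
    chroms = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=VQ,Number=1,Type=String,Description="Call quality flag">\n'
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".", ".", "GT:VQ"]
            for s in samples:
                call = v.call(s)
                gt = "/".join("." if a is None else str(a) for a in call.alleles)
                fields.append(f"{gt}:{_QUAL_TO_VQ[call.quality]}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read the VCF subset back into VariantRecords (one ALT per record)."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: record at {rec.chrom}:{rec.pos} must have exactly one ALT"
                )
            calls: dict[str, GenotypeCall] = {}
            for s in samples:
                sample = rec.samples[s]
                gt = sample.get("GT", (None, None))
                vq = sample.get("VQ")
                quality = _VQ_TO_QUAL.get(vq, "nocall" if gt is None else "low")
                a1 = gt[0] if gt and len(gt) > 0 else None
                a2 = gt[1] if gt and len(gt) > 1 else None
                if a1 is None and a2 is None:
                    calls[s] = GenotypeCall(None, None, "nocall")
                else:
                    if quality == "nocall":
                        quality = "low"
                    calls[s] = GenotypeCall(a1, a2, quality)
            records.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0], calls)
            )
    return records, samples


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_ANN_FIXED = ["chrom", "pos", "ref", "alt", "gene", "func_class"]


def write_annotations(
    path: str | Path, annotations: Mapping[VariantKey, AnnotationRecord]
) -> None:
    freq_sources = sorted({s for a in annotations.values() for s in a.pop_freqs})
    patho = list(PATHO_PREDICTORS) + sorted(
        {p for a in annotations.values() for p in a.patho_calls}
        - set(PATHO_PREDICTORS)
    )
    cons = list(CONS_SCORES) + sorted(
        {c for a in annotations.values() for c in a.cons_calls} - set(CONS_SCORES)
    )
    cols = (
        _ANN_FIXED
        + [f"freq_{s}" for s in freq_sources]
        + [f"patho_{p}" for p in patho]
        + [f"cons_{c}" for c in cons]
    )
    rows = []
    for key in sorted(annotations):
        a = annotations[key]
        row = dict(zip(_ANN_FIXED, [*key[:2], key[2], key[3], a.gene or "", a.func_class]))
        for s in freq_sources:
            f = a.pop_freqs.get(s)
            row[f"freq_{s}"] = "" if f is None else FLOAT_FMT % f
        for p in patho:
            row[f"patho_{p}"] = a.patho_calls.get(p, "missing")
        for c in cons:
            row[f"cons_{c}"] = a.cons_calls.get(c, "missing")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Annotation TSV; unknown patho_/cons_ columns become opaque extra calls."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANN_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    out: dict[VariantKey, AnnotationRecord] = {}
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    patho_cols = [c for c in df.columns if c.startswith("patho_")]
    cons_cols = [c for c in df.columns if c.startswith("cons_")]
    for _, row in df.iterrows():
        key: VariantKey = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        pop_freqs = {
            c[len("freq_"):]: float(row[c]) for c in freq_cols if row[c] != ""
        }
        patho = {
            c[len("patho_"):]: row[c] for c in patho_cols if row[c] != ""
        }
        cons = {c[len("cons_"):]: row[c] for c in cons_cols if row[c] != ""}
        out[key] = AnnotationRecord(
            key=key,
            gene=row["gene"] or None,
            func_class=row["func_class"],
            pop_freqs=pop_freqs,
            patho_calls=patho,
            cons_calls=cons,
        )
    return out


def read_gene_list(path: str | Path) -> set[str]:
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    if not out:
        logger.warning("gene list %s is empty", path)
    return out


def write_gene_list(path: str | Path, genes: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_network(path: str | Path) -> list[tuple[str, str]]:
    """Two-column undirected edge list; duplicate edges are collapsed."""
    seen: set[frozenset[str]] = set()
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns")
            key = frozenset(parts[:2])
            if key not in seen:
                seen.add(key)
                edges.append((parts[0], parts[1]))
    return edges


def write_network(path: str | Path, edges: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_markers(path: str | Path) -> list[MarkerLocus]:
    """Marker TSV: id, alleles, freqs (comma-separated), then genotype columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "alleles", "freqs"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    ind_cols = [c for c in df.columns if c not in ("id", "alleles", "freqs")]
    markers = []
    for _, row in df.iterrows():
        alleles = tuple(row["alleles"].split(","))
        freqs = np.array([float(x) for x in row["freqs"].split(",")])
        genos: dict[str, Optional[tuple[int, int]]] = {}
        for c in ind_cols:
            g = row[c]
            if g in ("", "./.", "."):
                genos[c] = None
            else:
                a, b = g.split("/")
                genos[c] = (int(a), int(b))
        markers.append(
            MarkerLocus(alleles=alleles, freqs=freqs, genotypes=genos, name=row["id"])
        )
    return markers


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def write_expression(
    prefix: str | Path, matrix: ExpressionMatrix
) -> dict[str, Path]:
    prefix = Path(prefix)
    paths = {
        "matrix": prefix.with_suffix(".matrix.tsv"),
        "detp": prefix.with_suffix(".detp.tsv"),
        "samples": prefix.with_suffix(".samples.tsv"),
        "probemap": prefix.with_suffix(".probes.tsv"),
    }
    matrix.intensities.to_csv(paths["matrix"], sep="\t", float_format=FLOAT_FMT)
    matrix.detection_p.to_csv(paths["detp"], sep="\t", float_format=FLOAT_FMT)
    pd.DataFrame(
        {"sample": matrix.samples, "group": matrix.groups.values}
    ).to_csv(paths["samples"], sep="\t", index=False)
    matrix.probe_gene.rename_axis("probe").rename("gene").to_csv(
        paths["probemap"], sep="\t"
    )
    return paths


def read_expression(
    matrix_path: str | Path,
    detp_path: str | Path,
    samples_path: str | Path,
    probemap_path: str | Path,
    log2_transformed: bool = False,
) -> ExpressionMatrix:
    intensities = pd.read_csv(matrix_path, sep="\t", index_col=0)
    detp = pd.read_csv(detp_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise ValueError(f"{samples_path}: missing mandatory column {col!r}")
    groups = pd.Series(sheet["group"].values, index=sheet["sample"].values)
    pm = pd.read_csv(probemap_path, sep="\t", dtype=str)
    for col in ("probe", "gene"):
        if col not in pm.columns:
            raise ValueError(f"{probemap_path}: missing mandatory column {col!r}")
    probe_gene = pd.Series(pm["gene"].values, index=pm["probe"].values)
    return ExpressionMatrix(intensities, detp, groups, probe_gene, log2_transformed)


# ---------------------------------------------------------------------------
# Run configuration and orchestration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "pedigree",
    "family",
    "vcf",
    "annotations",
    "cmd_genes",
    "brain_genes",
    "nd_genes",
    "network",
    "funnel",
    "disease_model",
    "linkage",
    "expression",
}

_FUNNEL_KEYS = {
    "case_ids",
    "control_ids",
    "max_pop_freq",
    "min_deleterious",
    "min_conserved",
    "window_size",
    "max_mismatch_frac",
    "require_hom_ref_controls",
    "apply_shared_regions",
}


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    pedigree: Path
    family: Optional[str]
    vcf: Path
    annotations: Path
    cmd_genes: Path
    brain_genes: Path
    nd_genes: Path
    network: Path
    funnel: FunnelConfig
    disease_model: DiseaseModel
    typed_ids: list[str]
    n_markers: int
    expression: Optional[dict] = None


def load_run_config(path: str | Path) -> RunConfig:
    base = Path(path).parent
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def p(key: str) -> Path:
        val = raw.get(key)
        if val is None:
            raise ValueError(f"config is missing required path {key!r}")
        out = (base / val).resolve() if not os.path.isabs(val) else Path(val)
        if not out.exists():
            raise FileNotFoundError(f"config path {key}={out} does not exist")
        return out

    fun_raw = dict(raw.get("funnel", {}))
    unknown = set(fun_raw) - _FUNNEL_KEYS
    if unknown:
        raise ValueError(f"unknown funnel config keys: {sorted(unknown)}")
    fun_raw["case_ids"] = frozenset(map(str, fun_raw.get("case_ids", [])))
    fun_raw["control_ids"] = frozenset(map(str, fun_raw.get("control_ids", [])))
    funnel_cfg = FunnelConfig(**fun_raw)

    dm = raw.get("disease_model", {})
    model = DiseaseModel(
        float(dm.get("freq", 0.0001)),
        tuple(float(x) for x in dm.get("penetrances", (0.0001, 1.0, 1.0))),
    )
    linkage = raw.get("linkage", {})

    expr = raw.get("expression")
    if expr is not None:
        for k in ("matrix", "detp", "samples", "probemap"):
            rel = expr[k]
            full = (base / rel).resolve() if not os.path.isabs(rel) else Path(rel)
            if not full.exists():
                raise FileNotFoundError(f"expression path {k}={full} does not exist")
            expr[k] = full

    return RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=(base / raw.get("out_dir", "results")).resolve(),
        pedigree=p("pedigree"),
        family=raw.get("family"),
        vcf=p("vcf"),
        annotations=p("annotations"),
        cmd_genes=p("cmd_genes"),
        brain_genes=p("brain_genes"),
        nd_genes=p("nd_genes"),
        network=p("network"),
        funnel=funnel_cfg,
        disease_model=model,
        typed_ids=[str(x) for x in linkage.get("typed", [])],
        n_markers=int(linkage.get("n_markers", 1000)),
        expression=expr,
    )


def write_funnel_report(path: str | Path, report: FunnelReport) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tn_survivors\tn_removed\n")
        for s in report.stages:
            fh.write(f"{s.name}\t{s.n}\t{s.n_removed}\n")


def write_candidates(path: str | Path, report: FunnelReport) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tflag\n")
        for key in report.final:
            flag = report.candidate_flags.get(key, "neither")
            fh.write(f"{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t{flag}\n")


def run_all(config: RunConfig) -> dict:
    """Funnel + linkage power + optional expression analysis; writes a bundle."""
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    peds = read_ped(config.pedigree)
    fam = config.family or sorted(peds)[0]
    ped = peds[fam]

    records, _samples = read_vcf(config.vcf)
    annotations = read_annotations(config.annotations)
    cmd = read_gene_list(config.cmd_genes)
    brain = read_gene_list(config.brain_genes)
    nd = read_gene_list(config.nd_genes)
    edges = read_network(config.network)

    report = run_funnel(
        {"calls": records}, annotations, cmd, brain, nd, edges, config.funnel
    )
    write_funnel_report(out_dir / "funnel_report.tsv", report)
    write_candidates(out_dir / "candidates.tsv", report)

    results: dict = {"funnel": report.counts()}

    if config.typed_ids:
        lod = max_lod_power(
            ped,
            config.disease_model,
            config.typed_ids,
            n_markers=config.n_markers,
            seed=config.seed,
        )
        results["max_lod"] = float(LOD_FMT % lod)
        with open(out_dir / "linkage.json", "w") as fh:
            json.dump(
                {
                    "max_lod": LOD_FMT % lod,
                    "n_markers": config.n_markers,
                    "typed": sorted(config.typed_ids),
                    "seed": config.seed,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    if config.expression is not None:
        expr = config.expression
        matrix = read_expression(
            expr["matrix"], expr["detp"], expr["samples"], expr["probemap"]
        )
        retained = call_rate_filter(matrix)
        anchor = expr.get("anchor", "ADAM17")
        targets = sorted(set(matrix.probe_gene.values) - {anchor})
        screen = pearson_screen(matrix, anchor, targets, retained_probes=retained)
        screen.to_csv(
            out_dir / "expression_screen.tsv",
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
        pair_rows = []
        for target in targets:
            probes = [p for p in matrix.probes_for(target) if p in set(retained)]
            if not probes:
                continue
            x = gene_signal(matrix, anchor)
            y = gene_signal(matrix, target, probes)
            fit = fit_pair(x.to_numpy(), y.to_numpy())
            pair_rows.append({"target": target, **asdict(fit)})
        pd.DataFrame(pair_rows).to_csv(
            out_dir / "expression_fits.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
        results["expression_targets"] = len(pair_rows)

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)
    return results
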