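"""Readers and writers for the pipeline's file formats.

Delimited files are headered, comma-separated UTF-8; floats are serialised
with 12 significant digits so regression tests are byte-stable.  Genotypes
travel either as wide count tables (rows = individuals, columns = markers,
empty cell = missing) or as a minimal biallelic VCF (GT-only), parsed with
cyvcf2.  Counts follow the minor-allele convention: after computing allele
frequencies, the counted allele is the rarer one.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ablup import EvaluationResult
from .gs_models import GenotypeMatrix, MarkerEffectModel, preprocess_genotypes
from .pedigree import Pedigree
from .synthetic_data import SimulationConfig, StudyBundle

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_phenotypes", "write_phenotypes",
    "read_genotypes", "write_genotypes", "write_vcf",
    "read_evaluation", "write_evaluation",
    "write_marker_model", "read_marker_model",
    "write_report", "write_bundle", "read_bundle",
]

FLOAT_FMT = "%.12g"
UNKNOWN_SENTINEL = "0"


def write_pedigree(ped: Pedigree, path, sentinel: str = UNKNOWN_SENTINEL) -> None:
    df = ped.records.copy()
    for col in ("sire", "dam"):
        df[col] = [sentinel if v is None else v for v in df[col]]
    df.to_csv(path, index=False)


def read_pedigree(path, sentinel: str = UNKNOWN_SENTINEL) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    for col in ("sire", "dam"):
        df[col] = df[col].where(df[col] != sentinel, None)
    return Pedigree(
        df.assign(
            sire=[None if pd.isna(v) else v for v in df["sire"]],
            dam=[None if pd.isna(v) else v for v in df["dam"]],
        )
    )


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["id"] = df["id"].astype(str)
    for col in ("age", "trait"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df


# ------------------------------------------------------------------ genotypes

def write_genotypes(df: pd.DataFrame, path) -> None:
    """Wide count table; NaN written as empty cell."""
    out = df.copy()
    out.index.name = "id"
    out.to_csv(path, float_format="%g")


def read_genotypes(path, format: str = "counts", preprocess: bool = False,
                   **preprocess_kwargs):
    """Read a genotype matrix from a counts table or minimal VCF.

    Returns the raw parsed DataFrame (lossless round trip) unless
    ``preprocess=True``, in which case a filtered/imputed
    :class:`GenotypeMatrix` is returned.
    """
    if format == "counts":
        df = pd.read_csv(path, index_col="id")
        df.index = df.index.astype(str)
        df = df.astype(float)
    elif format == "vcf":
        df = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if preprocess:
        return preprocess_genotypes(df, **preprocess_kwargs)
    return df


def _read_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, columns = [], []
    n_multi = 0
    for k, v in enumerate(vcf):
        try:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = v.gt_types
            counts = np.select(
                [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
            )
            called = counts[np.isfinite(counts)]
            if called.size and called.mean() / 2.0 > 0.5:
                counts = 2.0 - counts  # flip so the minor allele is counted
            markers.append(v.ID or f"{v.CHROM}:{v.POS}")
            columns.append(counts)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record #{k + 1} in {path}: {exc}") from exc
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic VCF records")
    return pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="id"), columns=markers,
    )


def write_vcf(df: pd.DataFrame, path) -> None:
    """Minimal biallelic VCF v4.2 with GT-only genotype fields.

    Counts are interpreted as dosage of the ALT allele; missing becomes ./..
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(df.index.astype(str)) + "\n")
        for pos, marker in enumerate(df.columns, start=1):
            col = df[marker]
            gts = "\t".join(
                "./." if pd.isna(v) else gt_map[int(v)] for v in col
            )
            fh.write(f"1\t{pos}\t{marker}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


# ------------------------------------------------------------------ results

def write_evaluation(result: EvaluationResult, path) -> None:
    """EBV table as TSV plus a JSON sidecar with variance components."""
    path = Path(path)
    result.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {
        "varcomps": result.varcomps,
        "h2": result.h2,
        "loglik": None if not np.isfinite(result.loglik) else result.loglik,
        "converged": bool(result.converged),
        "dropped_terms": list(result.dropped_terms),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_evaluation(path) -> EvaluationResult:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"id": str})
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EvaluationResult(
        table=table, varcomps=meta["varcomps"], h2=meta["h2"],
        loglik=meta["loglik"] if meta["loglik"] is not None else np.nan,
        loglik_trace=[], converged=meta["converged"],
        dropped_terms=meta["dropped_terms"],
    )


def write_marker_model(model: MarkerEffectModel, prefix) -> None:
    prefix = Path(prefix)
    df = model.to_frame()
    df["col_mean"] = model.col_means
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {
        "method": model.method,
        "mu": model.mu,
        "pi": model.pi,
        "lambda": None if np.ndim(model.lambda_) else _opt(model.lambda_),
        "sigma_g2": _opt(model.sigma_g2),
        "sigma_e2": _opt(model.sigma_e2),
        "metadata": {k: v for k, v in model.metadata.items()
                     if not isinstance(v, np.ndarray)},
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _opt(v):
    return None if v is None else float(v)


def read_marker_model(prefix) -> MarkerEffectModel:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    lam = df["lambda_k"].to_numpy() if "lambda_k" in df else meta["lambda"]
    return MarkerEffectModel(
        method=meta["method"], mu=meta["mu"],
        effects=df["effect"].to_numpy(), markers=list(df["marker"].astype(str)),
        col_means=df["col_mean"].to_numpy(), lambda_=lam, pi=meta["pi"],
        inclusion_prob=df["inclusion_prob"].to_numpy() if "inclusion_prob" in df else None,
        sigma_g2=meta["sigma_g2"], sigma_e2=meta["sigma_e2"],
        metadata=meta["metadata"],
    )


def write_report(report, prefix) -> None:
    """Validation report as TSV (summary) + JSON (rep-level detail)."""
    prefix = Path(prefix)
    report.to_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False,
                             float_format=FLOAT_FMT)
    payload = {
        "scenario": report.scenario,
        "methods": list(report.methods),
        "accuracy": {m: list(map(_opt, v)) for m, v in report.accuracy.items()},
        "predictive_ability": {m: list(map(_opt, v))
                               for m, v in report.predictive_ability.items()},
        "n_validation": report.n_validation,
        "rep_correlations": report.rep_correlations.to_dict(orient="list"),
    }
    if report.clusters is not None:
        payload["clusters"] = report.clusters.to_dict(orient="records")
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))


# ------------------------------------------------------------------ bundles

def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Write a simulated study to a directory of delimited files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(bundle.pedigree, outdir / "pedigree.csv")
    write_phenotypes(bundle.phenotypes_htj, outdir / "phenotypes.csv")
    write_phenotypes(bundle.phenotypes_ht35, outdir / "phenotypes_ht35.csv")
    write_genotypes(bundle.genotypes_f1, outdir / "genotypes_f1.csv")
    write_genotypes(bundle.genotypes_f2, outdir / "genotypes_f2.csv")
    bundle.truth.to_csv(outdir / "truth.csv", index=False, float_format=FLOAT_FMT)
    bundle.qtl.to_csv(outdir / "qtl.csv", index=False, float_format=FLOAT_FMT)
    cfg = dataclasses.asdict(bundle.config)
    cfg["f1_ids"] = bundle.f1_ids
    cfg["f2_ids"] = bundle.f2_ids
    cfg["f2_parents"] = bundle.f2_parents
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg))


def read_bundle(outdir) -> StudyBundle:
    outdir = Path(outdir)
    cfg = yaml.safe_load((outdir / "config.yaml").read_text())
    f1_ids = [str(i) for i in cfg.pop("f1_ids")]
    f2_ids = [str(i) for i in cfg.pop("f2_ids")]
    f2_parents = [str(i) for i in cfg.pop("f2_parents")]
    for key in ("f1_site_sizes", "maf_range", "h2_f1_sites", "site_means_htj"):
        cfg[key] = tuple(cfg[key])
    config = SimulationConfig(**cfg)
    return StudyBundle(
        config=config,
        pedigree=read_pedigree(outdir / "pedigree.csv"),
        phenotypes_htj=read_phenotypes(outdir / "phenotypes.csv"),
        phenotypes_ht35=read_phenotypes(outdir / "phenotypes_ht35.csv"),
        genotypes_f1=read_genotypes(outdir / "genotypes_f1.csv"),
        genotypes_f2=read_genotypes(outdir / "genotypes_f2.csv"),
        truth=pd.read_csv(outdir / "truth.csv", dtype={"id": str}),
        qtl=pd.read_csv(outdir / "qtl.csv"),
        f1_ids=f1_ids, f2_ids=f2_ids, f2_parents=f2_parents,
    )
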