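"""Cross-generational validation experiments.

This module is the experimental harness around the marker models: four
training/validation scenarios (juvenile or mature height, EBVs or
deregressed EBVs), tenfold cross-validation repeated ten times with the F2
validation set fixed, cluster sub-analyses with three training-set
compositions, and the marker-density experiment.

Metrics follow the breeding literature: *accuracy* is the Pearson
correlation between the validation individuals' (D)EBVs from the full-data
evaluation and their genomic predictions; *predictive ability* correlates
predictions with raw phenotypes.  Both are computed on the full validation
set once per repetition (fold predictions averaged), and summarised as mean
+/- SE over repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ablup import EvaluationResult, ModelSpec, fit_ablup
from .deregression import deregress_population
from .gs_models import (
    GenotypeMatrix,
    RidgeLambdaError,
    fit_bayesb,
    fit_grr,
    fit_rrblup,
    predict,
    preprocess_genotypes,
    _reml_marker_variances,
)
from .pedigree import RelationshipMatrix, build_A
from .synthetic_data import StudyBundle

__all__ = [
    "ScenarioSpec",
    "ValidationReport",
    "StudyData",
    "make_folds",
    "accuracy_metrics",
    "prepare_study",
    "run_scenario",
    "cluster_subanalysis",
    "marker_density_experiment",
]

logger = logging.getLogger(__name__)

GS_METHODS = ("RR-BLUP", "GRR", "Bayes-B")


@dataclass
class ScenarioSpec:
    """One of the four cross-generational analyses.

    1: juvenile EBVs -> juvenile genomic EBVs; 2: juvenile DEBVs -> juvenile
    genomic DEBVs; 3: mature EBVs -> juvenile genomic EBVs; 4: mature DEBVs
    -> juvenile genomic DEBVs.  Deregressed training responses are always
    validated against deregressed values.
    """

    scenario: int = 1
    methods: tuple = ("RR-BLUP", "GRR", "Bayes-B", "ABLUP")
    folds: int = 10
    reps: int = 10
    seed: int = 0
    lambda_policy: str = "once"      # "once" | "per-fold"
    mcmc_iters: int = 3000
    mcmc_burn_in: int = 1000
    mcmc_thin: int = 5

    def __post_init__(self):
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1, 2, 3 or 4")
        bad = [m for m in self.methods if m not in GS_METHODS + ("ABLUP",)]
        if bad:
            raise ValueError(f"unknown methods: {bad}")


@dataclass
class ValidationReport:
    """Per-method accuracies and predictive abilities with rep-level SEs."""

    scenario: object
    methods: list
    accuracy: dict                   # method -> (mean, se)
    predictive_ability: dict
    rep_correlations: pd.DataFrame
    folds: pd.DataFrame
    clusters: pd.DataFrame | None = None
    n_validation: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.methods:
            acc = self.accuracy.get(m, (np.nan, np.nan))
            pa = self.predictive_ability.get(m, (np.nan, np.nan))
            rows.append({
                "scenario": self.scenario, "method": m,
                "accuracy": acc[0], "accuracy_se": acc[1],
                "predictive_ability": pa[0], "predictive_ability_se": pa[1],
            })
        return pd.DataFrame(rows)


# ------------------------------------------------------------------ folds

def make_folds(ids, k: int, reps: int, seed: int) -> pd.DataFrame:
    """Random near-equal partitions: ``reps`` independent k-fold splits.

    The remainder is spread one individual per fold.  Deterministic given
    ``seed``; returns a table with columns rep, fold, id.
    """
    ids = [str(i) for i in ids]
    if k <= 1:
        raise ValueError("need at least two folds")
    if len(ids) < k:
        raise ValueError("fewer individuals than folds")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        perm = rng.permutation(len(ids))
        sizes = np.full(k, len(ids) // k)
        sizes[: len(ids) % k] += 1
        stop = np.cumsum(sizes)
        start = np.concatenate([[0], stop[:-1]])
        for fold, (a, b) in enumerate(zip(start, stop)):
            for j in perm[a:b]:
                rows.append((rep, fold, ids[j]))
    return pd.DataFrame(rows, columns=["rep", "fold", "id"])


def pearson(x, y) -> float:
    """Pearson correlation; NaN (flagged undefined) when a vector is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pearson: zero variance; correlation undefined")
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def accuracy_metrics(x, y) -> tuple[float, float]:
    """Correlation between two measurement sets with a rep-level SE.

    ``x``/``y`` may be 1-D (single measurement: SE is NaN) or 2-D with one
    row per repetition, in which case the per-rep correlations are averaged
    and ``SE = sd / sqrt(reps)``.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    rs = [pearson(a, b) for a, b in zip(x, y)]
    return summarise_rep_correlations(rs)


def summarise_rep_correlations(rs) -> tuple[float, float]:
    rs = np.asarray([r for r in rs], float)
    if len(rs) == 0:
        return (np.nan, np.nan)
    if len(rs) == 1:
        return (float(rs[0]), np.nan)
    return (float(np.nanmean(rs)), float(np.nanstd(rs, ddof=1) / np.sqrt(len(rs))))


# ------------------------------------------------------------------ study data

@dataclass
class StudyData:
    """Evaluated study: relationship matrix, full-data fits, deregressed
    values and the processed genotype matrix shared by all scenarios."""

    bundle: StudyBundle
    relmat: RelationshipMatrix
    eval_htj: EvaluationResult
    eval_ht35: EvaluationResult | None
    debv_htj: pd.DataFrame
    debv_ht35: pd.DataFrame | None
    genotypes: GenotypeMatrix
    f1_ids: list
    f2_ids: list

    def training_response(self, scenario: int) -> pd.Series:
        src = {
            1: ("ebv", self.eval_htj, None),
            2: ("debv", None, self.debv_htj),
            3: ("ebv", self.eval_ht35, None),
            4: ("debv", None, self.debv_ht35),
        }[scenario]
        return _response_series(src, self.f1_ids)

    def validation_response(self, scenario: int) -> pd.Series:
        src = {
            1: ("ebv", self.eval_htj, None),
            2: ("debv", None, self.debv_htj),
            3: ("ebv", self.eval_htj, None),
            4: ("debv", None, self.debv_htj),
        }[scenario]
        return _response_series(src, self.f2_ids)

    def validation_phenotype(self) -> pd.Series:
        ph = self.bundle.phenotypes_htj.set_index("id")["trait"]
        return ph.reindex(self.f2_ids)


def _response_series(src, ids) -> pd.Series:
    kind, evaluation, debv = src
    if kind == "ebv":
        if evaluation is None:
            raise ValueError("evaluation result unavailable for this scenario")
        s = evaluation.table.set_index("id")["ebv"]
    else:
        if debv is None:
            raise ValueError("deregressed values unavailable for this scenario")
        s = debv.set_index("id")["debv"]
    out = s.reindex(ids)
    return out.dropna()


def prepare_study(
    bundle: StudyBundle,
    model_spec: ModelSpec | None = None,
    include_ht35: bool = True,
) -> StudyData:
    """Run the full-data evaluations and deregression for a bundle.

    The juvenile-height fit uses phenotypes from both generations (the
    validation individuals' "original" EBVs come from this fit); the mature-
    height fit uses the F1 generation only.
    """
    model_spec = model_spec or ModelSpec()
    relmat = build_A(bundle.pedigree)
    eval_htj = fit_ablup(bundle.phenotypes_htj, relmat, model_spec,
                         on_nonconvergence="warn")
    genotyped = bundle.f1_ids + bundle.f2_ids
    debv_htj = deregress_population(eval_htj, bundle.pedigree, ids=genotyped)
    eval_ht35 = None
    debv_ht35 = None
    if include_ht35 and len(bundle.phenotypes_ht35):
        eval_ht35 = fit_ablup(bundle.phenotypes_ht35, relmat, model_spec,
                              on_nonconvergence="warn")
        debv_ht35 = deregress_population(eval_ht35, bundle.pedigree,
                                         ids=bundle.f1_ids)
    raw = pd.concat([bundle.genotypes_f1, bundle.genotypes_f2])
    genotypes = preprocess_genotypes(raw)
    f1 = [i for i in bundle.f1_ids if i in set(genotypes.ids)]
    f2 = [i for i in bundle.f2_ids if i in set(genotypes.ids)]
    return StudyData(
        bundle=bundle, relmat=relmat, eval_htj=eval_htj, eval_ht35=eval_ht35,
        debv_htj=debv_htj, debv_ht35=debv_ht35, genotypes=genotypes,
        f1_ids=f1, f2_ids=f2,
    )


# ------------------------------------------------------------------ scenarios

def _fit_gs(method, y, Z, spec, lam=None, sigma_e2=None, fold_seed=0):
    if method == "RR-BLUP":
        return fit_rrblup(y, Z, lam=lam)
    if method == "GRR":
        return fit_grr(y, Z, lam_init=lam, sigma_e2=sigma_e2)
    if method == "Bayes-B":
        return fit_bayesb(
            y, Z, iters=spec.mcmc_iters, burn_in=spec.mcmc_burn_in,
            thin=spec.mcmc_thin, seed=fold_seed,
        )
    raise ValueError(f"unknown GS method {method!r}")


def _gs_cross_validation(
    spec: ScenarioSpec,
    train_response: pd.Series,
    Z_train_pool: GenotypeMatrix,
    Z_valid: GenotypeMatrix,
    valid_acc_target: np.ndarray,
    valid_pheno: np.ndarray | None,
    methods,
    fold_table: pd.DataFrame | None = None,
):
    """Shared rep x fold engine: train on ~90% of the pool, always predict
    the full validation set; correlate per repetition."""
    train_ids = list(train_response.index)
    fold_table = fold_table if fold_table is not None else make_folds(
        train_ids, spec.folds, spec.reps, spec.seed
    )
    lam = sigma_e2 = None
    if spec.lambda_policy == "once" and any(m in ("RR-BLUP", "GRR") for m in methods):
        Zp = Z_train_pool.subset_individuals(train_ids)
        y = train_response.to_numpy()
        try:
            lam, _, sigma_e2 = _reml_marker_variances(
                y - y.mean(), Zp.Z - Zp.Z.mean(axis=0)
            )
        except RidgeLambdaError:
            # no detectable genomic variance (e.g. deregressed mature-height
            # responses): shrink everything hard instead of failing
            lam, sigma_e2 = 1e6, float(np.var(y))
            logger.warning(
                "ridge lambda at the zero-variance boundary; using lambda=1e6"
            )
    acc_rows, pa_rows = {m: [] for m in methods}, {m: [] for m in methods}
    for rep, grp in fold_table.groupby("rep"):
        preds = {m: [] for m in methods}
        for fold, fgrp in grp.groupby("fold"):
            holdout = set(fgrp["id"])
            ids_in = [i for i in train_ids if i not in holdout]
            Zt = Z_train_pool.subset_individuals(ids_in)
            yt = train_response.loc[ids_in].to_numpy()
            for m in methods:
                model = _fit_gs(m, yt, Zt, spec, lam=lam, sigma_e2=sigma_e2,
                                fold_seed=spec.seed * 1000 + rep * 17 + fold)
                preds[m].append(predict(model, Z_valid))
        for m in methods:
            pm = np.mean(preds[m], axis=0)
            acc_rows[m].append(pearson(pm, valid_acc_target))
            if valid_pheno is not None:
                pa_rows[m].append(pearson(pm, valid_pheno))
    return acc_rows, pa_rows, fold_table


def run_scenario(spec: ScenarioSpec, data: StudyData) -> ValidationReport:
    """Run one cross-generational scenario over all requested methods.

    GS methods are trained per rep x fold on ~90% of the genotyped F1
    responses and always predict the full (genotyped, deregressable) F2
    validation set; the ABLUP baseline re-solves the pedigree model on the
    same folds' phenotypes.
    """
    train = data.training_response(spec.scenario)
    valid = data.validation_response(spec.scenario)
    if len(valid) < 3:
        raise ValueError("validation set too small after dropping undefined responses")
    dropped = len(data.f2_ids) - len(valid)
    if dropped:
        logger.info("run_scenario: %d validation ids lack responses", dropped)
    Z_valid = data.genotypes.subset_individuals(list(valid.index))
    pheno = data.validation_phenotype().reindex(valid.index).to_numpy()

    gs_methods = [m for m in spec.methods if m != "ABLUP"]
    acc_rows, pa_rows, fold_table = _gs_cross_validation(
        spec, train, data.genotypes, Z_valid, valid.to_numpy(), pheno, gs_methods,
    )
    accuracy = {m: summarise_rep_correlations(acc_rows[m]) for m in gs_methods}
    pa = {m: summarise_rep_correlations(pa_rows[m]) for m in gs_methods}
    reps_frame = pd.DataFrame(
        {f"{m}_accuracy": acc_rows[m] for m in gs_methods}
        | {f"{m}_predictive_ability": pa_rows[m] for m in gs_methods}
    )

    methods = list(spec.methods)
    if "ABLUP" in spec.methods:
        if spec.scenario in (1, 3):
            from .ablup import ablup_cross_generation

            phen = (data.bundle.phenotypes_htj if spec.scenario == 1
                    else data.bundle.phenotypes_ht35)
            phen_f1 = phen[phen["id"].isin(set(data.f1_ids))]
            base = ablup_cross_generation(
                data.relmat, phen_f1, list(valid.index), valid.to_numpy(),
                validation_phenotype=pheno, folds=spec.folds, reps=spec.reps,
                seed=spec.seed,
                varcomps=(data.eval_htj if spec.scenario == 1
                          else data.eval_ht35).varcomps,
            )
            accuracy["ABLUP"] = base.accuracy["ABLUP"]
            pa["ABLUP"] = base.predictive_ability["ABLUP"]
        else:
            logger.warning("ABLUP baseline undefined for deregressed scenarios; skipped")
            methods = [m for m in methods if m != "ABLUP"]

    return ValidationReport(
        scenario=spec.scenario, methods=methods, accuracy=accuracy,
        predictive_ability=pa, rep_correlations=reps_frame, folds=fold_table,
        n_validation=len(valid),
    )


# ------------------------------------------------------------------ clusters

def cluster_subanalysis(
    data: StudyData,
    spec: ScenarioSpec,
    threshold: float | None = None,
    methods=("RR-BLUP",),
) -> pd.DataFrame:
    """Within-cluster accuracies under three training-set compositions.

    Validation individuals are split at ``threshold`` on their full-data
    EBVs (default: the sample median, since any fixed split value is a
    dataset-specific choice).  Training variants: (1) the full genotyped F1
    set; (2) the F1 set minus the parents of the opposing cluster; (3) only
    the F1 parents of the cluster in question.  High overall accuracy paired
    with near-zero within-cluster accuracy is the signature of correlations
    driven by family means.
    """
    train = data.training_response(spec.scenario)
    valid = data.validation_response(spec.scenario)
    ebv_valid = data.eval_htj.table.set_index("id")["ebv"].reindex(valid.index)
    if threshold is None:
        threshold = float(ebv_valid.median())
    pm = data.bundle.pedigree.parent_map()
    clusters = {
        "low": list(ebv_valid.index[ebv_valid < threshold]),
        "high": list(ebv_valid.index[ebv_valid >= threshold]),
    }
    parents_of = {
        name: {p for i in ids for p in pm.get(i, (None, None)) if p is not None}
        for name, ids in clusters.items()
    }
    pheno_all = data.validation_phenotype()
    rows = []
    for name, members in clusters.items():
        if len(members) < 3:
            logger.warning("cluster %s has <3 members; skipped", name)
            continue
        other = "high" if name == "low" else "low"
        train_sets = {
            1: list(train.index),
            2: [i for i in train.index if i not in parents_of[other]],
            3: [i for i in train.index if i in parents_of[name]],
        }
        vresp = valid.loc[members].to_numpy()
        Zv = data.genotypes.subset_individuals(members)
        vph = pheno_all.reindex(members).to_numpy()
        for variant, ids_in in train_sets.items():
            if len(ids_in) < spec.folds:
                logger.warning("cluster %s variant %d: training set too small; skipped",
                               name, variant)
                continue
            sub = train.loc[[i for i in ids_in if i in train.index]]
            acc_rows, pa_rows, _ = _gs_cross_validation(
                spec, sub, data.genotypes, Zv, vresp, vph, list(methods),
            )
            for m in methods:
                a = summarise_rep_correlations(acc_rows[m])
                p = summarise_rep_correlations(pa_rows[m])
                rows.append({
                    "cluster": name, "variant": variant, "method": m,
                    "n_validation": len(members), "n_training": len(sub),
                    "accuracy": a[0], "accuracy_se": a[1],
                    "predictive_ability": p[0], "predictive_ability_se": p[1],
                })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ density

def marker_density_experiment(
    y,
    Z: GenotypeMatrix,
    sizes,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    lam: float | None = None,
) -> pd.DataFrame:
    """RR-BLUP cross-validation accuracy as a function of marker count.

    For each requested marker-set size, ``reps`` random draws are made; each
    draw is scored by tenfold cross-validation (correlation between held-out
    responses and their predictions, pooled over folds).  Returns a table
    with mean and sd per size.
    """
    if isinstance(Z, GenotypeMatrix):
        ids = Z.ids
    else:
        Z = preprocess_genotypes(np.asarray(Z, float))
        ids = Z.ids
    p = Z.shape[1]
    y = pd.Series(np.asarray(y, float), index=[str(i) for i in ids])
    rng = np.random.default_rng(seed)
    # one fold partition shared by every size and draw: only the marker
    # sampling is replicated, so size = p reproduces the full-panel CV exactly
    ft = make_folds(ids, folds, 1, seed)
    rows = []
    for size in sizes:
        if size > p:
            raise ValueError(f"marker-set size {size} exceeds panel size {p}")
        accs = []
        for rep in range(reps):
            draw = np.sort(rng.choice(p, size=size, replace=False))
            Zs = Z.subset_markers(draw)
            pred = pd.Series(np.nan, index=y.index)
            lam_draw = lam
            if lam_draw is None:
                yc = y.to_numpy() - y.mean()
                try:
                    lam_draw, _, _ = _reml_marker_variances(
                        yc, Zs.Z - Zs.Z.mean(axis=0)
                    )
                except RidgeLambdaError:
                    lam_draw = 1e6
            for fold, fgrp in ft.groupby("fold"):
                test_ids = list(fgrp["id"])
                tr_ids = [i for i in y.index if i not in set(test_ids)]
                model = fit_rrblup(y.loc[tr_ids].to_numpy(),
                                   Zs.subset_individuals(tr_ids), lam=lam_draw)
                pred.loc[test_ids] = predict(model, Zs.subset_individuals(test_ids))
            accs.append(pearson(y.to_numpy(), pred.to_numpy()))
        rows.append({"size": int(size), "accuracy_mean": float(np.mean(accs)),
                     "accuracy_sd": float(np.std(accs, ddof=1)) if reps > 1 else np.nan,
                     "reps": reps})
    return pd.DataFrame(rows)
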