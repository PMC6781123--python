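"""Pedigree BLUP (ABLUP) evaluation of a multi-environment progeny trial.

The evaluation model is the individual-tree ("animal") mixed model

    y = X b + Z1 a + Z2 sa + Z3 s(rep) + Z4 sf + Z5 f + e

with fixed mean, site and age effects; a random additive effect
``a ~ N(0, A s2_a)`` structured by the numerator relationship matrix; and
identity-covariance random terms for site x additive interaction ``sa``,
block-within-site ``s(rep)``, site x family interaction ``sf`` and family
``f``; the residual variance is common to all sites.  Variance components
are estimated by REML (:mod:`treegs.reml`).

Narrow-sense heritability uses the ratio

    h2 = s2_a / (s2_a + s2_sa + s2_sf + s2_f + s2_e)

note the block-within-site component is deliberately excluded from the
denominator; see docs/methods.md for discussion of this convention.

Theoretical accuracy of an EBV is ``r = sqrt(1 - SE_i^2 / ((1 + f_i) s2_a))``
with ``SE_i`` the prediction-error standard error and ``f_i`` the inbreeding
coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import RelationshipMatrix
from .reml import MixedModel, RandomTerm, REMLResult

__all__ = [
    "ModelSpec",
    "EvaluationResult",
    "fit_ablup",
    "heritability",
    "theoretical_accuracy",
    "ablup_cross_generation",
]

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["id", "site", "block", "family", "age", "trait"]


@dataclass
class ModelSpec:
    """Which effects enter the evaluation model.

    Terms whose design has fewer than two levels (e.g. site terms in a
    single-site analysis) are dropped automatically at fit time.
    """

    age_as_factor: bool = False
    site_additive: bool = True
    block: bool = True
    site_family: bool = True
    family: bool = True
    reml_method: str = "ai"
    max_iter: int = 200
    tol_loglik: float = 1e-6
    tol_var: float = 1e-5


@dataclass
class EvaluationResult:
    """Per-individual EBVs with uncertainty, plus model-level summaries."""

    table: pd.DataFrame          # id, ebv, se, reliability, accuracy
    varcomps: dict
    h2: float
    loglik: float
    loglik_trace: list = field(repr=False)
    converged: bool = True
    dropped_terms: list = field(default_factory=list)
    fixed_effects: np.ndarray | None = None

    @property
    def sigma_a2(self) -> float:
        return self.varcomps.get("additive", 0.0)

    def ebv_of(self, ids) -> np.ndarray:
        return self.table.set_index("id").loc[[str(i) for i in ids], "ebv"].to_numpy()

    def reliability_of(self, ids) -> np.ndarray:
        return self.table.set_index("id").loc[[str(i) for i in ids], "reliability"].to_numpy()


def heritability(varcomps: dict) -> float:
    """Narrow-sense h2 with the block-within-site term excluded."""
    num = varcomps.get("additive", 0.0)
    denom = num + sum(
        varcomps.get(k, 0.0) for k in ("site_additive", "site_family", "family", "residual")
    )
    if any(varcomps.get(k, 0.0) < 0 for k in varcomps):
        raise ValueError("negative variance component")
    if denom == 0:
        raise ValueError("heritability undefined: all variance components zero")
    return num / denom


def theoretical_accuracy(se: np.ndarray, f: np.ndarray, sigma_a2: float) -> np.ndarray:
    """Accuracy r of EBVs from their prediction-error SEs.

    Radicands that fall below zero (numerical noise around a PEV equal to the
    full additive variance) are clamped to zero.
    """
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    rad = 1.0 - np.asarray(se, float) ** 2 / ((1.0 + np.asarray(f, float)) * sigma_a2)
    clamped = rad < 0
    if np.any(clamped):
        logger.info("theoretical_accuracy: clamped %d negative radicands", clamped.sum())
    return np.sqrt(np.clip(rad, 0.0, None))


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def _dummy(codes: pd.Series) -> tuple[sp.csr_matrix, list]:
    levels, inv = np.unique(codes.to_numpy(), return_inverse=True)
    n = len(codes)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), inv)), shape=(n, len(levels))
    )
    return Z, list(levels)


def build_design(
    phenotypes: pd.DataFrame,
    relmat: RelationshipMatrix,
    spec: ModelSpec,
):
    """Construct y, X and the random-term design matrices.

    The additive term spans *all* pedigree members so EBVs (and PEVs) are
    produced for unphenotyped individuals too.  Returns the MixedModel inputs
    plus bookkeeping needed to interpret the solution.
    """
    df = phenotypes.copy()
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    df["id"] = df["id"].astype(str)
    unknown = set(df["id"]) - set(relmat.ids)
    if unknown:
        raise ValueError(f"phenotyped ids absent from pedigree: {sorted(unknown)[:5]}")

    y = df["trait"].to_numpy(dtype=float)
    n = len(df)
    sites = df["site"].astype(str)
    n_sites = sites.nunique()

    X_parts = [np.ones((n, 1))]
    if n_sites > 1:
        S, _ = _dummy(sites)
        X_parts.append(S.toarray()[:, 1:])
    if spec.age_as_factor:
        Ag, _ = _dummy(df["age"].astype(str))
        if Ag.shape[1] > 1:
            X_parts.append(Ag.toarray()[:, 1:])
    else:
        age = df["age"].to_numpy(dtype=float)
        if np.ptp(age) > 0:
            X_parts.append((age - age.mean())[:, None])
    X = np.hstack(X_parts)

    # additive term over the full pedigree
    rows = relmat.index_of(df["id"])
    Z1 = sp.csr_matrix(
        (np.ones(n), (np.arange(n), rows)), shape=(n, len(relmat.ids))
    )
    cf = la.cho_factor(relmat.A + 1e-10 * np.eye(len(relmat.ids)), lower=True)
    Ainv = la.cho_solve(cf, np.eye(len(relmat.ids)))
    Ainv = 0.5 * (Ainv + Ainv.T)
    logdet_A = 2.0 * np.sum(np.log(np.diag(cf[0])))
    terms = [RandomTerm("additive", Z1, Ainv=Ainv, logdet_A=logdet_A)]

    def add_identity_term(name: str, codes: pd.Series, enabled: bool):
        if not enabled:
            return
        Z, levels = _dummy(codes)
        if len(levels) > 1:
            terms.append(RandomTerm(name, Z))
        else:
            logger.info("dropping term %s: fewer than two levels", name)

    # site x additive: a separate pedigree-structured effect per site.  The
    # covariance is block-diagonal over sites with A restricted to each
    # site's trees, which keeps the component identifiable (an identity
    # covariance would be fully aliased with the residual, since every tree
    # grows on exactly one site).
    if spec.site_additive and n_sites > 1:
        combos = sites + "|" + df["id"]
        Zsa, levels = _dummy(combos)
        runs: list[tuple[str, list]] = []
        for lv in levels:
            s_, id_ = lv.split("|", 1)
            if not runs or runs[-1][0] != s_:
                runs.append((s_, []))
            runs[-1][1].append(id_)
        blocks, logdet = [], 0.0
        for _, lev_ids in runs:
            Asub = relmat.submatrix(lev_ids)
            cfs = la.cho_factor(Asub + 1e-10 * np.eye(len(lev_ids)), lower=True)
            inv = la.cho_solve(cfs, np.eye(len(lev_ids)))
            blocks.append(0.5 * (inv + inv.T))
            logdet += 2.0 * np.sum(np.log(np.diag(cfs[0])))
        terms.append(RandomTerm("site_additive", Zsa, Ainv=la.block_diag(*blocks),
                                logdet_A=logdet))

    add_identity_term("block", sites + "|" + df["block"].astype(str), spec.block)
    add_identity_term(
        "site_family", sites + "|" + df["family"].astype(str),
        spec.site_family and n_sites > 1,
    )
    add_identity_term("family", df["family"].astype(str), spec.family)
    return y, X, terms


def fit_ablup(
    phenotypes: pd.DataFrame,
    relmat: RelationshipMatrix,
    spec: ModelSpec | None = None,
    varcomps: dict | None = None,
    init: dict | None = None,
    on_nonconvergence: str = "raise",
    compute_pev: bool = True,
) -> EvaluationResult:
    """Fit the evaluation model and extract EBVs for every pedigree member.

    Parameters
    ----------
    phenotypes
        Table with columns ``id, site, block, family, age, trait``.
    relmat
        Numerator relationship matrix covering all phenotyped ids.
    spec
        Model configuration; defaults fit every supported term.
    varcomps
        If given, variance components are held fixed (no REML) and the MME is
        solved once — used for fold resampling and for closed-form checks.

    Returns
    -------
    EvaluationResult
        EBVs, SEs, reliabilities and theoretical accuracies for all pedigree
        members, with variance components and the printed-formula h2.
    """
    spec = spec or ModelSpec()
    y, X, terms = build_design(phenotypes, relmat, spec)
    model = MixedModel(y, X, terms)

    if varcomps is not None:
        sol, _ = model.solve(varcomps, compute_C=compute_pev)
        res = REMLResult(
            varcomps=dict(varcomps), loglik=np.nan, loglik_trace=[],
            converged=True, n_iter=0, solution=sol,
        )
    else:
        res = model.reml(
            init=init,
            method=spec.reml_method,
            max_iter=spec.max_iter,
            tol_loglik=spec.tol_loglik,
            tol_var=spec.tol_var,
            on_nonconvergence=on_nonconvergence,
        )

    sol = res.solution
    sigma_a2 = res.varcomps.get("additive", 0.0)
    ebv = sol.u["additive"]
    pev = sol.pev.get("additive")
    f = relmat.f
    if pev is None:
        se = np.full_like(ebv, np.nan)
        rel = np.full_like(ebv, np.nan)
        acc = np.full_like(ebv, np.nan)
    elif sigma_a2 > 0:
        se = np.sqrt(pev)
        rel = np.clip(1.0 - pev / ((1.0 + f) * sigma_a2), 0.0, 1.0)
        acc = theoretical_accuracy(se, f, sigma_a2)
    else:
        se = np.sqrt(pev)
        rel = np.zeros_like(ebv)
        acc = np.zeros_like(ebv)
    table = pd.DataFrame(
        {"id": relmat.ids, "ebv": ebv, "se": se, "reliability": rel, "accuracy": acc}
    )
    return EvaluationResult(
        table=table,
        varcomps=res.varcomps,
        h2=heritability(res.varcomps) if sigma_a2 >= 0 else np.nan,
        loglik=res.loglik,
        loglik_trace=res.loglik_trace,
        converged=res.converged,
        dropped_terms=res.dropped,
        fixed_effects=sol.beta,
    )


def ablup_cross_generation(
    relmat: RelationshipMatrix,
    phenotypes_f1: pd.DataFrame,
    validation_ids,
    original_ebv: np.ndarray,
    validation_phenotype: np.ndarray | None = None,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    spec: ModelSpec | None = None,
    varcomps: dict | None = None,
    reestimate_varcomps: bool = False,
):
    """Pedigree-only cross-generational validation baseline.

    F1 phenotyped individuals are partitioned into ``folds`` random subsets,
    ``reps`` times.  For each rep x fold the evaluation model is fitted on
    the other folds' phenotypes and the validation individuals' EBVs are
    predicted through the relationship matrix.  Accuracy is the Pearson
    correlation of these predictions with ``original_ebv`` (the full-data
    EBVs); predictive ability correlates them with raw phenotypes.

    By default the variance components of a single full-data fit are reused
    across folds (one REML fit; each fold is then a single MME solve); pass
    ``reestimate_varcomps=True`` to rerun REML per fold.

    Returns a :class:`treegs.validation.ValidationReport` with the single
    method ``"ABLUP"``.
    """
    from .validation import ValidationReport, make_folds, summarise_rep_correlations

    spec = spec or ModelSpec()
    ids = phenotypes_f1["id"].astype(str).to_numpy()
    unique_train_ids = pd.unique(ids)
    if len(unique_train_ids) < folds:
        raise ValueError("fewer training individuals than folds")
    validation_ids = [str(i) for i in validation_ids]
    original_ebv = np.asarray(original_ebv, dtype=float)

    if varcomps is None and not reestimate_varcomps:
        full = fit_ablup(phenotypes_f1, relmat, spec, on_nonconvergence="warn")
        varcomps = full.varcomps

    fold_table = make_folds(unique_train_ids, folds, reps, seed)
    vidx = relmat.index_of(validation_ids)
    rep_acc, rep_pa = [], []
    for rep, grp in fold_table.groupby("rep"):
        preds = np.zeros((folds, len(validation_ids)))
        for fold, fgrp in grp.groupby("fold"):
            holdout = set(fgrp["id"])
            train = phenotypes_f1[~phenotypes_f1["id"].astype(str).isin(holdout)]
            if reestimate_varcomps:
                fit = fit_ablup(train, relmat, spec, on_nonconvergence="warn",
                                compute_pev=False)
            else:
                fit = fit_ablup(train, relmat, spec, varcomps=varcomps,
                                compute_pev=False)
            preds[fold] = fit.table["ebv"].to_numpy()[vidx]
        pred_mean = preds.mean(axis=0)
        rep_acc.append(_safe_corr(pred_mean, original_ebv))
        if validation_phenotype is not None:
            rep_pa.append(_safe_corr(pred_mean, validation_phenotype))
    return ValidationReport(
        scenario="ablup-baseline",
        methods=["ABLUP"],
        accuracy={"ABLUP": summarise_rep_correlations(rep_acc)},
        predictive_ability={
            "ABLUP": summarise_rep_correlations(rep_pa) if rep_pa else (np.nan, np.nan)
        },
        rep_correlations=pd.DataFrame({"rep": range(reps), "ABLUP_accuracy": rep_acc}),
        folds=fold_table,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])
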