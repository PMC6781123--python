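"""Marker-effect prediction models: RR-BLUP, generalized ridge, Bayes-B.

All three fit the linear model ``y = 1 mu + Z g + e`` where ``y`` are tree
records (EBVs or deregressed EBVs), ``Z`` the n x p matrix of minor-allele
counts and ``g`` the marker effects; a genomic value is the sum of an
individual's marker effects plus the intercept.

* RR-BLUP: ``g = (Z'Z + lambda I)^-1 Z' y`` with a single ridge parameter
  ``lambda = s2_e / s2_g`` (all effects shrunk equally); ``lambda`` can be
  estimated by REML on the equivalent single-variance random-effect model.
* GRR: a second step replaces the common ``lambda`` with per-marker
  ``lambda_k = s2_e / s2_gk`` where ``s2_gk = g_k^2 / (1 - h_kk)`` and
  ``h_kk`` is the (n+k)-th diagonal element of the influence matrix of the
  ridge-augmented regression (computed here through its n x n dual form).
* Bayes-B: mixture prior — an effect is null with probability ``pi`` and
  otherwise has its own scaled-inverse-chi-square variance; fitted by Gibbs
  sampling (:mod:`treegs._bayesb`), ``pi`` fixed (default 0.5).

Systems are solved in the p x p primal form when ``p <= n`` and the
algebraically identical n x n dual (Woodbury) form otherwise, which is what
makes tens of thousands of markers tractable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
from scipy.optimize import minimize_scalar

__all__ = [
    "GenotypeMatrix",
    "MarkerEffectModel",
    "RidgeLambdaError",
    "preprocess_genotypes",
    "fit_rrblup",
    "estimate_ridge_lambda",
    "fit_grr",
    "fit_bayesb",
    "predict",
]

logger = logging.getLogger(__name__)

LAMBDA_CAP = 1e12


class RidgeLambdaError(RuntimeError):
    """The genomic variance hit the zero boundary; advise a fixed lambda."""


@dataclass
class GenotypeMatrix:
    """Imputed allele-count matrix with ids and marker names.

    ``Z`` holds raw (mean-imputed) counts; centering constants are applied by
    the fitting routines so that models can be applied to new individuals
    with the *training* centering.
    """

    ids: list
    markers: list
    Z: np.ndarray
    maf: np.ndarray
    col_means: np.ndarray

    @property
    def shape(self):
        return self.Z.shape

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        index = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([index[str(i)] for i in ids], dtype=np.intp)
        return GenotypeMatrix(
            ids=[self.ids[k] for k in idx], markers=self.markers,
            Z=self.Z[idx], maf=self.maf, col_means=self.col_means,
        )

    def subset_markers(self, which) -> "GenotypeMatrix":
        which = np.asarray(which)
        if which.dtype.kind == "b":
            which = np.flatnonzero(which)
        return GenotypeMatrix(
            ids=self.ids, markers=[self.markers[k] for k in which],
            Z=self.Z[:, which], maf=self.maf[which], col_means=self.col_means[which],
        )


@dataclass
class MarkerEffectModel:
    """Fitted marker model: intercept, effects and shrinkage metadata."""

    method: str
    mu: float
    effects: np.ndarray
    markers: list
    col_means: np.ndarray           # training centering constants
    lambda_: float | np.ndarray | None = None
    pi: float | None = None
    inclusion_prob: np.ndarray | None = None
    sigma_g2: float | None = None
    sigma_e2: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"marker": self.markers, "effect": self.effects})
        if np.ndim(self.lambda_) == 1:
            df["lambda_k"] = self.lambda_
        if self.inclusion_prob is not None:
            df["inclusion_prob"] = self.inclusion_prob
        return df


def preprocess_genotypes(
    Z_raw,
    ids=None,
    markers=None,
    call_rate_threshold: float = 0.9,
) -> GenotypeMatrix:
    """Filter and impute a raw 0/1/2 count matrix with missing values.

    Markers with call rate below ``call_rate_threshold`` or zero minor-allele
    frequency (monomorphic) are dropped; remaining missing entries are
    imputed to the marker mean.  Individuals with no called genotypes at all
    are dropped with a warning.
    """
    if isinstance(Z_raw, pd.DataFrame):
        ids = list(Z_raw.index.astype(str)) if ids is None else [str(i) for i in ids]
        markers = list(Z_raw.columns.astype(str)) if markers is None else list(markers)
        Z = Z_raw.to_numpy(dtype=float)
    else:
        Z = np.array(Z_raw, dtype=float)
        ids = [str(i) for i in (ids if ids is not None else range(Z.shape[0]))]
        markers = list(markers) if markers is not None else [f"m{j}" for j in range(Z.shape[1])]

    obs = np.isfinite(Z)
    dead = ~obs.any(axis=1)
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} individuals with all-missing genotypes")
        Z, obs = Z[~dead], obs[~dead]
        ids = [i for i, d in zip(ids, dead) if not d]

    call_rate = obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.nansum(np.where(obs, Z, 0.0), axis=0) / np.maximum(obs.sum(axis=0), 1)
    freq = means / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = (call_rate >= call_rate_threshold) & (maf > 0.0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("preprocess_genotypes: dropped %d markers", n_dropped)
    Z, means, maf = Z[:, keep], means[keep], maf[keep]
    markers = [m for m, k in zip(markers, keep) if k]
    # impute to marker mean
    miss = ~np.isfinite(Z)
    if miss.any():
        Z = np.where(miss, np.broadcast_to(means, Z.shape), Z)
    return GenotypeMatrix(ids=ids, markers=markers, Z=np.ascontiguousarray(Z),
                          maf=maf, col_means=means)


def _as_zy(y, Z):
    """Common unpacking: centered response/genotypes + bookkeeping."""
    if isinstance(Z, GenotypeMatrix):
        markers, means, Zm = Z.markers, Z.col_means, Z.Z
    else:
        Zm = np.asarray(Z, dtype=float)
        markers = [f"m{j}" for j in range(Zm.shape[1])]
        means = Zm.mean(axis=0)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in the response")
    if Zm.shape[0] != len(y):
        raise ValueError("response length does not match genotype rows")
    if Zm.shape[0] == 0 or Zm.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    mu = float(y.mean())
    yc = y - mu
    Zc = Zm - means
    return mu, yc, Zc, markers, means


def _ridge_solve(Zc: np.ndarray, yc: np.ndarray, lam) -> np.ndarray:
    """Solve (Zc'Zc + diag(lam))^-1 Zc' yc, primal or dual by shape."""
    n, p = Zc.shape
    lam = np.asarray(lam, dtype=float)
    if lam.ndim == 0:
        lam = np.full(p, float(lam))
    if p <= n:
        M = Zc.T @ Zc
        M[np.arange(p), np.arange(p)] += lam
        return la.solve(M, Zc.T @ yc, assume_a="pos")
    Zl = Zc / lam
    K = Zl @ Zc.T
    K[np.arange(n), np.arange(n)] += 1.0
    alpha = la.solve(K, yc, assume_a="pos")
    return Zl.T @ alpha


def fit_rrblup(y, Z, lam: float | None = None) -> MarkerEffectModel:
    """Ridge-regression BLUP of marker effects with a common shrinkage.

    ``lam`` is the ridge parameter ``s2_e / s2_g``; if omitted it is
    estimated by REML (:func:`estimate_ridge_lambda`).  The intercept is the
    response mean; effects are fitted on centered y and Z.
    """
    mu, yc, Zc, markers, means = _as_zy(y, Z)
    sigma_g2 = sigma_e2 = None
    if lam is None:
        lam, sigma_g2, sigma_e2 = _reml_marker_variances(yc, Zc)
    if lam <= 0:
        raise ValueError("ridge lambda must be positive")
    g = _ridge_solve(Zc, yc, lam)
    return MarkerEffectModel(
        method="RR-BLUP", mu=mu, effects=g, markers=markers, col_means=means,
        lambda_=float(lam), sigma_g2=sigma_g2, sigma_e2=sigma_e2,
    )


def estimate_ridge_lambda(y, Z) -> float:
    """REML estimate of ``lambda = s2_e / s2_g`` under ``g ~ N(0, I s2_g)``.

    Works in the n x n kernel form: eigendecompose ``Zc Zc'`` on the
    orthogonal complement of the intercept and optimise the profiled
    restricted likelihood of the variance ratio.
    """
    _, yc, Zc, _, _ = _as_zy(y, Z)
    if len(yc) <= 10:
        raise ValueError("need more than 10 observations to estimate lambda")
    lam, _, _ = _reml_marker_variances(yc, Zc)
    return lam


def _reml_marker_variances(yc: np.ndarray, Zc: np.ndarray):
    """(lambda, s2_g, s2_e) by 1-D REML on the marker-kernel model."""
    n = len(yc)
    # orthonormal basis of the complement of the intercept via a Householder
    # reflection mapping e1 -> 1/sqrt(n)
    u = np.full(n, 1.0 / np.sqrt(n))
    v = u.copy()
    v[0] -= 1.0
    v /= np.linalg.norm(v)
    H = np.eye(n) - 2.0 * np.outer(v, v)
    B = H[:, 1:]                       # n x (n-1)
    Zt = B.T @ Zc
    Kt = Zt @ Zt.T
    s, U = la.eigh(Kt)
    s = np.clip(s, 0.0, None)
    yt = U.T @ (B.T @ yc)
    m = n - 1

    def negll(log_gamma):
        gam = np.exp(log_gamma)
        d = gam * s + 1.0
        sig2 = np.sum(yt**2 / d) / m
        return np.sum(np.log(d)) + m * np.log(sig2)

    lo, hi = np.log(1e-8), np.log(1e8)
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    gam = float(np.exp(res.x))
    if res.x <= lo + 1e-3:
        raise RidgeLambdaError(
            "genomic variance estimate at the zero boundary; supply a fixed lambda"
        )
    d = gam * s + 1.0
    sigma_e2 = float(np.sum(yt**2 / d) / m)
    sigma_g2 = gam * sigma_e2
    return 1.0 / gam, sigma_g2, sigma_e2


def grr_hat_diagonal(Zc: np.ndarray, lam: float) -> np.ndarray:
    """Diagonal entries ``h_kk`` (rows n+k) of the ridge influence matrix.

    The influence matrix is ``H = T (T'T)^-1 T'`` for the augmented design
    ``T = [[1, Z], [0, lam I]]``; block elimination of the intercept reduces
    the marker-block diagonal of ``(T'T)^-1`` to ``(Zc'Zc + lam^2 I)^-1`` so
    that ``h_{n+k} = 1 - zc_k' (lam^2 I + Zc Zc')^-1 zc_k`` — an n x n solve
    regardless of p (checked against the brute-force H in the tests).
    """
    n = Zc.shape[0]
    M = Zc @ Zc.T
    M[np.arange(n), np.arange(n)] += lam**2
    V = la.solve(M, Zc, assume_a="pos")
    return 1.0 - np.einsum("ij,ij->j", Zc, V)


def fit_grr(y, Z, lam_init: float | None = None,
            sigma_e2: float | None = None) -> MarkerEffectModel:
    """Generalized ridge regression with per-marker shrinkage.

    Step 1 is an RR-BLUP fit (lambda estimated unless given); step 2 derives
    ``lambda_k = s2_e / (g_k^2 / (1 - h_kk))`` and re-solves the ridge system
    with ``diag(lambda_k)``.  Markers with vanishing step-1 effects or
    leverage ``h_kk`` ~ 1 get their shrinkage capped at a large finite value
    (warning logged).
    """
    step1 = fit_rrblup(y, Z, lam=lam_init)
    mu, yc, Zc, markers, means = _as_zy(y, Z)
    lam = float(step1.lambda_)
    if sigma_e2 is None:
        sigma_e2 = step1.sigma_e2
    if sigma_e2 is None:
        # fixed user lambda: plug-in residual variance from step 1
        fit = Zc @ step1.effects
        edf = float(np.sum(np.einsum("ij,ij->j", Zc, _ridge_dual_apply(Zc, lam))))
        sigma_e2 = float(np.sum((yc - fit) ** 2) / max(len(yc) - 1 - edf, 1.0))
    h = grr_hat_diagonal(Zc, lam)
    one_minus_h = 1.0 - h
    bad = one_minus_h < 1e-10
    g1sq = step1.effects**2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_gk2 = g1sq / one_minus_h
        lam_k = sigma_e2 / sigma_gk2
    capped = bad | ~np.isfinite(lam_k) | (lam_k > LAMBDA_CAP)
    if capped.any():
        logger.warning("fit_grr: capping shrinkage for %d markers", int(capped.sum()))
        lam_k = np.where(capped, LAMBDA_CAP, lam_k)
    g = _ridge_solve(Zc, yc, lam_k)
    return MarkerEffectModel(
        method="GRR", mu=mu, effects=g, markers=markers, col_means=means,
        lambda_=lam_k, sigma_e2=sigma_e2, sigma_g2=step1.sigma_g2,
        metadata={"lambda_step1": lam, "h_kk": h},
    )


def _ridge_dual_apply(Zc: np.ndarray, lam: float) -> np.ndarray:
    """Columns of (lam I + Zc Zc')^-1 Zc, used for the ridge edf."""
    n = Zc.shape[0]
    M = Zc @ Zc.T
    M[np.arange(n), np.arange(n)] += lam
    return la.solve(M, Zc, assume_a="pos")


def fit_bayesb(
    y,
    Z,
    pi: float = 0.5,
    iters: int = 10_000,
    burn_in: int = 2_000,
    thin: int = 10,
    seed: int = 0,
    nu: float = 5.0,
    nu_e: float = 5.0,
    r2: float = 0.5,
) -> MarkerEffectModel:
    """Bayes-B by Gibbs sampling with a fixed mixture probability ``pi``.

    The effect-variance prior is scaled-inverse-chi-square(``nu``, S) with S
    set so the prior mean effect variance equals
    ``r2 var(y) / ((1 - pi) sum_k var(z_k))``; the residual prior scale
    matches ``(1 - r2) var(y)``.  Chains are reproducible from ``seed``; a
    degenerate residual draw triggers one jittered-seed restart (logged).

    Defaults are test-scale (10k iterations); the full-scale settings used
    for production runs are 100k iterations, 20k burn-in, thinning 100.
    """
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must be in (0, 1)")
    if iters <= burn_in:
        raise ValueError("iters must exceed burn_in")
    mu0, yc, Zc, markers, means = _as_zy(y, Z)
    vy = float(np.var(yc))
    if vy == 0:
        vy = 1e-8
    sum_vz = float(np.sum(np.var(Zc, axis=0)))
    target = r2 * vy / max((1.0 - pi) * sum_vz, 1e-12)
    S = target * (nu - 2.0) / nu
    S_e = (1.0 - r2) * vy * (nu_e - 2.0) / nu_e

    from ._bayesb import bayesb_gibbs

    Zf = np.asfortranarray(Zc)
    for attempt in range(2):
        mu_c, g, incl, sig_e, n_samples = bayesb_gibbs(
            Zf, yc, pi, nu, S, nu_e, S_e, iters, burn_in, thin,
            (seed + attempt * 7919) % 2**31,
        )
        if np.isfinite(sig_e) and np.isfinite(g).all():
            break
        logger.warning("fit_bayesb: degenerate chain; restarting with jittered seed")
    return MarkerEffectModel(
        method="Bayes-B", mu=mu0 + mu_c, effects=g, markers=markers,
        col_means=means, pi=pi, inclusion_prob=incl, sigma_e2=sig_e,
        metadata={"seed": seed, "iters": iters, "burn_in": burn_in,
                  "thin": thin, "nu": nu, "S": S, "n_samples": n_samples},
    )


def predict(model: MarkerEffectModel, Z_new) -> np.ndarray:
    """Genomic values ``mu + Zc g`` using the training-set centering.

    ``Z_new`` may be a :class:`GenotypeMatrix` (marker ids are checked and
    must match the training order) or a bare array assumed aligned.
    """
    if isinstance(Z_new, GenotypeMatrix):
        if list(Z_new.markers) != list(model.markers):
            missing = sorted(set(model.markers) - set(Z_new.markers))
            raise ValueError(
                f"marker mismatch: {len(missing)} training markers absent, "
                f"e.g. {missing[:5]}"
            )
        Zm = Z_new.Z
    else:
        Zm = np.asarray(Z_new, dtype=float)
        if Zm.shape[1] != len(model.markers):
            raise ValueError("marker count mismatch")
    return model.mu + (Zm - model.col_means) @ model.effects
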