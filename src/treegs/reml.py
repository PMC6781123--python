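"""Dense mixed-model machinery: Henderson's equations and REML.

Model
-----
``y = X b + sum_j Z_j u_j + e`` with ``u_j ~ N(0, A_j s2_j)`` (``A_j`` the
identity for environmental terms, the numerator relationship matrix for the
additive term) and ``e ~ N(0, I s2_e)``.

Everything is driven by the mixed-model equations (MME) with coefficient
matrix

    M = [X Z]' [X Z] / s2_e  +  blockdiag(0, A_j^-1 / s2_j ...)

whose inverse ``C`` yields BLUEs/BLUPs, prediction-error (co)variances
(``PEV_i = C_ii`` for the corresponding random level) and the trace terms
needed by REML.

Two REML algorithms are provided:

* ``"em"`` — classical expectation-maximisation updates.  Monotone in the
  restricted likelihood but slow near boundaries.
* ``"ai"`` (default) — a hybrid: a few EM warm-up rounds, then
  Average-Information (Newton-type) updates with step halving, falling back
  to EM whenever an AI step would leave the parameter space or decrease the
  likelihood.  Variances are constrained non-negative by projection on a
  small floor; a component pinned at the floor for several consecutive
  iterations is dropped from the model.

All REML identities used here (traces of ``P V_j`` through ``C``, the
determinant identity ``log|V| + log|X'V^-1 X| = log|R| + log|G| + log|M|``)
are verified against direct dense-``V`` computations in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

__all__ = ["RandomTerm", "MixedModel", "MMESolution", "REMLResult", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the likelihood trace."""

    def __init__(self, message: str, loglik_trace: list):
        super().__init__(message)
        self.loglik_trace = loglik_trace


@dataclass
class RandomTerm:
    """One random effect: design matrix and (inverse) covariance structure."""

    name: str
    Z: sp.csr_matrix              # n x q incidence matrix
    Ainv: np.ndarray | None = None  # None => identity covariance
    logdet_A: float = 0.0

    @property
    def nlevels(self) -> int:
        return self.Z.shape[1]


@dataclass
class MMESolution:
    beta: np.ndarray
    u: dict
    residuals: np.ndarray
    fitted: np.ndarray
    pev: dict                      # term name -> diag of C block (zeros if dropped)
    varcomps: dict


@dataclass
class REMLResult:
    varcomps: dict
    loglik: float
    loglik_trace: list = field(repr=False)
    converged: bool = True
    n_iter: int = 0
    solution: MMESolution | None = None
    dropped: list = field(default_factory=list)


def full_rank_columns(X: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR pivoting).

    Used to absorb aliased fixed effects (e.g. an age covariate constant
    within sites) without user intervention.
    """
    if X.shape[1] == 0:
        return np.array([], dtype=np.intp)
    _, R, piv = la.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag[0], 1.0)).sum())
    return np.sort(piv[:rank])


class MixedModel:
    """Dense MME representation of a single-trait linear mixed model."""

    def __init__(self, y: np.ndarray, X: np.ndarray, terms: list[RandomTerm]):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in the response")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        keep = full_rank_columns(X)
        self.x_columns_kept = keep
        X = X[:, keep]
        self.n, self.p = X.shape
        self.y = y
        self.X = X
        self.terms = terms
        blocks = [sp.csr_matrix(X)] + [t.Z for t in terms]
        W = sp.hstack(blocks, format="csr")
        self.W = W
        self.WtW = np.asarray((W.T @ W).todense())
        self.Wty = np.asarray(W.T @ y).ravel()
        self.yty = float(y @ y)
        # column offsets of each block inside W
        sizes = [self.p] + [t.nlevels for t in terms]
        ends = np.cumsum(sizes)
        self.slices = {"__fixed__": slice(0, self.p)}
        for t, s0, s1 in zip(terms, ends[:-1], ends[1:]):
            self.slices[t.name] = slice(int(s0), int(s1))

    # ------------------------------------------------------------------ MME
    def _active_index(self, active: list) -> np.ndarray:
        idx = [np.arange(self.p)]
        for t in self.terms:
            if t.name in active:
                sl = self.slices[t.name]
                idx.append(np.arange(sl.start, sl.stop))
        return np.concatenate(idx).astype(np.intp)

    def _assemble(self, sigma2: dict, active: list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = self._active_index(active)
        s2e = sigma2["residual"]
        M = self.WtW[np.ix_(idx, idx)] / s2e
        rhs = self.Wty[idx] / s2e
        pos = self.p
        for t in self.terms:
            if t.name not in active:
                continue
            q = t.nlevels
            if t.Ainv is None:
                d = np.arange(pos, pos + q)
                M[d, d] += 1.0 / sigma2[t.name]
            else:
                M[pos: pos + q, pos: pos + q] += t.Ainv / sigma2[t.name]
            pos += q
        return M, rhs, idx

    def solve(self, varcomps: dict, compute_C: bool = False):
        """Solve the MME at fixed variance components.

        Returns an :class:`MMESolution`; with ``compute_C`` the full inverse
        of the (active) coefficient matrix is formed and per-level PEVs are
        extracted.
        """
        active = [t.name for t in self.terms if varcomps.get(t.name, 0.0) > 0.0]
        M, rhs, idx = self._assemble(varcomps, active)
        cf = self._chol(M)
        s = la.cho_solve(cf, rhs, check_finite=False)
        C = _chol_inverse(cf[0]) if compute_C else None
        return self._package(s, varcomps, active, C), (cf, s, idx, active, C, M)

    def _package(self, s, varcomps, active, C) -> MMESolution:
        beta = s[: self.p]
        u, pev = {}, {}
        pos = self.p
        cdiag = np.diag(C) if C is not None else None
        for t in self.terms:
            q = t.nlevels
            if t.name in active:
                u[t.name] = s[pos: pos + q]
                if cdiag is not None:
                    pev[t.name] = cdiag[pos: pos + q].copy()
                pos += q
            else:
                u[t.name] = np.zeros(q)
                if cdiag is not None:
                    pev[t.name] = np.full(q, np.nan)
        fitted = self.X @ beta
        for t in self.terms:
            fitted = fitted + t.Z @ u[t.name]
        resid = self.y - fitted
        return MMESolution(beta=beta, u=u, residuals=resid, fitted=fitted,
                           pev=pev, varcomps=dict(varcomps))

    # ----------------------------------------------------------------- REML
    def _loglik(self, varcomps, active, M_chol, s) -> float:
        """Restricted log-likelihood up to an additive constant."""
        s2e = varcomps["residual"]
        idx = self._active_index(active)
        ypy = (self.yty - s @ self.Wty[idx]) / s2e
        logdet_M = 2.0 * np.sum(np.log(np.diag(M_chol)))
        logdet_G = 0.0
        for t in self.terms:
            if t.name in active:
                logdet_G += t.nlevels * np.log(varcomps[t.name]) + t.logdet_A
        logdet_R = self.n * np.log(s2e)
        return -0.5 * (logdet_R + logdet_G + logdet_M + ypy)

    def _chol(self, M):
        try:
            return la.cho_factor(M, lower=True, check_finite=False)
        except la.LinAlgError:
            jitter = 1e-10 * float(np.mean(np.diag(M)))
            M2 = M + jitter * np.eye(M.shape[0])
            return la.cho_factor(M2, lower=True, check_finite=False)

    def _loglik_at(self, varcomps, active) -> float:
        """Restricted log-likelihood at arbitrary components (no inverse)."""
        M, rhs, idx = self._assemble(varcomps, active)
        cf = self._chol(M)
        s = la.cho_solve(cf, rhs, check_finite=False)
        return self._loglik(varcomps, active, cf[0], s)

    def _reml_quantities(self, varcomps, active):
        """Solve MME with full inverse and derive score/EM ingredients."""
        M, rhs, idx = self._assemble(varcomps, active)
        cf = self._chol(M)
        s = la.cho_solve(cf, rhs, check_finite=False)
        C = _chol_inverse(cf[0].copy())
        sol = self._package(s, varcomps, active, C)
        s2e = varcomps["residual"]
        ll = self._loglik(varcomps, active, cf[0], s)
        quad, trace = {}, {}
        pos = self.p
        for t in self.terms:
            if t.name not in active:
                continue
            q = t.nlevels
            uj = sol.u[t.name]
            Cjj = C[pos: pos + q, pos: pos + q]
            if t.Ainv is None:
                quad[t.name] = float(uj @ uj)
                trace[t.name] = float(np.trace(Cjj))
            else:
                quad[t.name] = float(uj @ (t.Ainv @ uj))
                trace[t.name] = float(np.sum(t.Ainv * Cjj))
            pos += q
        return sol, cf, idx, ll, quad, trace

    def _em_update(self, varcomps, active, sol, quad, trace):
        new = dict(varcomps)
        for name in active:
            q = self.slices[name].stop - self.slices[name].start
            new[name] = (quad[name] + trace[name]) / q
        new["residual"] = float(self.y @ sol.residuals) / (self.n - self.p)
        return new

    def _score_and_ai(self, varcomps, active, sol, quad, trace, cf=None, idx=None):
        s2e = varcomps["residual"]
        names = list(active) + ["residual"]
        score = np.zeros(len(names))
        fvecs = np.zeros((self.n, len(names)))
        tr_sum = 0.0
        for k, name in enumerate(active):
            t = next(t for t in self.terms if t.name == name)
            s2j = varcomps[name]
            q = t.nlevels
            trPVj = (q - trace[name] / s2j) / s2j
            tr_sum += q - trace[name] / s2j
            yPVjPy = quad[name] / s2j**2
            score[k] = -0.5 * (trPVj - yPVjPy)
            fvecs[:, k] = (t.Z @ sol.u[name]) / s2j
        trP = (self.n - self.p - tr_sum) / s2e
        yPPy = float(sol.residuals @ sol.residuals) / s2e**2
        score[-1] = -0.5 * (trP - yPPy)
        fvecs[:, -1] = sol.residuals / s2e

        # AI_jk = 0.5 f_j' P f_k ; P f = (f - W s_f)/s2e with M s_f = W'f/s2e
        if cf is None or idx is None:
            M, _, idx = self._assemble(varcomps, active)
            cf = self._chol(M)
        Wt = self.W.T
        rhs = np.asarray(Wt @ fvecs)[idx, :] / s2e
        S = la.cho_solve(cf, rhs, check_finite=False)
        Wsub = self.W[:, idx]
        Pf = (fvecs - Wsub @ S) / s2e
        AI = 0.5 * (fvecs.T @ Pf)
        return names, score, AI

    def reml(
        self,
        init: dict | None = None,
        method: str = "ai",
        max_iter: int = 200,
        em_warmup: int = 3,
        tol_loglik: float = 1e-6,
        tol_var: float = 1e-5,
        pin_floor: float = 1e-8,
        pin_iters: int = 5,
        on_nonconvergence: str = "raise",
    ) -> REMLResult:
        """Estimate variance components by REML.

        ``init`` maps term names (plus ``"residual"``) to starting values;
        by default the phenotypic variance is split equally.
        """
        if method not in ("ai", "em"):
            raise ValueError(f"unknown REML method {method!r}")
        # scale everything by the fixed-effects-adjusted variance: raw var(y)
        # can be dominated by site-mean gaps and misleads initialisation
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        r0 = self.y - self.X @ beta0
        vary = float(r0 @ r0 / max(self.n - self.p, 1))
        floor = pin_floor * vary
        names_all = [t.name for t in self.terms]
        if init is None:
            # residual-heavy start keeps the early EM steps away from the
            # degenerate zero-residual basin that rich random structures
            # (pedigree + site x pedigree terms) admit at small n
            J = len(names_all)
            init = {n: 0.2 * vary / max(J, 1) for n in names_all}
            init["residual"] = 0.7 * vary
            if "additive" in init:
                init["additive"] = 0.2 * vary
        varcomps = {n: float(init.get(n, 0.5 * vary / max(len(names_all), 1))) for n in names_all}
        varcomps["residual"] = float(init.get("residual", 0.5 * vary))
        active = [n for n in names_all if varcomps[n] > 0]
        dropped = [n for n in names_all if n not in active]
        pinned_count = {n: 0 for n in names_all}

        trace_ll: list[float] = []
        prev_ll = -np.inf
        ll_stall = 0
        converged = False
        it = 0
        while it < max_iter:
            it += 1
            sol, cf, idx, ll, quad, trace = self._reml_quantities(varcomps, active)
            trace_ll.append(ll)
            use_em = method == "em" or it <= em_warmup
            old = dict(varcomps)
            if use_em:
                varcomps = self._em_update(varcomps, active, sol, quad, trace)
                em_pred = varcomps
            else:
                names, score, AI = self._score_and_ai(
                    varcomps, active, sol, quad, trace, cf=cf, idx=idx
                )
                # Newton step restricted to components well off the boundary;
                # near-zero components make the AI matrix numerically singular
                # and are updated by EM instead
                em_cand = self._em_update(varcomps, active, sol, quad, trace)
                em_pred = em_cand
                big = [k for k, nm in enumerate(names)
                       if nm == "residual" or varcomps[nm] > 1e-5 * vary]
                delta = None
                if np.all(np.isfinite(AI)) and np.all(np.isfinite(score)) and big:
                    sub = np.ix_(big, big)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        try:
                            d_big = la.solve(AI[sub], score[big], assume_a="sym")
                        except la.LinAlgError:
                            d_big = None
                    if d_big is not None and np.all(np.isfinite(d_big)):
                        delta = np.array(
                            [em_cand[nm] - varcomps[nm] for nm in names]
                        )
                        delta[big] = d_big
                stepped = False
                if delta is not None:
                    step = 1.0
                    cap = 100.0 * vary
                    for _ in range(10):
                        cand = dict(varcomps)
                        ok = True
                        for nm, d in zip(names, step * delta):
                            v = varcomps[nm] + d
                            # trust region: no component may explode or, for
                            # the residual, hit the floor
                            if v > cap or (nm == "residual" and v <= floor):
                                ok = False
                                break
                            cand[nm] = max(v, floor)
                        # accept only likelihood-non-decreasing steps
                        if ok and self._loglik_at(cand, active) >= ll - 1e-6:
                            varcomps = cand
                            stepped = True
                            break
                        step *= 0.5
                if not stepped:
                    varcomps = self._em_update(varcomps, active, sol, quad, trace)

            # boundary projection; a component is considered pinned only when
            # its EM update (which never leaves an interior optimum) also
            # keeps it at the floor — AI projections alone do not count
            for nm in list(active):
                if varcomps[nm] <= floor:
                    varcomps[nm] = floor
                if em_pred.get(nm, np.inf) <= 2.0 * floor:
                    pinned_count[nm] += 1
                else:
                    pinned_count[nm] = 0
                if pinned_count[nm] >= pin_iters:
                    varcomps[nm] = 0.0
                    active.remove(nm)
                    dropped.append(nm)

            # relative change over components that are not effectively zero
            sizable = [nm for nm in active + ["residual"]
                       if max(old[nm], varcomps[nm]) > 1e-4 * vary]
            dvar = max(
                (abs(varcomps[nm] - old[nm]) / max(old[nm], floor) for nm in sizable),
                default=0.0,
            )
            if abs(ll - prev_ll) < tol_loglik:
                ll_stall += 1
            else:
                ll_stall = 0
            if it > 1 and ll_stall >= 1 and (dvar < tol_var or ll_stall >= 3):
                converged = True
                break
            prev_ll = ll

        sol, (cf, s, idx, active_fin, C, M) = self.solve(varcomps, compute_C=True)
        ll = self._loglik(varcomps, active_fin, cf[0], s)
        trace_ll.append(ll)
        if not converged:
            msg = f"REML did not converge in {max_iter} iterations (|dlogL| trace attached)"
            if on_nonconvergence == "raise":
                raise ConvergenceError(msg, trace_ll)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return REMLResult(
            varcomps=dict(varcomps),
            loglik=ll,
            loglik_trace=trace_ll,
            converged=converged,
            n_iter=it,
            solution=sol,
            dropped=dropped,
        )


def _chol_inverse(L: np.ndarray) -> np.ndarray:
    """Full inverse from a lower Cholesky factor via LAPACK dpotri."""
    inv, info = la.lapack.dpotri(L, lower=1)
    if info != 0:
        raise la.LinAlgError(f"dpotri failed with info={info}")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv
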