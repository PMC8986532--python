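"""Penalized-spline generalized additive mixed models.

Gaussian identity-link GAMMs with up to two univariate smooths (cubic or
cyclic cubic regression splines), an optional tensor-product interaction,
linear terms, and one animal-level random intercept. The random intercept
is represented as a block of indicator columns with an identity (ridge)
penalty, so the whole model is a penalized least-squares problem

    min ||y - X beta||^2 + sum_k lambda_k beta' S_k beta.

Smoothing parameters (including the ridge weight of the random intercept,
whose implied variance is sigma^2_resid / lambda_re) are estimated by
maximizing the integrated marginal likelihood of the Gaussian model, with
the residual variance profiled out. Every smooth is centered with a
sum-to-zero constraint over the data so the intercept stays identifiable;
effective degrees of freedom (e.d.f.) are the trace of each term's block
of the influence matrix.

Two marginal-likelihood flavors are available: REML (the penalty null
space integrated flat; the default for reporting a single model) and ML
(null-space directions treated as fixed effects), whose optimum yields a
marginal AIC — parameter count = fixed effects + smoothing/variance
parameters + scale — used to rank candidate fixed-effect structures. A
conditional, e.d.f.-based AIC is also reported per fit.

Smooth-term significance follows the tests of Wood (2013): terms with a
penalty null space use the fractional-rank pseudo-inverse Wald statistic
on the term's fitted values with a chi-square-mixture reference; fully
penalized terms (the centered cyclic spline, tensor interactions, the
random intercept) use the random-effect likelihood-free test, whitening
by the marginal covariance of the other random effects and referring
||R_m b_m||^2/sigma^2 to its exact weighted-chi-square null law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .core_io import SampleTable, ValidationError
from .splines import SplineBasis, cubic_spline_basis, cyclic_spline_basis

__all__ = [
    "LinearTerm",
    "InteractionTerm",
    "SmoothTerm",
    "TensorTerm",
    "GammFit",
    "CompiledGamm",
    "fit_gamm",
    "smooth_term_test",
    "select_model",
    "candidate_models",
    "parse_formula",
]

_RHO_CLIP = 25.0


@dataclass(frozen=True)
class LinearTerm:
    var: str

    @property
    def name(self) -> str:
        return self.var


@dataclass(frozen=True)
class InteractionTerm:
    """Product of two linear covariates."""

    var_a: str
    var_b: str

    @property
    def name(self) -> str:
        return f"{self.var_a}:{self.var_b}"


@dataclass(frozen=True)
class SmoothTerm:
    var: str
    basis: str = "cubic_spline"  # or "cyclic_cubic_spline"
    k: int = 10
    period: float = 365.0

    def __post_init__(self) -> None:
        if self.basis not in ("cubic_spline", "cyclic_cubic_spline"):
            raise ValidationError(f"unknown basis {self.basis!r}")
        if self.k < 3:
            raise ValidationError("spline k must be >= 3")

    @property
    def name(self) -> str:
        return ("cc" if self.basis == "cyclic_cubic_spline" else "s") + f"({self.var})"


@dataclass(frozen=True)
class TensorTerm:
    """Tensor-product interaction (main effects excluded) of two smooths."""

    a: SmoothTerm
    b: SmoothTerm

    @property
    def name(self) -> str:
        return f"ti({self.a.var},{self.b.var})"


def _liu_tail(x: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang upper-tail approximation for sum lam_i * chi2_1."""
    lam = np.asarray(lam, dtype=float)
    mu_q = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    if c2 <= 0:
        return 1.0
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    sig_q = np.sqrt(2 * c2)
    t = (x - mu_q) / sig_q
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        dof = c2**3 / c3**2
    mu_x = dof + delta
    sig_x = np.sqrt(2.0) * a
    z = t * sig_x + mu_x
    if delta > 0:
        return float(sps.ncx2.sf(z, dof, delta))
    return float(sps.chi2.sf(z, dof))


def _sim_f_tail(x: float, lam: np.ndarray, res_df: float, nq: int = 50) -> float:
    """Tail of (sum lam_i chi2_1) / (chi2_df / df), by quadrature over the
    denominator."""
    p = (np.arange(1, nq + 1) - 0.5) / nq
    q = sps.chi2.ppf(p, res_df)
    return float(np.mean([_liu_tail(x * qi / res_df, lam) for qi in q]))


def _wood_test(b: np.ndarray, Xt: np.ndarray, V: np.ndarray, rank: float,
               res_df: float) -> tuple[float, float, float]:
    """Smooth-term significance following Wood (2013, Biometrika 100:221).

    Tests f = Xt b = 0 using the Bayesian covariance V of the term
    coefficients, pseudo-inverted at the (possibly fractional) reference
    rank; fractional parts use a two-eigenvalue interpolation and a
    chi-square-mixture reference distribution, and the two sign-ambiguous
    statistic variants are averaged. Returns (stat, p, rank_used).
    """
    R = np.linalg.qr(Xt, mode="r")
    Vf = R @ V @ R.T
    Vf = (Vf + Vf.T) / 2.0
    ev, U = np.linalg.eigh(Vf)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order], U[:, order]
    siv = np.sign(U[0, :])
    siv[siv == 0] = 1.0
    U = U * siv

    k = max(0, int(np.floor(rank)))
    nu = abs(rank - k)
    k1 = k + 1 if nu > 0 else k
    r_est = int((ev > max(ev[0], 1e-300) * 1e-14).sum())
    if r_est < k1:
        k1 = k = r_est
        nu = 0.0
        rank = float(r_est)
    vec = U[:, :k1].copy()
    if nu > 0 and k > 0:
        if k > 1:
            vec[:, : k - 1] /= np.sqrt(ev[: k - 1])
        b12 = np.sqrt(max(0.5 * nu * (1 - nu), 0.0))
        B = np.array([[1.0, b12], [b12, nu]])
        scale = np.diag(ev[k - 1 : k1] ** -0.5)
        B = scale @ B @ scale
        ebv, ebU = np.linalg.eigh(B)
        rB = ebU @ np.diag(np.sqrt(np.maximum(ebv, 0))) @ ebU.T
        vec1 = vec.copy()
        vec1[:, k - 1 : k1] = (rB @ np.diag([-1.0, 1.0]) @ vec[:, k - 1 : k1].T).T
        vec[:, k - 1 : k1] = (rB @ vec[:, k - 1 : k1].T).T
    else:
        if k == 0:
            vec = vec / np.sqrt(ev[0])
        else:
            vec = vec / np.sqrt(ev[:k])
        vec1 = vec
        if k == 1:
            rank = 1.0
    fb = R @ b
    d = float(((vec.T @ fb) ** 2).sum())
    d1 = float(((vec1.T @ fb) ** 2).sum())

    rank1 = rank
    pval = 2.0
    if nu > 0:
        if k1 == 1:
            rank1 = 1.0
            lam = np.ones(1)
        else:
            lam = np.ones(k1)
            rp = nu + 1.0
            lam[k - 1] = (rp + np.sqrt(rp * (2 - rp))) / 2.0
            lam[k1 - 1] = rp - lam[k - 1]
        pval = (_sim_f_tail(d, lam, res_df) + _sim_f_tail(d1, lam, res_df)) / 2.0
    if pval > 1.0:
        r1 = max(rank1, 1.0)
        pval = (
            float(sps.f.sf(d / r1, r1, res_df)) + float(sps.f.sf(d1 / r1, r1, res_df))
        ) / 2.0
    return d, float(min(pval, 1.0)), float(rank)


def _mroot(S: np.ndarray) -> np.ndarray:
    """B with B @ B.T = S (positive semidefinite), rank columns only."""
    ev, U = np.linalg.eigh((S + S.T) / 2.0)
    keep = ev > max(ev.max(), 1e-300) * 1e-12
    return U[:, keep] * np.sqrt(ev[keep])


def _wsumchi2_tail(x: float, weights: np.ndarray, dfs: np.ndarray) -> float:
    """P(sum_j w_j chi2_{df_j} > x) by Imhof's exact integral."""
    w = np.asarray(weights, dtype=float)
    h = np.asarray(dfs, dtype=float)
    keep = w != 0
    w, h = w[keep], h[keep]
    if len(w) == 0:
        return 1.0 if x <= 0 else 0.0

    def integrand(u):
        theta = 0.5 * np.sum(h * np.arctan(w * u)) - 0.5 * x * u
        rho = np.exp(0.25 * np.sum(h * np.log1p((w * u) ** 2)))
        return np.sin(theta) / (u * rho)

    from scipy.integrate import quad

    scale = np.abs(w).max()
    cut = 1.0 / scale
    with warnings.catch_warnings():
        # the tail piece decays like u^-(1+sum(h)/2); quadpack's
        # extrapolation can flag slow convergence spuriously
        warnings.simplefilter("ignore")
        v1, _ = quad(integrand, 0, cut, limit=200)
        v2, _ = quad(integrand, cut, np.inf, limit=400)
    return float(min(max(0.5 + (v1 + v2) / np.pi, 0.0), 1.0))


class _FullPenaltyTester:
    """Significance test for fully penalized terms (no penalty null space),
    following the random-effect test of Wood (2013, Biometrika 100:1005).

    The term's coefficients are tested against zero with the other random
    effects integrated into the response covariance (whitening by
    ``chol(I + R_re S_re^{-1} R_re')``) and the remaining penalties absorbed
    into a QR factorization; the statistic ||R_m b_m||^2 / sigma^2 is
    referred to its exact weighted-chi-square null distribution, with an
    F-type correction for the estimated scale.
    """

    def __init__(self, compiled: "CompiledGamm"):
        self.c = compiled
        self.R = np.linalg.qr(compiled.X, mode="r")

    def test(self, term: _TermInfo, lam_map: dict, beta: np.ndarray,
             Vp: np.ndarray, sigma2: float, resid_df: float) -> tuple[float, float, float]:
        c = self.c
        p = c.p
        rand = next((t for t in c.terms if t.kind == "random"), None)
        use_re = rand is not None and rand.name != term.name
        rind = np.zeros(p, dtype=bool)
        if use_re:
            rind[rand.sl] = True
        R1 = self.R[:, ~rind]
        if use_re:
            lam_re = lam_map[rand.name]
            R2 = self.R[:, rind]
            M = np.eye(self.R.shape[0]) + (R2 @ R2.T) / lam_re
            L = linalg.cholesky(M, lower=False)
            Ve = Vp @ self.R.T @ M @ self.R @ Vp / sigma2
        else:
            L = None
            Ve = Vp @ (c.XtX @ Vp) / sigma2
        # absorb every non-random penalty (including the tested term's own)
        nonrand_pos = np.flatnonzero(~rind)
        colmap = {g: i for i, g in enumerate(nonrand_pos)}
        p1 = len(nonrand_pos)
        S1 = np.zeros((p1, p1))
        i = 0
        for g in c.groups:
            idx = np.arange(g.sl.start, g.sl.stop)
            for S, name in zip(g.mats, g.names):
                if not (use_re and rand is not None and g.sl == rand.sl):
                    sub = np.array([colmap[j] for j in idx])
                    S1[np.ix_(sub, sub)] += lam_map[name] * S
                i += 1
        top = L @ R1 if use_re else R1
        B1 = _mroot(S1)
        LRB = np.vstack([top, B1.T])
        # move the tested term's columns last, then QR
        term_cols = np.array([colmap[j] for j in range(term.sl.start, term.sl.stop)])
        others = np.setdiff1d(np.arange(p1), term_cols)
        LRB = LRB[:, np.concatenate([others, term_cols])]
        Rq = np.linalg.qr(LRB, mode="r")
        dm = len(term_cols)
        Rm = Rq[-dm:, -dm:]
        b_m = beta[term.sl]
        stat = float(((Rm @ b_m) ** 2).sum()) / sigma2
        B = _mroot(Ve[term.sl, term.sl])
        ev = np.linalg.eigvalsh((Rm @ B).T @ (Rm @ B)) / sigma2
        ev = np.clip(ev, 0.0, None)[::-1]
        rank = float((ev > max(ev.max(), 1e-300) * 1e-12).sum())
        if stat <= 0:
            return stat, 1.0, rank
        k = max(1, int(round(resid_df)))
        pval = _wsumchi2_tail(
            0.0,
            np.concatenate([ev, [-stat / k]]),
            np.concatenate([np.ones(len(ev)), [k]]),
        )
        return stat, pval, rank


def _constrain(X: np.ndarray, S: np.ndarray):
    """Sum-to-zero reparametrization: returns (XZ, Z'SZ, Z)."""
    C = X.sum(axis=0)[:, None]
    Q, _ = np.linalg.qr(C, mode="complete")
    Z = Q[:, 1:]
    return X @ Z, Z.T @ S @ Z, Z


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


@dataclass
class _TermInfo:
    name: str
    kind: str  # intercept | linear | interaction | smooth | tensor | random
    sl: slice
    spec: object = None
    basis: SplineBasis | None = None
    Z: np.ndarray | None = None
    basis_b: SplineBasis | None = None
    Z_b: np.ndarray | None = None
    levels: np.ndarray | None = None


@dataclass
class _PenaltyGroup:
    sl: slice
    mats: list  # block-sized penalty matrices
    names: list  # one smoothing-parameter name per matrix
    ranks: list = field(default_factory=list)
    logdets: list = field(default_factory=list)


class CompiledGamm:
    """Design, penalties and reusable structure for one model on one table.

    Compiling once and calling :meth:`fit` per response makes replicated
    simulations cheap: only the response changes across replicates.
    """

    def __init__(
        self,
        data: SampleTable,
        fixed: Sequence,
        random_intercept: str | None = "animal_id",
    ):
        df = data.df
        n = len(df)
        cols = [np.ones((n, 1))]
        terms = [_TermInfo("(Intercept)", "intercept", slice(0, 1))]
        groups: list[_PenaltyGroup] = []
        pos = 1
        for spec in fixed:
            if isinstance(spec, LinearTerm):
                x = df[spec.var].to_numpy(float)[:, None]
                cols.append(x)
                terms.append(_TermInfo(spec.name, "linear", slice(pos, pos + 1), spec))
                pos += 1
            elif isinstance(spec, InteractionTerm):
                x = (df[spec.var_a].to_numpy(float) * df[spec.var_b].to_numpy(float))[:, None]
                cols.append(x)
                terms.append(
                    _TermInfo(spec.name, "interaction", slice(pos, pos + 1), spec)
                )
                pos += 1
            elif isinstance(spec, SmoothTerm):
                basis = _build_basis(df[spec.var].to_numpy(float), spec)
                Xc, Sc, Z = _constrain(basis.X, basis.S)
                sl = slice(pos, pos + Xc.shape[1])
                cols.append(Xc)
                terms.append(_TermInfo(spec.name, "smooth", sl, spec, basis, Z))
                groups.append(_PenaltyGroup(sl, [Sc], [spec.name]))
                pos = sl.stop
            elif isinstance(spec, TensorTerm):
                ba = _build_basis(df[spec.a.var].to_numpy(float), spec.a)
                bb = _build_basis(df[spec.b.var].to_numpy(float), spec.b)
                Xa, Sa, Za = _constrain(ba.X, ba.S)
                Xb, Sb, Zb = _constrain(bb.X, bb.S)
                Xt = _row_kron(Xa, Xb)
                pa, pb = Xa.shape[1], Xb.shape[1]
                S1 = np.kron(Sa, np.eye(pb))
                S2 = np.kron(np.eye(pa), Sb)
                sl = slice(pos, pos + pa * pb)
                cols.append(Xt)
                terms.append(
                    _TermInfo(spec.name, "tensor", sl, spec, ba, Za, bb, Zb)
                )
                groups.append(
                    _PenaltyGroup(sl, [S1, S2], [f"{spec.name}|{spec.a.var}", f"{spec.name}|{spec.b.var}"])
                )
                pos = sl.stop
            else:
                raise ValidationError(f"unknown term spec {spec!r}")
        if random_intercept is not None:
            codes, levels = pd.factorize(df[random_intercept])
            Zr = np.zeros((n, len(levels)))
            Zr[np.arange(n), codes] = 1.0
            sl = slice(pos, pos + len(levels))
            cols.append(Zr)
            info = _TermInfo(f"(1|{random_intercept})", "random", sl)
            info.levels = np.asarray(levels)
            terms.append(info)
            groups.append(_PenaltyGroup(sl, [np.eye(len(levels))], [info.name]))
            pos = sl.stop

        self.X = np.hstack(cols)
        self.n, self.p = self.X.shape
        self.terms = terms
        self.groups = groups
        self.random_intercept = random_intercept
        self.XtX = self.X.T @ self.X
        # rank check of the unpenalized part (intercept + linear/interaction)
        fixed_cols = [t.sl for t in terms if t.kind in ("intercept", "linear", "interaction")]
        Xf = np.hstack([self.X[:, s] for s in fixed_cols])
        if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            raise ValidationError("fixed-effect design is rank deficient")
        for g in groups:
            for S in g.mats:
                ev = np.linalg.eigvalsh(S)
                tol = max(ev.max(), 1.0) * 1e-10
                g.ranks.append(int((ev > tol).sum()))
                g.logdets.append(float(np.log(ev[ev > tol]).sum()))
        self.lam_names = [name for g in groups for name in g.names]
        # penalty null-space dimension per penalized term: fully penalized
        # terms (null dim 0) get the random-effect-style significance test
        self.null_dim = {}
        for t in terms:
            if t.kind not in ("smooth", "tensor", "random"):
                continue
            g = next(g for g in self.groups if g.sl == t.sl)
            dim = t.sl.stop - t.sl.start
            if len(g.mats) == 1:
                self.null_dim[t.name] = dim - g.ranks[0]
            else:
                ev = np.linalg.eigvalsh(sum(g.mats))
                self.null_dim[t.name] = int((ev <= max(ev.max(), 1.0) * 1e-10).sum())
        self._tester: _FullPenaltyTester | None = None
        # rotation separating penalty null space (treated as fixed effects
        # by marginal ML) from penalized directions, block by block
        T = np.eye(self.p)
        pos_idx: list[int] = []
        self._group_pos: list[np.ndarray] = []  # rotated positive dirs per group
        self._group_Sproj: list[list[np.ndarray]] = []
        for g in self.groups:
            idx = np.arange(g.sl.start, g.sl.stop)
            Ssum = sum(g.mats)
            ev, U = np.linalg.eigh(Ssum)
            tol = max(ev.max(), 1.0) * 1e-10
            keep = ev > tol
            order = np.argsort(keep)  # null directions first
            U = U[:, order]
            keep = keep[order]
            T[np.ix_(idx, idx)] = U
            gp = idx[keep]
            pos_idx.extend(gp.tolist())
            self._group_pos.append(gp)
            self._group_Sproj.append([U[:, keep].T @ S @ U[:, keep] for S in g.mats])
        self.T = T
        self.pos_idx = np.asarray(pos_idx, dtype=int)
        self.M0 = self.p - len(pos_idx)
        self.XtX_rot = T.T @ self.XtX @ T

    # -- criterion -----------------------------------------------------

    def _assemble(self, lam: np.ndarray) -> np.ndarray:
        A = self.XtX.copy()
        i = 0
        for g in self.groups:
            idx = np.arange(g.sl.start, g.sl.stop)
            for S in g.mats:
                A[np.ix_(idx, idx)] += lam[i] * S
                i += 1
        return A

    def _logdet_S(self, lam: np.ndarray):
        """log generalized determinant and total rank of the penalty."""
        total, rank = 0.0, 0
        i = 0
        for g in self.groups:
            if len(g.mats) == 1:
                total += g.ranks[0] * np.log(lam[i]) + g.logdets[0]
                rank += g.ranks[0]
                i += 1
            else:
                M = sum(lam[i + j] * S for j, S in enumerate(g.mats))
                ev = np.linalg.eigvalsh(M)
                tol = max(ev.max(), 1e-300) * 1e-10
                keep = ev > tol
                total += float(np.log(ev[keep]).sum())
                rank += int(keep.sum())
                i += len(g.mats)
        return total, rank

    def _score(self, rho: np.ndarray, Xty: np.ndarray, yty: float):
        lam = np.exp(np.clip(rho, -_RHO_CLIP, _RHO_CLIP))
        A = self._assemble(lam)
        try:
            c, low = linalg.cho_factor(A, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve((c, low), Xty, check_finite=False)
        rss = max(yty - 2 * beta @ Xty + beta @ (self.XtX @ beta), 1e-300)
        pen = float(beta @ (A - self.XtX) @ beta)
        Dp = rss + max(pen, 0.0)
        logdet_A = 2.0 * float(np.log(np.diag(c)).sum())
        logdet_S, rank = self._logdet_S(lam)
        m = self.n - (self.p - rank)
        if m <= 0:
            return np.inf
        return m * (np.log(2 * np.pi * Dp / m) + 1.0) + logdet_A - logdet_S

    def _score_ml(self, rho: np.ndarray, Xty_rot: np.ndarray, yty: float):
        """-2 x marginal ML: penalized directions integrated out, null
        directions (true fixed effects) and the scale profiled."""
        lam = np.exp(np.clip(rho, -_RHO_CLIP, _RHO_CLIP))
        Ar = self.XtX_rot.copy()
        i = 0
        for gp, Sprojs in zip(self._group_pos, self._group_Sproj):
            for Sp in Sprojs:
                Ar[np.ix_(gp, gp)] += lam[i] * Sp
                i += 1
        try:
            c, low = linalg.cho_factor(Ar, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve((c, low), Xty_rot, check_finite=False)
        rss = max(yty - 2 * beta @ Xty_rot + beta @ (self.XtX_rot @ beta), 1e-300)
        pen = float(beta @ (Ar - self.XtX_rot) @ beta)
        Dp = rss + max(pen, 0.0)
        if len(self.pos_idx):
            A1 = Ar[np.ix_(self.pos_idx, self.pos_idx)]
            try:
                c1 = linalg.cholesky(A1, check_finite=False)
            except linalg.LinAlgError:
                return np.inf
            logdet_A1 = 2.0 * float(np.log(np.diag(c1)).sum())
        else:
            logdet_A1 = 0.0
        logdet_S, _ = self._logdet_S(lam)
        n = self.n
        return n * (np.log(2 * np.pi * Dp / n) + 1.0) + logdet_A1 - logdet_S

    # -- fitting -------------------------------------------------------

    def fit(
        self,
        y,
        method: str = "REML",
        rho0: np.ndarray | None = None,
        max_restarts: int = 3,
        xatol: float = 0.05,
    ) -> "GammFit":
        """Estimate smoothing parameters and fit.

        ``method='REML'`` maximizes the integrated marginal likelihood with
        the penalty null space integrated flat (restricted likelihood);
        ``method='ML'`` treats null-space directions as fixed effects and
        integrates only the penalized directions, which additionally yields
        a marginal AIC (``aic_marginal``) comparable across models with
        different fixed effects.
        """
        y = np.asarray(y, dtype=float)
        if len(y) != self.n:
            raise ValidationError("response length mismatch")
        if method not in ("ML", "REML"):
            raise ValidationError("method must be 'ML' or 'REML'")
        Xty = self.X.T @ y
        yty = float(y @ y)
        if method == "ML":
            score, args = self._score_ml, (self.T.T @ Xty, yty)
        else:
            score, args = self._score, (Xty, yty)
        d = len(self.lam_names)
        converged = True
        if d == 0:
            lam = np.empty(0)
            rho = np.empty(0)
            score_val = float(score(rho, *args))
        else:
            rho = np.zeros(d) if rho0 is None else np.asarray(rho0, dtype=float).copy()
            best = None
            rng = np.random.default_rng(0)
            for attempt in range(max_restarts + 1):
                res = optimize.minimize(
                    score,
                    rho,
                    args=args,
                    method="Nelder-Mead",
                    options={
                        "xatol": xatol,
                        "fatol": 1e-4,
                        "maxfev": 400 * max(d, 1),
                    },
                )
                if best is None or res.fun < best.fun:
                    best = res
                if res.success and np.isfinite(res.fun):
                    break
                rho = (rho0 if rho0 is not None else np.zeros(d)) + rng.normal(0, 2, d)
            else:
                warnings.warn("smoothing-parameter optimization did not converge")
            converged = bool(best.success and np.isfinite(best.fun))
            rho = np.clip(best.x, -_RHO_CLIP, _RHO_CLIP)
            lam = np.exp(rho)
            score_val = float(best.fun)
        aic_marginal = (
            score_val + 2.0 * (self.M0 + d + 1) if method == "ML" else None
        )
        return self._finalize(y, Xty, lam, rho, method, converged, aic_marginal)

    def fit_at(self, y, rho) -> "GammFit":
        """Fit with the smoothing parameters held fixed at exp(rho)."""
        y = np.asarray(y, dtype=float)
        rho = np.asarray(rho, dtype=float)
        lam = np.exp(np.clip(rho, -_RHO_CLIP, _RHO_CLIP))
        return self._finalize(y, self.X.T @ y, lam, rho, "fixed", True)

    def _finalize(self, y, Xty, lam, rho, method, converged,
                  aic_marginal=None) -> "GammFit":
        A = self._assemble(lam)
        jitter = 0.0
        for attempt in range(4):
            try:
                c, low = linalg.cho_factor(
                    A + jitter * np.eye(self.p), check_finite=False
                )
                break
            except linalg.LinAlgError:
                jitter = max(jitter * 100.0, np.trace(A) / self.p * 1e-10)
        else:
            raise linalg.LinAlgError("penalized normal equations not positive definite")
        if jitter:
            A = A + jitter * np.eye(self.p)
        beta = linalg.cho_solve((c, low), Xty, check_finite=False)
        Ainv = linalg.cho_solve((c, low), np.eye(self.p), check_finite=False)
        fitted = self.X @ beta
        resid = y - fitted
        rss = float(resid @ resid)
        edf_vec = (Ainv * self.XtX).sum(axis=1)
        total_edf = float(edf_vec.sum())
        n = self.n
        resid_df = max(n - total_edf, 1.0)
        sigma2 = rss / resid_df
        lam_map = dict(zip(self.lam_names, lam))
        var_individual = None
        re_name = None
        for t in self.terms:
            if t.kind == "random":
                re_name = t.name
                var_individual = float(sigma2 / lam_map[t.name])
        # conditional AIC: Gaussian deviance at fitted values + 2*(edf+1)
        sig2_ml = max(rss / n, 1e-300)
        aic = n * (np.log(2 * np.pi * sig2_ml) + 1.0) + 2.0 * (total_edf + 1.0)
        var_y = float(np.var(y, ddof=1)) if n > 1 else np.nan
        adj_r2 = 1.0 - sigma2 / var_y if var_y and var_y > 0 else np.nan

        # alternative (upper) e.d.f. per coefficient, 2*tr(F) - tr(FF):
        # this is the reference d.f. the smooth-term test is referred to
        F_infl = Ainv @ self.XtX
        edf1_vec = 2.0 * edf_vec - (F_infl * F_infl.T).sum(axis=1)
        edf = {}
        term_tests = {}
        for t in self.terms:
            block_edf = float(edf_vec[t.sl].sum())
            edf[t.name] = block_edf
            b = beta[t.sl]
            Vb = sigma2 * Ainv[t.sl, t.sl]
            if t.kind in ("linear", "interaction", "intercept"):
                se = float(np.sqrt(max(Vb[0, 0], 0.0)))
                tval = float(b[0] / se) if se > 0 else np.inf
                p = float(2 * sps.t.sf(abs(tval), resid_df))
                term_tests[t.name] = {
                    "estimate": float(b[0]),
                    "se": se,
                    "t": tval,
                    "edf": 1.0,
                    "ref_df": 1.0,
                    "F": tval**2,
                    "p": p,
                }
            elif t.kind in ("smooth", "tensor", "random"):
                dim = t.sl.stop - t.sl.start
                if self.null_dim.get(t.name, 1) == 0 or t.kind == "random":
                    if self._tester is None:
                        self._tester = _FullPenaltyTester(self)
                    Vp_full = sigma2 * Ainv
                    stat, p, rank_used = self._tester.test(
                        t, lam_map, beta, Vp_full, sigma2, resid_df
                    )
                    term_tests[t.name] = {
                        "edf": block_edf,
                        "ref_df": rank_used,
                        "F": stat / max(rank_used, 1e-10),
                        "p": p,
                    }
                else:
                    ref_df = float(min(dim, max(edf1_vec[t.sl].sum(), 0.0)))
                    Xt = self.X[:, t.sl]
                    stat, p, rank_used = _wood_test(b, Xt, Vb, ref_df, resid_df)
                    term_tests[t.name] = {
                        "edf": block_edf,
                        "ref_df": ref_df,
                        "F": stat / max(rank_used, 1e-10),
                        "p": p,
                    }
        smoothing = {k: float(v) for k, v in lam_map.items()}
        return GammFit(
            compiled=self,
            coefficients=beta,
            cov=sigma2 * Ainv,
            fitted=fitted,
            y=y,
            rho=np.asarray(rho, dtype=float),
            smoothing_params=smoothing,
            var_individual=var_individual,
            var_residual=float(sigma2),
            edf=edf,
            total_edf=total_edf,
            aic=float(aic),
            adj_r2=float(adj_r2),
            term_tests=term_tests,
            rss=rss,
            method=method,
            converged=converged,
            random_term=re_name,
            aic_marginal=aic_marginal,
        )


def _build_basis(x: np.ndarray, spec: SmoothTerm) -> SplineBasis:
    if spec.basis == "cubic_spline":
        return cubic_spline_basis(x, k=spec.k)
    return cyclic_spline_basis(x, k=spec.k, period=spec.period, lo=1.0)


@dataclass
class GammFit:
    """A fitted GAMM (see module docstring for the estimation details)."""

    compiled: CompiledGamm = field(repr=False)
    coefficients: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    rho: np.ndarray = field(repr=False)
    smoothing_params: dict
    var_individual: float | None
    var_residual: float
    edf: dict
    total_edf: float
    aic: float
    adj_r2: float
    term_tests: dict
    rss: float
    method: str
    converged: bool
    random_term: str | None
    aic_marginal: float | None = None

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def term_names(self) -> list[str]:
        return [t.name for t in self.compiled.terms]

    def _term(self, name: str) -> _TermInfo:
        for t in self.compiled.terms:
            if t.name == name:
                return t
        raise KeyError(f"unknown term {name!r}; have {self.term_names()}")

    def term_effect(self, name: str, **values) -> np.ndarray:
        """Partial (centered) contribution of one term on a covariate grid.

        For smooths pass the covariate, e.g. ``term_effect("cc(doy)",
        doy=grid)``; for the tensor term pass both covariates.
        """
        t = self._term(name)
        b = self.coefficients[t.sl]
        if t.kind in ("linear",):
            x = np.asarray(values[t.spec.var], dtype=float)
            return x * b[0]
        if t.kind == "interaction":
            xa = np.asarray(values[t.spec.var_a], dtype=float)
            xb = np.asarray(values[t.spec.var_b], dtype=float)
            return xa * xb * b[0]
        if t.kind == "smooth":
            x = np.asarray(values[t.spec.var], dtype=float)
            return (t.basis.evaluate(x) @ t.Z) @ b
        if t.kind == "tensor":
            xa = np.asarray(values[t.spec.a.var], dtype=float)
            xb = np.asarray(values[t.spec.b.var], dtype=float)
            Ra = t.basis.evaluate(xa) @ t.Z
            Rb = t.basis_b.evaluate(xb) @ t.Z_b
            return _row_kron(Ra, Rb) @ b
        raise ValidationError(f"term_effect undefined for {t.kind}")

    def predict(self, data: SampleTable, include_random: bool = False) -> np.ndarray:
        df = data.df
        out = np.full(len(df), self.intercept)
        for t in self.compiled.terms:
            if t.kind == "intercept":
                continue
            if t.kind == "random":
                if include_random:
                    lut = dict(zip(t.levels, self.coefficients[t.sl]))
                    out += np.array([lut.get(a, 0.0) for a in df[self.compiled.random_intercept]])
                continue
            kwargs = {}
            if t.kind in ("linear",):
                kwargs[t.spec.var] = df[t.spec.var].to_numpy(float)
            elif t.kind == "interaction":
                kwargs[t.spec.var_a] = df[t.spec.var_a].to_numpy(float)
                kwargs[t.spec.var_b] = df[t.spec.var_b].to_numpy(float)
            elif t.kind == "smooth":
                kwargs[t.spec.var] = df[t.spec.var].to_numpy(float)
            elif t.kind == "tensor":
                kwargs[t.spec.a.var] = df[t.spec.a.var].to_numpy(float)
                kwargs[t.spec.b.var] = df[t.spec.b.var].to_numpy(float)
            out += self.term_effect(t.name, **kwargs)
        return out


def fit_gamm(
    y,
    data: SampleTable,
    fixed: Sequence,
    random_intercept: str | None = "animal_id",
    method: str = "ML",
    rho0=None,
) -> GammFit:
    """Compile and fit one GAMM; see :class:`CompiledGamm` for reuse."""
    return CompiledGamm(data, fixed, random_intercept).fit(y, method=method, rho0=rho0)


def smooth_term_test(fit: GammFit, term: str) -> dict:
    """{edf, ref_df, F, p} for one smooth term of a fitted model."""
    if term not in fit.term_tests:
        raise KeyError(f"unknown term {term!r}; have {list(fit.term_tests)}")
    t = fit.term_tests[term]
    return {k: t[k] for k in ("edf", "ref_df", "F", "p")}


def candidate_models(k: int = 10, period: float = 365.0) -> dict:
    """The eight candidate fixed-effect structures for model selection."""
    s_age = SmoothTerm("age", "cubic_spline", k)
    s_doy = SmoothTerm("doy", "cubic_spline", k)
    cc_doy = SmoothTerm("doy", "cyclic_cubic_spline", k, period)
    return {
        "age+doy": [LinearTerm("age"), LinearTerm("doy")],
        "age*doy": [LinearTerm("age"), LinearTerm("doy"), InteractionTerm("age", "doy")],
        "s(age)+doy": [s_age, LinearTerm("doy")],
        "age+s(doy)": [LinearTerm("age"), s_doy],
        "age+cc(doy)": [LinearTerm("age"), cc_doy],
        "s(age)+s(doy)": [s_age, s_doy],
        "s(age)+cc(doy)": [s_age, cc_doy],
        "s(age)+cc(doy)+ti(age,doy)": [s_age, cc_doy, TensorTerm(s_age, cc_doy)],
    }


def select_model(
    y,
    data: SampleTable,
    candidates: dict | None = None,
    random_intercept: str | None = "animal_id",
    method: str = "ML",
    k: int = 10,
) -> dict:
    """Fit all candidates and rank them by AIC.

    With ``method='ML'`` (default) the ranking uses the marginal AIC
    (fixed effects plus variance/smoothing parameters as the parameter
    count), which is comparable across candidates that differ in fixed
    effects; with REML the conditional (e.d.f.-based) AIC is used instead.
    Returns ``{"ranking": [(name, aic, delta, converged), ...],
    "best": name or None, "fits": {name: GammFit}}``. A winner is declared
    only when its AIC lead over the runner-up exceeds 2 and it converged.
    """
    if candidates is None:
        candidates = candidate_models(k=k)
    fits = {}
    for name, fixed in candidates.items():
        try:
            fits[name] = fit_gamm(y, data, fixed, random_intercept, method)
        except (ValidationError, linalg.LinAlgError) as exc:
            warnings.warn(f"candidate {name} failed: {exc}")

    def crit(fit: GammFit) -> float:
        return fit.aic_marginal if fit.aic_marginal is not None else fit.aic

    ranked = sorted(fits.items(), key=lambda kv: crit(kv[1]))
    best_aic = crit(ranked[0][1])
    ranking = [
        (name, crit(fit), crit(fit) - best_aic, fit.converged) for name, fit in ranked
    ]
    best = None
    if len(ranked) > 1:
        lead = crit(ranked[1][1]) - best_aic
        if lead > 2.0 and ranked[0][1].converged:
            best = ranked[0][0]
    elif ranked:
        best = ranked[0][0]
    return {"ranking": ranking, "best": best, "fits": fits}


def parse_formula(formula: str, k_default: int = 10) -> tuple[str, list, str | None]:
    """Parse a tiny formula grammar into term specs.

    Example: ``"state ~ s(age,k=10) + cc(doy,k=10,period=365) + (1|animal_id)"``
    returns ``("state", [SmoothTerm(...), SmoothTerm(...)], "animal_id")``.
    """
    import re

    lhs, _, rhs = formula.partition("~")
    response = lhs.strip()
    if not response or not rhs.strip():
        raise ValidationError(f"malformed formula {formula!r}")
    terms: list = []
    random_intercept = None
    for raw in re.split(r"\+(?![^(]*\))", rhs):
        tok = raw.strip()
        if not tok:
            continue
        m = re.fullmatch(r"\(1\|\s*(\w+)\s*\)", tok)
        if m:
            random_intercept = m.group(1)
            continue
        m = re.fullmatch(r"(s|cc|ti)\((.*)\)", tok)
        if m:
            fn, inner = m.groups()
            parts = [p.strip() for p in inner.split(",")]
            varnames = [p for p in parts if "=" not in p]
            opts = dict(p.split("=") for p in parts if "=" in p)
            k = int(opts.get("k", k_default))
            period = float(opts.get("period", 365))
            if fn == "s":
                terms.append(SmoothTerm(varnames[0], "cubic_spline", k))
            elif fn == "cc":
                terms.append(SmoothTerm(varnames[0], "cyclic_cubic_spline", k, period))
            else:
                terms.append(
                    TensorTerm(
                        SmoothTerm(varnames[0], "cubic_spline", k),
                        SmoothTerm(varnames[1], "cyclic_cubic_spline", k, period),
                    )
                )
            continue
        if ":" in tok:
            a, b = (s.strip() for s in tok.split(":"))
            terms.append(InteractionTerm(a, b))
            continue
        terms.append(LinearTerm(tok))
    return response, terms, random_intercept
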