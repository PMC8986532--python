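"""Penalized regression spline bases.

Both bases parametrize the spline by its values at a set of knots
(cardinal form). Writing ``h_j`` for inter-knot gaps, the second
derivatives at the knots are a linear map ``delta = B^{-1} D beta`` of the
knot values, and the wiggliness penalty — the integrated squared second
derivative — is ``beta' D' B^{-1} D beta``:

* the *cubic regression spline* uses natural boundary conditions
  (zero second derivative at the end knots); its penalty has nullity 2
  (constant and linear functions are unpenalized);
* the *cyclic cubic spline* identifies the last knot with the first and
  forces value, first and second derivative to match across the period
  boundary; its penalty has nullity 1 (constants only).

Knots are placed at data quantiles for the cubic basis and uniformly over
one full period for the cyclic basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ValidationError

__all__ = ["SplineBasis", "cubic_spline_basis", "cyclic_spline_basis"]


class BasisError(ValueError):
    """Too few distinct covariate values for the requested basis dimension."""


@dataclass
class SplineBasis:
    """Design columns, penalty and evaluator for one smooth."""

    kind: str  # "cubic" | "cyclic"
    knots: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    S: np.ndarray = field(repr=False)
    period: float | None = None

    @property
    def dim(self) -> int:
        return self.S.shape[0]

    def evaluate(self, x) -> np.ndarray:
        """Basis rows for new covariate values (cyclic values are wrapped)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "cubic":
            return _cr_rows(x, self.knots)
        return _cc_rows(x, self.knots)


def _cr_matrices(knots: np.ndarray):
    k = len(knots)
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    F = np.linalg.solve(B, D)  # knot values -> interior second derivatives
    S = D.T @ F
    return h, F, (S + S.T) / 2.0


def _interp_rows(x, knots, h, F_full, wrap: bool):
    """Natural-cubic interpolation weights of x on the knot values."""
    k = len(knots)
    n_coef = F_full.shape[1]
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    xl, xr, hj = knots[j], knots[j + 1], h[j]
    am = (xr - x) / hj
    ap = (x - xl) / hj
    cm = ((xr - x) ** 3 / hj - hj * (xr - x)) / 6.0
    cp = ((x - xl) ** 3 / hj - hj * (x - xl)) / 6.0
    rows = np.zeros((len(x), n_coef))
    nF = F_full.shape[0]
    jl = j % n_coef if wrap else j
    jr = (j + 1) % n_coef if wrap else j + 1
    np.add.at(rows, (np.arange(len(x)), jl), am)
    np.add.at(rows, (np.arange(len(x)), jr), ap)
    rows += cm[:, None] * F_full[j % nF] + cp[:, None] * F_full[(j + 1) % nF]
    return rows


def _cr_rows(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    k = len(knots)
    h, F, _ = _cr_matrices(knots)
    F_full = np.vstack([np.zeros(k), F, np.zeros(k)])  # natural: delta_1=delta_k=0
    inner = np.clip(x, knots[0], knots[-1])
    rows = _interp_rows(inner, knots, h, F_full, wrap=False)
    # linear extrapolation beyond the end knots
    low, high = x < knots[0], x > knots[-1]
    if low.any() or high.any():
        eps = (knots[-1] - knots[0]) * 1e-7
        for mask, x0, sgn in ((low, knots[0], 1.0), (high, knots[-1], -1.0)):
            if mask.any():
                r0 = _interp_rows(np.array([x0]), knots, h, F_full, wrap=False)
                r1 = _interp_rows(np.array([x0 + sgn * eps]), knots, h, F_full, wrap=False)
                slope = sgn * (r1 - r0) / eps
                rows[mask] = r0 + (x[mask] - x0)[:, None] * slope
    return rows


def cubic_spline_basis(x, k: int = 10, knots=None) -> SplineBasis:
    """Penalized cubic regression spline with knots at data quantiles."""
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise BasisError("cubic spline needs k >= 3")
    if knots is None:
        ux = np.unique(x)
        if len(ux) < k:
            raise BasisError(f"need >= {k} distinct x values, got {len(ux)}")
        knots = np.quantile(ux, np.linspace(0, 1, k))
        knots = np.unique(knots)
        if len(knots) < k:
            raise BasisError("quantile knots collide; reduce k")
    else:
        knots = np.asarray(knots, dtype=float)
    _, _, S = _cr_matrices(knots)
    basis = SplineBasis(kind="cubic", knots=knots, X=np.empty(0), S=S)
    basis.X = basis.evaluate(x)
    return basis


def _cc_matrices(knots: np.ndarray):
    k = len(knots)
    m = k - 1  # free coefficients; beta_k == beta_1
    h = np.diff(knots)
    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for i in range(m):
        ip = (i + 1) % m
        im = (i - 1) % m
        hi = h[i]
        him = h[i - 1]  # h_{i-1}, wrapping to the last gap for i=0
        B[i, i] = (him + hi) / 3.0
        B[i, ip] += hi / 6.0
        B[i, im] += him / 6.0
        D[i, i] = -(1.0 / him + 1.0 / hi)
        D[i, ip] += 1.0 / hi
        D[i, im] += 1.0 / him
    F = np.linalg.solve(B, D)  # knot values -> second derivatives (periodic)
    S = D.T @ F
    return h, F, (S + S.T) / 2.0


def _cc_rows(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    period = knots[-1] - knots[0]
    xw = (x - knots[0]) % period + knots[0]
    h, F, _ = _cc_matrices(knots)
    return _interp_rows(xw, knots, h, F, wrap=True)


def cyclic_spline_basis(x, k: int = 10, period: float = 365.0, lo: float = 1.0) -> SplineBasis:
    """Cyclic cubic spline over ``[lo, lo+period)`` with k uniform knots.

    The basis has ``k-1`` free coefficients; spline value and first two
    derivatives match at the period boundary by construction.
    """
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise BasisError("cyclic spline needs k >= 3")
    if np.any((x < lo) | (x > lo + period)):
        raise ValidationError(f"cyclic covariate outside [{lo}, {lo + period}]")
    if len(np.unique(x)) < k - 1:
        raise BasisError(f"need >= {k - 1} distinct x values for k={k}")
    knots = np.linspace(lo, lo + period, k)
    _, _, S = _cc_matrices(knots)
    basis = SplineBasis(kind="cyclic", knots=knots, X=np.empty(0), S=S, period=period)
    basis.X = basis.evaluate(x)
    return basis
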