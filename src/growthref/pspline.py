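"""Penalized cubic B-spline smoothing (P-splines).

The smoother used throughout the pipeline: a cubic B-spline basis on
equally spaced interior knots, a second-order difference penalty on the
basis coefficients, and a smoothing parameter chosen by generalized
cross-validation (GCV) unless fixed by the caller.  Because the penalty
null space contains all straight lines, constants and linear trends are
reproduced exactly at any penalty strength; heavier penalties shrink the
fit toward a straight line rather than toward zero.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

from .errors import FitError

__all__ = ["PenalizedCubicSpline"]

_DEFAULT_LAM_GRID = np.logspace(-4.0, 8.0, 49)
_RIDGE = 1e-9  # numerical regularisation only; far below any GCV-chosen penalty


def _knot_vector(lo: float, hi: float, n_interior: int, degree: int) -> np.ndarray:
    inner = np.linspace(lo, hi, n_interior + 2)
    return np.concatenate(
        [np.full(degree, lo), inner, np.full(degree, hi)]
    )


class PenalizedCubicSpline:
    """Cubic P-spline smoother of scattered ``(x, y)`` data.

    Parameters
    ----------
    n_knots
        Number of equally spaced interior knots.
    lam
        Fixed smoothing parameter; ``None`` selects it by GCV.
    penalty_order
        Order of the difference penalty on coefficients (default 2).
    lam_grid
        Candidate penalties searched when ``lam`` is ``None``.

    Attributes (after :meth:`fit`)
    ------------------------------
    lam_ : float        selected smoothing parameter
    edf_ : float        effective degrees of freedom, tr(H)
    gcv_ : float        GCV score at ``lam_``
    domain_ : (lo, hi)  fitted x-range; evaluation clamps to it
    """

    degree = 3

    def __init__(
        self,
        n_knots: int = 20,
        lam: float | None = None,
        penalty_order: int = 2,
        lam_grid: np.ndarray | None = None,
    ) -> None:
        if n_knots < 1:
            raise FitError("at least one interior knot is required")
        self.n_knots = int(n_knots)
        self.lam = lam
        self.penalty_order = int(penalty_order)
        self.lam_grid = _DEFAULT_LAM_GRID if lam_grid is None else np.asarray(lam_grid)
        self._bspline: BSpline | None = None

    # ------------------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        domain: tuple[float, float] | None = None,
    ) -> "PenalizedCubicSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < self.penalty_order + 2:
            raise FitError(f"cannot fit P-spline to {x.size} points")
        if domain is None:
            lo, hi = float(x.min()), float(x.max())
        else:
            lo, hi = float(domain[0]), float(domain[1])
        if not hi > lo:
            raise FitError("degenerate x-domain for spline fit")

        t = _knot_vector(lo, hi, self.n_knots, self.degree)
        xc = np.clip(x, lo, hi)
        B = BSpline.design_matrix(xc, t, self.degree)  # sparse CSR, n x nb
        nb = B.shape[1]
        D = np.diff(np.eye(nb), n=self.penalty_order, axis=0)
        P = D.T @ D
        A = (B.T @ B).toarray()
        b = B.T @ y
        n = x.size

        if self.lam is not None:
            lam = float(self.lam)
            coef = np.linalg.solve(A + lam * P + _RIDGE * np.eye(nb), b)
            H = np.linalg.solve(A + lam * P + _RIDGE * np.eye(nb), A)
            edf = float(np.trace(H))
            resid = y - B @ coef
            gcv = n * float(resid @ resid) / max(n - edf, 1e-8) ** 2
        else:
            best = None
            eye = np.eye(nb)
            for lam_c in self.lam_grid:
                M = A + lam_c * P + _RIDGE * eye
                try:
                    coef_c = np.linalg.solve(M, b)
                    edf_c = float(np.trace(np.linalg.solve(M, A)))
                except np.linalg.LinAlgError:  # pragma: no cover
                    continue
                resid = y - B @ coef_c
                denom = max(n - edf_c, 1e-8)
                gcv_c = n * float(resid @ resid) / denom**2
                if best is None or gcv_c < best[0]:
                    best = (gcv_c, lam_c, coef_c, edf_c)
            if best is None:  # pragma: no cover
                raise FitError("GCV search failed for every candidate penalty")
            gcv, lam, coef, edf = best

        self.lam_ = float(lam)
        self.edf_ = edf
        self.gcv_ = float(gcv)
        self.domain_ = (lo, hi)
        self._bspline = BSpline(t, coef, self.degree, extrapolate=False)
        return self

    # ------------------------------------------------------------------
    def __call__(self, x) -> np.ndarray:
        if self._bspline is None:
            raise FitError("spline evaluated before fit()")
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain_
        out = self._bspline(np.clip(x, lo, hi))
        # the rightmost breakpoint is open in BSpline; patch it explicitly
        if np.any(np.isnan(out)):
            out = np.where(
                np.isnan(out), self._bspline(np.nextafter(hi, lo)), out
            )
        return out
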