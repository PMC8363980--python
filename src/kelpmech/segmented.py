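"""Segmented (breakpoint) regression by iterative linearization.

Fits the two-segment model

    y = a + b·x + β·(x − ψ)₊ + error

to log10–log10 morphometric data and estimates the knot ψ where scaling
switches from the juvenile to the adult regime.  The estimator follows the
classical iterative-linearization scheme: at the current ψ the model is
augmented with the indicator term ``V = −1[x > ψ]`` scaled by γ, OLS is run
on {1, x, U=(x−ψ)₊, V}, and the knot is updated by ψ ← ψ + γ̂/β̂ until the
update is below tolerance.  At convergence γ̂ ≈ 0 and SE(ψ) = SE(γ̂)/|β̂|.
A step-halving safeguard rejects updates that increase the residual sum of
squares, and ψ is clamped to the interior (2nd-smallest, 2nd-largest x) so
both segments keep at least two points.

The knot on the log10 scale is back-transformed for reporting,
``psi_raw = 10^psi_log``, with the delta-method standard error
``SE = ln(10)·10^psi_log·SE(psi_log)``.

A brute-force grid search (:func:`grid_breakpoint`) over the same interior
is provided as an independent check: it profiles the residual sum of squares
of the plain two-segment model on a uniform ψ grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TooFewPoints

__all__ = ["BreakpointFit", "segmented_fit", "grid_breakpoint"]

LN10 = float(np.log(10.0))


@dataclass
class BreakpointFit:
    """Estimated breakpoint and segment geometry.

    ``psi_log`` is the knot on the fitted (log10) scale; ``psi_raw`` and
    ``se_psi_raw`` are back-transformed to the measurement scale (cm).
    ``slope_left``/``slope_right`` are the segment slopes below/above the
    knot.  ``converged`` is False when the iteration budget was exhausted
    or the knot had to be clamped to the interior boundary.
    """

    psi_log: float
    psi_raw: float
    se_psi_raw: float
    slope_left: float
    slope_right: float
    intercept: float
    iterations: int
    converged: bool
    sse: float
    se_psi_log: float = float("nan")
    boundary: bool = False


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least squares with coefficient covariance. Returns (beta, sse, cov)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    n, p = X.shape
    dof = max(n - rank, 1)
    xtx_inv = np.linalg.pinv(X.T @ X)
    cov = xtx_inv * (sse / dof)
    return beta, sse, cov


def _interior(x: np.ndarray) -> tuple[float, float]:
    xs = np.sort(x)
    return float(xs[1]), float(xs[-2])


def _segment_sse(x: np.ndarray, y: np.ndarray, psi: float):
    X = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    return _ols(X, y)


def _augmented_ols(x: np.ndarray, y: np.ndarray, psi: float):
    """OLS on {1, x, (x−ψ)₊, −1[x>ψ]} — the linearized working model."""
    U = np.clip(x - psi, 0.0, None)
    V = -(x > psi).astype(float)
    X = np.column_stack([np.ones_like(x), x, U, V])
    return _ols(X, y)


def segmented_fit(
    x,
    y,
    psi0: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> BreakpointFit:
    """Estimate a single breakpoint by iterative linearization.

    Parameters
    ----------
    x, y
        Log10-transformed predictor and response (equal-length, n ≥ 6).
    psi0
        Starting knot.  When omitted the iteration is restarted from a
        ladder of quantiles of ``x`` (5th–95th percentile) and the
        lowest-SSE optimum is kept, guarding against local minima of the
        profile.
    tol
        Convergence threshold on \\|Δψ\\|.
    max_iter
        Iteration budget; on exhaustion the best iterate is returned with
        ``converged=False`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 6:
        raise TooFewPoints(f"n = {x.size} < 6")
    lo, hi = _interior(x)
    if not lo < hi:
        raise TooFewPoints("x has too few distinct values")
    if psi0 is None:
        # the SSE profile in psi is generally non-convex; restart the
        # iteration from a ladder of quantiles and keep the best optimum
        starts = [float(q) for q in np.quantile(x, np.linspace(0.05, 0.95, 19))]
        fits = []
        for s in dict.fromkeys(starts):
            try:
                fits.append(segmented_fit(x, y, psi0=s, tol=tol, max_iter=max_iter))
            except TooFewPoints:
                continue
        if not fits:
            raise TooFewPoints("no feasible starting knot")
        return min(fits, key=lambda f: f.sse)
    psi = float(psi0)
    psi = float(np.clip(psi, lo + 1e-12, hi - 1e-12))
    if np.sum(x < psi) < 2 or np.sum(x > psi) < 2:
        raise TooFewPoints("need >= 2 points on each side of the initial knot")

    _, sse, _ = _segment_sse(x, y, psi)
    converged = False
    boundary = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        coef, _, _ = _augmented_ols(x, y, psi)
        beta_u, gamma = coef[2], coef[3]
        if beta_u == 0:
            converged = True
            break
        step = gamma / beta_u
        # step-halving: never accept a knot that worsens the two-segment SSE
        accepted = False
        cand, cand_sse = psi, sse
        for _ in range(30):
            cand = float(np.clip(psi + step, lo, hi))
            _, cand_sse, _ = _segment_sse(x, y, cand)
            if cand_sse <= sse + 1e-15:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            converged = True
            break
        moved = abs(cand - psi)
        boundary = cand in (lo, hi)
        psi, sse = cand, cand_sse
        if moved < tol:
            converged = True
            break

    # SE(ψ) from the augmented model evaluated at the final knot
    acoef, _, acov = _augmented_ols(x, y, psi)
    beta_u = acoef[2]
    se_gamma = float(np.sqrt(max(acov[3, 3], 0.0)))
    se_psi_log = abs(se_gamma / beta_u) if beta_u != 0 else float("nan")

    coef, sse, cov = _segment_sse(x, y, psi)
    intercept, slope_left, beta = (float(c) for c in coef)
    psi_raw = 10.0**psi
    return BreakpointFit(
        psi_log=psi,
        psi_raw=psi_raw,
        se_psi_raw=LN10 * psi_raw * se_psi_log,
        slope_left=slope_left,
        slope_right=slope_left + beta,
        intercept=intercept,
        iterations=iterations,
        converged=converged and not boundary,
        sse=sse,
        se_psi_log=se_psi_log,
        boundary=boundary,
    )


def grid_breakpoint(x, y, n_grid: int = 10_000) -> BreakpointFit:
    """Brute-force breakpoint search on a uniform knot grid.

    Profiles the SSE of the two-segment model over ``n_grid`` candidate
    knots between the 2nd-smallest and 2nd-largest x and returns the
    minimizer.  No standard error is produced.  Intended as an oracle for
    :func:`segmented_fit`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 6:
        raise TooFewPoints(f"n = {x.size} < 6")
    lo, hi = _interior(x)
    grid = np.linspace(lo, hi, n_grid)
    # batched normal equations: X(ψ) = [1, x, (x−ψ)₊], solved for all ψ at once
    U = np.clip(x[None, :] - grid[:, None], 0.0, None)   # (g, n)
    ones = np.ones_like(x)
    cols = [ones, x]
    XtX = np.empty((n_grid, 3, 3))
    Xty = np.empty((n_grid, 3))
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            XtX[:, i, j] = float(a @ b)
        XtX[:, i, 2] = XtX[:, 2, i] = U @ a
        Xty[:, i] = float(a @ y)
    XtX[:, 2, 2] = np.einsum("gn,gn->g", U, U)
    Xty[:, 2] = U @ y
    beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    yty = float(y @ y)
    sse = yty - np.einsum("gi,gi->g", beta, Xty)
    k = int(np.argmin(sse))
    psi = float(grid[k])
    b0, b1, b2 = (float(c) for c in beta[k])
    return BreakpointFit(
        psi_log=psi,
        psi_raw=10.0**psi,
        se_psi_raw=float("nan"),
        slope_left=b1,
        slope_right=b1 + b2,
        intercept=b0,
        iterations=n_grid,
        converged=True,
        sse=float(max(sse[k], 0.0)),
    )
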