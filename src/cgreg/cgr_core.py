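"""Simplex-constrained least squares for genome-proportion estimation.

For one admixed individual with counted-allele dosages ``y`` (length M)
and a design matrix ``X`` (M x N) of expected allele contents of N
candidate founder populations, the genome proportions ``b`` solve

    minimise  (y - Xb)' (y - Xb)
    subject to  b_k >= 0  and  sum_k b_k = 1   (equality mode)
                               sum_k b_k <= 1  (inequality mode)

The objective is a convex quadratic, so the constrained minimiser is the
global one.  We solve the reduced N-dimensional problem (via G = X'X and
c = X'y) with SLSQP and then polish the solution by solving the KKT
system of the identified active set exactly; a brute-force grid oracle
(:func:`grid_oracle`) is provided for independent verification.

The inequality form is useful when the candidate list may be incomplete:
the unassigned remainder ``1 - sum(b)`` absorbs genome from populations
missing from the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.optimize import minimize

from .founder_panel import FounderPanel
from .genotype_io import MISSING, GenotypeMatrix

#: constraint-satisfaction tolerance promised on output
CONSTRAINT_TOL = 1e-6
#: KKT residual tolerance targeted by the polish step
KKT_TOL = 1e-8
_CLIP = 1e-8

MODES = ("equality", "inequality")


@dataclass
class ProportionEstimate:
    """Estimated founder genome proportions for one individual."""

    individual_id: str
    b_hat: np.ndarray
    rss: float
    constraint_mode: str
    solver_status: str  # converged | max_iter | degenerate
    n_markers_used: int = 0


def objective(y: np.ndarray, X: np.ndarray, b: np.ndarray) -> float:
    """Residual sum of squares (y - Xb)'(y - Xb)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    b = np.asarray(b, dtype=float)
    if X.shape != (y.shape[0], b.shape[0]):
        raise ValueError(
            f"dimension mismatch: y has {y.shape[0]} markers, "
            f"X is {X.shape}, b has {b.shape[0]} populations"
        )
    r = y - X @ b
    return float(r @ r)


def _active_set_polish(
    G: np.ndarray, c: np.ndarray, b0: np.ndarray, mode: str
) -> tuple[np.ndarray, bool, bool]:
    """Solve the KKT system for the active set identified by ``b0``.

    Returns (b, ok, degenerate): ``ok`` means the polished point is primal
    and dual feasible to KKT_TOL-level tolerances, ``degenerate`` that the
    reduced normal-equations matrix was singular.
    """
    n = len(b0)
    scale = max(np.abs(G).max(), 1.0)
    free = b0 > 1e-7
    if not free.any():
        free = b0 == b0.max()
    sum_active = mode == "equality" or abs(b0.sum() - 1.0) < 1e-7
    degenerate = False
    for _ in range(2):
        nf = int(free.sum())
        Gff = G[np.ix_(free, free)]
        if sum_active:
            A = np.zeros((nf + 1, nf + 1))
            A[:nf, :nf] = 2.0 * Gff
            A[:nf, nf] = 1.0
            A[nf, :nf] = 1.0
            rhs = np.concatenate([2.0 * c[free], [1.0]])
        else:
            A = 2.0 * Gff
            rhs = 2.0 * c[free]
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            degenerate = True
        bf = sol[:nf]
        lam = sol[nf] if sum_active else 0.0
        if mode == "inequality" and sum_active and lam < -KKT_TOL * scale:
            # sum constraint not actually binding; retry without it
            sum_active = False
            continue
        break
    b = np.zeros(n)
    b[free] = bf
    # primal feasibility
    if (b < -1e-6).any():
        return b0, False, degenerate
    if mode == "inequality" and b.sum() > 1.0 + CONSTRAINT_TOL:
        return b0, False, degenerate
    # dual feasibility at the zero-clamped coordinates
    grad = 2.0 * (G @ b - c)
    mu = grad[~free] - lam
    if mu.size and mu.min() < -1e-6 * scale:
        return b0, False, degenerate
    # stationarity on the free set
    if nf and np.abs(grad[free] - lam).max() > 1e-5 * scale:
        return b0, False, degenerate
    return b, True, degenerate


def _solve_reduced(G: np.ndarray, c: np.ndarray, mode: str) -> tuple[np.ndarray, str]:
    """Minimise b'Gb - 2c'b over the simplex (or sub-simplex)."""
    n = len(c)
    if n == 1:
        if mode == "equality":
            return np.array([1.0]), "converged"
        # scalar QP on [0, 1]
        b = 0.0 if G[0, 0] <= 0 else float(np.clip(c[0] / G[0, 0], 0.0, 1.0))
        return np.array([b]), "converged"

    fun = lambda b: float(b @ G @ b - 2.0 * (c @ b))
    jac = lambda b: 2.0 * (G @ b - c)
    if mode == "equality":
        cons = [{"type": "eq", "fun": lambda b: b.sum() - 1.0, "jac": lambda b: np.ones(n)}]
    else:
        cons = [{"type": "ineq", "fun": lambda b: 1.0 - b.sum(), "jac": lambda b: -np.ones(n)}]
    x0 = np.full(n, 1.0 / n)
    res = minimize(
        fun,
        x0,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=cons,
        options={"ftol": 1e-14, "maxiter": 500},
    )
    b = np.clip(res.x, 0.0, None)
    status = "converged" if res.success else "max_iter"
    polished, ok, degenerate = _active_set_polish(G, c, b, mode)
    if ok and fun(polished) <= fun(b) + 1e-12 * max(abs(fun(b)), 1.0):
        b, status = polished, "converged"
    if degenerate or _reduced_hessian_singular(G, b, mode):
        status = "degenerate"
    return b, status


def _reduced_hessian_singular(G: np.ndarray, b: np.ndarray, mode: str) -> bool:
    """Detect non-identifiable coefficients: singular Hessian on the free set."""
    free = b > 1e-7
    if free.sum() <= 1:
        return False
    Gff = G[np.ix_(free, free)]
    eig = np.linalg.eigvalsh(Gff)
    return bool(eig[0] < 1e-10 * max(eig[-1], 1.0))


def solve(
    y: np.ndarray,
    X: np.ndarray,
    mode: str = "equality",
    individual_id: str = "",
) -> ProportionEstimate:
    """Estimate simplex-constrained genome proportions for one individual.

    Missing entries of ``y`` (NaN, or :data:`MISSING` in integer input) are
    removed together with the corresponding rows of ``X`` before solving
    (pairwise deletion).  Negative coefficients within 1e-8 of zero are
    clipped to exactly 0; in equality mode the vector is renormalised to
    sum exactly 1 afterwards.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("design matrix must have at least one column")
    if y.shape[0] != X.shape[0]:
        raise ValueError("y length does not match design rows")
    if np.issubdtype(y.dtype, np.integer):
        keep = y != MISSING
    else:
        keep = ~np.isnan(y.astype(float))
    if not keep.any():
        raise ValueError("all genotype entries missing")
    ym = y[keep].astype(float)
    Xm = X[keep]
    m, n = Xm.shape
    if m < n:
        warnings.warn(
            f"fewer markers ({m}) than populations ({n}); coefficients may be unstable",
            stacklevel=2,
        )
    G = Xm.T @ Xm
    c = Xm.T @ ym
    b, status = _solve_reduced(G, c, mode)
    b = np.where((b < 0) & (b > -_CLIP), 0.0, b)
    if (b < 0).any():  # beyond clip tolerance: clamp and report
        b = np.clip(b, 0.0, None)
    if mode == "equality":
        b = b / b.sum()
    r = ym - Xm @ b
    return ProportionEstimate(
        individual_id=individual_id,
        b_hat=b,
        rss=float(r @ r),
        constraint_mode=mode,
        solver_status=status,
        n_markers_used=m,
    )


def solve_ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Unconstrained least-squares coefficients (diagnostic only).

    Coefficients may be negative or exceed one and are then not
    interpretable as proportions.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    keep = ~np.isnan(y)
    coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    return coef


def estimate_proportions(
    genotypes: GenotypeMatrix,
    panel: FounderPanel,
    mode: str = "equality",
) -> list[ProportionEstimate]:
    """Solve per individual against a founder panel's design matrix."""
    if genotypes.marker_ids != panel.marker_ids:
        raise ValueError(
            "genotype markers do not match panel markers; run align_markers first"
        )
    X = panel.design
    counts = genotypes.counts
    out = []
    for j, ind in enumerate(genotypes.individual_ids):
        out.append(solve(counts[:, j], X, mode=mode, individual_id=ind))
    return out


def estimates_to_frame(estimates: list[ProportionEstimate], populations: list[str]):
    """Stack per-individual estimates into an individuals-by-populations DataFrame."""
    import pandas as pd

    if not estimates:
        return pd.DataFrame(columns=populations)
    return pd.DataFrame(
        np.vstack([e.b_hat for e in estimates]),
        index=[e.individual_id for e in estimates],
        columns=populations,
    )


# ---------------------------------------------------------------------------
# brute-force grid oracle
# ---------------------------------------------------------------------------

#: above this many grid points the oracle switches to the closed-form
#: innermost-axis minimisation (identical result, see _grid_min_accelerated)
_LITERAL_MAX = 2_000_000


def simplex_grid(n: int, step: float) -> np.ndarray:
    """All points of the unit simplex grid: compositions of 1 at resolution ``step``.

    Rows are in lexicographic order.
    """
    T = _steps(step)
    return _compositions(n, T) / T


def _steps(step: float) -> int:
    T = round(1.0 / step)
    if abs(T * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1")
    return T


_COMPOSITION_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _compositions(n: int, T: int) -> np.ndarray:
    """Non-negative integer n-vectors summing to T, lexicographically ordered.

    Built iteratively: length-k prefixes with sum <= T are each extended by
    all feasible next values, which preserves lexicographic order; the
    final coordinate is the remainder.  Results are cached read-only.
    """
    key = (n, T)
    cached = _COMPOSITION_CACHE.get(key)
    if cached is not None:
        return cached
    if n == 1:
        out = np.array([[T]], dtype=np.int64)
    else:
        prefix = np.arange(T + 1, dtype=np.int64).reshape(-1, 1)
        for _ in range(n - 2):
            rem = T - prefix.sum(axis=1)
            reps = rem + 1
            idx = np.repeat(np.arange(len(prefix)), reps)
            offsets = np.repeat(np.cumsum(reps) - reps, reps)
            nxt = np.arange(reps.sum(), dtype=np.int64) - offsets
            prefix = np.column_stack([prefix[idx], nxt])
        out = np.column_stack([prefix, T - prefix.sum(axis=1)])
    out.flags.writeable = False
    if out.nbytes < 64_000_000 and len(_COMPOSITION_CACHE) < 16:
        _COMPOSITION_CACHE[key] = out
    return out


def _grid_objectives(B: np.ndarray, G: np.ndarray, c: np.ndarray) -> np.ndarray:
    return ((B @ G) * B).sum(axis=1) - 2.0 * (B @ c)


_FLOAT_GRID_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _float_grid(n: int, T: int) -> np.ndarray:
    key = (n, T)
    cached = _FLOAT_GRID_CACHE.get(key)
    if cached is None:
        cached = _compositions(n, T) / T
        cached.flags.writeable = False
        if cached.nbytes < 64_000_000 and len(_FLOAT_GRID_CACHE) < 16:
            _FLOAT_GRID_CACHE[key] = cached
    return cached


def _grid_min_literal(G: np.ndarray, c: np.ndarray, T: int) -> np.ndarray:
    n = G.shape[0]
    B = _float_grid(n, T)
    vals = _grid_objectives(B, G, c)
    return B[int(np.argmin(vals))]  # first occurrence = lexicographically smallest


def _grid_min_accelerated(G: np.ndarray, c: np.ndarray, T: int) -> np.ndarray:
    """Exact grid minimiser with the last free axis minimised in closed form.

    Enumerates prefixes of the first n-2 coordinates; for each, the
    objective restricted to the penultimate coordinate m (the last being
    determined by the sum) is a quadratic with constant curvature, so its
    integer minimiser is found among {0, floor(m*), ceil(m*), R}.  Visits
    the same feasible grid and applies the same lexicographic tie-break as
    literal enumeration.
    """
    n = G.shape[0]
    full = _float_grid(n - 1, T)  # rows (prefix..., remainder)/T, lex ordered
    P, r = full[:, :-1], full[:, -1]
    g_pm, g_pl = G[:-2, -2], G[:-2, -1]
    # f(u) = f0 + beta*u + alpha*u^2 along the penultimate axis, u = m/T
    f0 = (
        ((P @ G[:-2, :-2]) * P).sum(axis=1)
        + 2.0 * r * (P @ g_pl)
        + r * r * G[-1, -1]
        - 2.0 * (P @ c[:-2] + r * c[-1])
    )
    alpha = G[-2, -2] - 2.0 * G[-2, -1] + G[-1, -1]
    beta = (
        2.0 * (P @ (g_pm - g_pl))
        + 2.0 * r * (G[-2, -1] - G[-1, -1])
        - 2.0 * (c[-2] - c[-1])
    )
    if alpha > 0:
        # integer minimiser of a strictly convex parabola lies at floor or
        # ceil of the stationary point, clipped into [0, R]; the clipped
        # pair also covers the endpoint cases
        u_star = -beta / (2.0 * alpha)
        lo = np.clip(np.floor(u_star * T), 0, r * T)
        u_lo = lo / T
        u_hi = np.minimum(lo + 1, r * T) / T
        f_lo = f0 + beta * u_lo + alpha * u_lo * u_lo
        f_hi = f0 + beta * u_hi + alpha * u_hi * u_hi
        take_hi = f_hi < f_lo  # strict: ties keep the smaller m
        best_val = np.where(take_hi, f_hi, f_lo)
        best_u = np.where(take_hi, u_hi, u_lo)
    else:
        # degenerate axis (identical design columns): linear in u
        f_end = f0 + beta * r
        take_end = f_end < f0
        best_val = np.where(take_end, f_end, f0)
        best_u = np.where(take_end, r, 0.0)
    i = int(np.argmin(best_val))
    return np.concatenate([P[i], [best_u[i], r[i] - best_u[i]]])


def grid_oracle(
    y: np.ndarray, X: np.ndarray, mode: str = "equality", step: float = 0.01
) -> np.ndarray:
    """Exhaustive-grid minimiser of the constrained objective (verification oracle).

    Evaluates every feasible grid point at resolution ``step`` (equality:
    compositions of 1; inequality: grid points with sum <= 1, realised by
    adding a zero-design slack coordinate) and returns the objective-
    minimising proportion vector; ties go to the lexicographically
    smallest vector.  Restricted to N <= 4 populations.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n > 4:
        raise ValueError("grid oracle supports at most 4 populations")
    T = _steps(step)
    Xe = X if mode == "equality" else np.hstack([X, np.zeros((X.shape[0], 1))])
    ne = Xe.shape[1]
    G = Xe.T @ Xe
    c = Xe.T @ y
    n_points = comb(T + ne - 1, ne - 1)
    if ne >= 3 and n_points > _LITERAL_MAX:
        b = _grid_min_accelerated(G, c, T)
    else:
        b = _grid_min_literal(G, c, T)
    return b[:n]
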