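"""Non-negative PARAFAC (trilinear) decomposition with rank diagnostics.

The cube entry x[i,j,k] is modeled as sum_f a[i,f] b[j,f] c[k,f] with all
three factor blocks constrained non-negative: a holds relative fluorophore
concentrations (scores), b and c the emission and excitation spectra. Fitting
is alternating least squares with column-wise non-negative updates (HALS),
which leaves the objective non-increasing at every step. Rank is diagnosed
with the core consistency diagnostic (CORCONDIA) and explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eem import EEMCube
from .errors import ConfigError, DataError

__all__ = [
    "ParafacModel",
    "fit_parafac",
    "corcondia",
    "select_components",
    "congruence_match",
]


@dataclass
class ParafacModel:
    """Fitted trilinear model.

    Emission/excitation loading columns are scaled to unit maximum; the scale
    is carried by the scores, which therefore read as relative concentrations.
    """

    scores: np.ndarray        # samples x F
    em_loadings: np.ndarray   # emission x F
    ex_loadings: np.ndarray   # excitation x F
    n_components: int
    explained_variance: float
    corcondia: float | None
    converged: bool
    n_iter: int
    fit_history: list[float] = field(default_factory=list)
    seed: int | None = None

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "if,jf,kf->ijk", self.scores, self.em_loadings, self.ex_loadings
        )


def _as_array(cube) -> np.ndarray:
    if isinstance(cube, EEMCube):
        if cube.mask.any():
            raise DataError(
                "cube has missing values; run interpolate_missing first"
            )
        return cube.data
    X = np.asarray(cube, dtype=float)
    if X.ndim != 3:
        raise DataError("expected a 3-way array or EEMCube")
    return X


def _unfoldings(X: np.ndarray):
    n0, n1, n2 = X.shape
    return (
        X.reshape(n0, n1 * n2),                       # mode 0, (j,k) with k fastest
        X.transpose(1, 0, 2).reshape(n1, n0 * n2),    # mode 1, (i,k) with k fastest
        X.transpose(2, 0, 1).reshape(n2, n0 * n1),    # mode 2, (i,j) with j fastest
    )


def _khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker with the second factor's index fastest, matching
    the unfolding layout above."""
    F = U.shape[1]
    return np.einsum("if,jf->ijf", U, V).reshape(-1, F)


def _hals_update(
    factor: np.ndarray, M: np.ndarray, G: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One pass of column-wise non-negative least-squares updates.

    ``M = X_(n) Z`` and ``G = Z^T Z`` for the Khatri-Rao design ``Z``; each
    column update is the exact NNLS minimizer with the others held fixed.
    """
    A = factor
    for f in range(A.shape[1]):
        g = G[f, f]
        if g <= 1e-300:
            A[:, f] = rng.uniform(0.1, 1.0, size=A.shape[0])
            continue
        A[:, f] = np.maximum(0.0, A[:, f] + (M[:, f] - A @ G[:, f]) / g)
    return A


def _init_factors(X, F, mode_dims, kind, rng):
    if kind == "svd":
        factors = []
        for unf, d in zip(_unfoldings(X), mode_dims):
            r = min(F, min(unf.shape))
            U, _, _ = np.linalg.svd(unf, full_matrices=False)
            A = np.abs(U[:, :r])
            if r < F:
                A = np.hstack([A, rng.uniform(0.1, 1.0, size=(d, F - r))])
            factors.append(A)
        return factors
    return [rng.uniform(0.1, 1.0, size=(d, F)) for d in mode_dims]


def fit_parafac(
    cube,
    n_components: int,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    compute_corcondia: bool = True,
) -> ParafacModel:
    """Fit a non-negative trilinear model, keeping the best of ``n_starts``
    initializations (one SVD-based, the rest seeded random).

    Convergence: relative change of the fit (1 - relative residual) below
    ``tol``. Non-convergence is reported through ``converged``/``n_iter``,
    never raised.
    """
    X = _as_array(cube)
    F = int(n_components)
    if F < 1:
        raise ConfigError("n_components must be >= 1")
    if n_starts < 1:
        raise ConfigError("n_starts must be >= 1")
    norm_x = float(np.linalg.norm(X))
    if norm_x == 0:
        raise DataError("cannot fit an all-zero cube")
    unfs = _unfoldings(X)
    dims = X.shape

    best = None
    rng_master = np.random.default_rng(seed)
    for start in range(n_starts):
        rng = np.random.default_rng(rng_master.integers(2**31))
        factors = _init_factors(X, F, dims, "svd" if start == 0 else "random", rng)
        fit_prev = -np.inf
        history: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            for mode in range(3):
                others = [factors[m] for m in range(3) if m != mode]
                # design matrix follows the unfolding layout (last index fastest)
                Z = _khatri_rao(others[0], others[1])
                M = unfs[mode] @ Z
                G = (others[0].T @ others[0]) * (others[1].T @ others[1])
                factors[mode] = _hals_update(factors[mode], M, G, rng)
            # cheap SSE via the mode-2 quantities of the last update
            A = factors[2]
            sse = norm_x**2 - 2.0 * float(np.sum(A * M)) + float(
                np.sum((A.T @ A) * G)
            )
            sse = max(sse, 0.0)
            fit = 1.0 - np.sqrt(sse) / norm_x
            history.append(fit)
            if abs(fit - fit_prev) < tol:
                converged = True
                break
            fit_prev = fit
        if best is None or history[-1] > best[0]:
            best = (history[-1], [f.copy() for f in factors], converged, it, history)

    _, (A, B, C), converged, n_iter, history = best

    # unit-maximum spectral loadings, scale pushed into the scores
    for mat in (B, C):
        mx = mat.max(axis=0)
        mx[mx == 0] = 1.0
        A *= mx
        mat /= mx
    # deterministic component order: by score energy, descending
    order = np.argsort(-np.sum(A**2, axis=0), kind="stable")
    A, B, C = A[:, order], B[:, order], C[:, order]

    sse = float(np.linalg.norm(X - np.einsum("if,jf,kf->ijk", A, B, C)) ** 2)
    model = ParafacModel(
        scores=A,
        em_loadings=B,
        ex_loadings=C,
        n_components=F,
        explained_variance=100.0 * (1.0 - sse / norm_x**2),
        corcondia=None,
        converged=converged,
        n_iter=n_iter,
        fit_history=history,
        seed=seed,
    )
    if compute_corcondia:
        try:
            model.corcondia = corcondia(model, X)
        except DataError:
            # degenerate (e.g. vanished) component: core not identifiable
            model.corcondia = float("nan")
    return model


def corcondia(model: ParafacModel, cube) -> float:
    """Core consistency diagnostic (percent).

    Fits the least-squares Tucker core given the PARAFAC factors and measures
    its distance to the superidentity: 100 * (1 - sum((g - t)^2) / sum(t^2)).
    A one-component model scores 100 by construction (the optimal 1x1x1 core
    is unity at convergence).
    """
    X = _as_array(cube)
    F = model.n_components
    if F == 1:
        return 100.0
    factors = (model.scores, model.em_loadings, model.ex_loadings)
    for name, fac in zip(("score", "emission", "excitation"), factors):
        if np.linalg.matrix_rank(fac) < F:
            raise DataError(
                f"{name} factor matrix is rank-deficient; the Tucker core is "
                f"not identifiable — try fewer components"
            )
    pinvs = [np.linalg.pinv(f) for f in factors]
    core = np.einsum("ip,jq,kr,pqr->ijk", pinvs[0], pinvs[1], pinvs[2], X)
    target = np.zeros((F, F, F))
    idx = np.arange(F)
    target[idx, idx, idx] = 1.0
    return float(100.0 * (1.0 - np.sum((core - target) ** 2) / F))


def select_components(
    cube,
    f_range=range(1, 6),
    corcondia_threshold: float = 80.0,
    low_variance_threshold: float = 50.0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Scan component counts and pick the rank.

    Rule: the largest F whose CORCONDIA stays at or above the threshold
    (default 80) — a documented stand-in for visual inspection. If no F
    qualifies, the smallest F in the range is returned and, when its
    explained variance is below ``low_variance_threshold``, the diagnostics
    table flags it as low-variance (pure-noise-like data).
    """
    f_values = sorted(f_range)
    if not f_values:
        raise ConfigError("f_range must be non-empty")
    rows = []
    for F in f_values:
        m = fit_parafac(cube, F, **fit_kwargs)
        rows.append(
            {
                "n_components": F,
                "corcondia": m.corcondia,
                "explained_variance": m.explained_variance,
                "n_iter": m.n_iter,
                "converged": m.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("n_components")
    # NaN corcondia (degenerate over-factored fit) never qualifies
    ok = table.index[table["corcondia"] >= corcondia_threshold]
    chosen = int(ok.max()) if len(ok) else int(f_values[0])
    table["chosen"] = table.index == chosen
    table["low_variance_flag"] = (
        table["explained_variance"] < low_variance_threshold
    )
    return chosen, table


def congruence_match(
    estimated: tuple[np.ndarray, np.ndarray, np.ndarray],
    truth: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    """Greedy component matching by mean Tucker congruence across the three
    modes; returns the per-true-component congruence (order: truth columns).

    Comparison is invariant to permutation and positive scaling, which is all
    a trilinear model determines.
    """
    def cong(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 0.0
        return float(u @ v / (nu * nv))

    F = truth[0].shape[1]
    Fe = estimated[0].shape[1]
    table = np.zeros((F, Fe))
    for f in range(F):
        for g in range(Fe):
            table[f, g] = np.mean(
                [cong(truth[m][:, f], estimated[m][:, g]) for m in range(3)]
            )
    out = np.zeros(F)
    used: set[int] = set()
    for _ in range(min(F, Fe)):
        f, g = np.unravel_index(
            np.argmax(np.where(
                np.isin(np.arange(Fe), list(used))[None, :], -np.inf, table
            )),
            table.shape,
        )
        out[f] = table[f, g]
        used.add(int(g))
        table[f, :] = -np.inf
    return out
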