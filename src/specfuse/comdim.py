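"""ComDim / CCSWA multiblock decomposition and the multiblock one-class
classifier used for mid-level data fusion.

Each common dimension (CD) is the leading unit eigenvector of the
salience-weighted sum of the per-block sample cross-product matrices
W = sum_b lambda_b X_b X_b^T; the saliences lambda_b = ||X_b^T q||^2 are
iterated to a fixed point, every block is deflated by the CD and the process
repeats. The one-class classifier combines the score distance (Mahalanobis
distance in CD space, SD) and the orthogonal distance (residual sum of
squares after deflation, OD), each normalized by a 95% limit, into the same
reduced-distance rule as single-block SIMCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .simca import DEFAULT_THRESHOLD, confusion_metrics, optimize_threshold

__all__ = [
    "Block",
    "ComDimModel",
    "MultiblockOCC",
    "normalize_blocks",
    "apply_block_normalization",
    "fit_comdim",
    "explained_variance",
    "project",
    "fit_mb_occ",
    "occ_distance",
    "evaluate_occ",
]


@dataclass
class Block:
    """One data block (samples × variables) with its normalization record."""

    matrix: np.ndarray
    name: str = ""
    point_divisor: float | None = None
    frobenius_divisor: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataError(f"block {self.name!r} must be 2-D")


def normalize_blocks(blocks: list[Block]) -> list[Block]:
    """Two-stage block normalization, recorded for exact replay.

    Stage 1 divides every point of a block by the square root of the block's
    sum of squared values (its Frobenius norm); stage 2 re-divides by the
    Frobenius norm of the result so all blocks end with unit norm — and hence
    equal total variance — whatever their raw scale.
    """
    ns = {b.matrix.shape[0] for b in blocks}
    if len(ns) > 1:
        raise DataError(f"blocks disagree on the sample count: {sorted(ns)}")
    out = []
    for b in blocks:
        point = float(np.linalg.norm(b.matrix))
        if point <= 0:
            raise DataError(f"block {b.name!r} has zero norm")
        m = b.matrix / point
        frob = float(np.linalg.norm(m))
        m = m / frob
        out.append(
            Block(matrix=m, name=b.name, point_divisor=point,
                  frobenius_divisor=frob)
        )
    return out


def apply_block_normalization(matrix: np.ndarray, trained: Block) -> np.ndarray:
    """Normalize new-sample rows with a training block's stored divisors."""
    if trained.point_divisor is None or trained.frobenius_divisor is None:
        raise DataError(
            f"block {trained.name!r} carries no normalization record"
        )
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[None, :]
    if matrix.shape[1] != trained.matrix.shape[1]:
        raise DataError(
            f"block {trained.name!r}: variable count {matrix.shape[1]} does "
            f"not match training ({trained.matrix.shape[1]})"
        )
    return matrix / (trained.point_divisor * trained.frobenius_divisor)


@dataclass
class ComDimModel:
    global_scores: np.ndarray          # samples × K, unit columns
    saliences: np.ndarray              # blocks × K
    block_loadings: list[np.ndarray]   # per block: variables × K
    eigenvalues: np.ndarray            # K, of the weighted W at convergence
    explained_variance: np.ndarray     # % per CD, of the total block variance
    block_names: list[str]
    n_iter: np.ndarray
    converged: np.ndarray
    total_variance: float
    residual_blocks: list[np.ndarray] = field(default_factory=list)

    @property
    def n_cd(self) -> int:
        return self.global_scores.shape[1]

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance)

    def truncated(self, k: int) -> "ComDimModel":
        """First-k-CD model; valid because extraction is sequential."""
        if not 1 <= k <= self.n_cd:
            raise ConfigError(f"cannot truncate to {k} of {self.n_cd} CDs")
        return ComDimModel(
            global_scores=self.global_scores[:, :k],
            saliences=self.saliences[:, :k],
            block_loadings=[L[:, :k] for L in self.block_loadings],
            eigenvalues=self.eigenvalues[:k],
            explained_variance=self.explained_variance[:k],
            block_names=list(self.block_names),
            n_iter=self.n_iter[:k],
            converged=self.converged[:k],
            total_variance=self.total_variance,
            residual_blocks=[],  # residuals of the full model do not apply
        )


def fit_comdim(
    blocks: list[Block],
    n_cd: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> ComDimModel:
    """CCSWA extraction of ``n_cd`` common dimensions.

    Saliences start at 1 for every block; the leading-eigenvector sign is
    fixed by making the largest-magnitude score positive, so outputs are
    deterministic. Non-convergence of the salience iteration is flagged per
    CD, never raised.
    """
    if not blocks:
        raise ConfigError("at least one block required")
    n = blocks[0].matrix.shape[0]
    if n_cd >= n:
        raise ConfigError(f"n_cd={n_cd} must be smaller than n_samples={n}")
    Xs = [b.matrix.copy() for b in blocks]
    B = len(Xs)
    total_var = float(sum(np.sum(X**2) for X in Xs))

    scores = np.zeros((n, n_cd))
    sal = np.zeros((B, n_cd))
    loads = [np.zeros((X.shape[1], n_cd)) for X in Xs]
    eigs = np.zeros(n_cd)
    evs = np.zeros(n_cd)
    iters = np.zeros(n_cd, dtype=int)
    conv = np.zeros(n_cd, dtype=bool)

    for k in range(n_cd):
        lam = np.ones(B)
        crosses = [X @ X.T for X in Xs]
        q = None
        for it in range(1, max_iter + 1):
            W = sum(l * C for l, C in zip(lam, crosses))
            w, V = np.linalg.eigh(W)
            q = V[:, -1]
            if q[np.argmax(np.abs(q))] < 0:
                q = -q
            lam_new = np.array([float(q @ C @ q) for C in crosses])
            if np.max(np.abs(lam_new - lam)) < tol:
                lam = lam_new
                conv[k] = True
                iters[k] = it
                break
            lam = lam_new
            iters[k] = it
        eigs[k] = float(sum(l * (q @ C @ q) for l, C in zip(lam, crosses)))
        scores[:, k] = q
        sal[:, k] = lam
        removed = 0.0
        for b, X in enumerate(Xs):
            p = X.T @ q
            loads[b][:, k] = p
            removed += float(p @ p)
            Xs[b] = X - np.outer(q, p)
        evs[k] = 100.0 * removed / total_var

    return ComDimModel(
        global_scores=scores,
        saliences=sal,
        block_loadings=loads,
        eigenvalues=eigs,
        explained_variance=evs,
        block_names=[b.name for b in blocks],
        n_iter=iters,
        converged=conv,
        total_variance=total_var,
        residual_blocks=Xs,
    )


def explained_variance(model: ComDimModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-CD and cumulative percent of the total normalized block variance
    captured by the successive deflations."""
    return model.explained_variance, model.cumulative_variance


def project(
    model: ComDimModel, new_blocks: list[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Project new (already normalized) blocks through the training
    deflation path.

    For each CD, the score is the salience-weighted combination of the
    sample's block images on the stored loadings, scaled by the CD
    eigenvalue; each block is then deflated by the outer product of the new
    scores and the training loadings. Training rows projected through this
    path reproduce their training scores exactly.

    Returns ``(scores, residual_blocks)``.
    """
    if len(new_blocks) != len(model.block_loadings):
        raise DataError(
            f"expected {len(model.block_loadings)} blocks, got {len(new_blocks)}"
        )
    Xs = []
    for b, X in enumerate(new_blocks):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != model.block_loadings[b].shape[0]:
            raise DataError(
                f"block {model.block_names[b]!r}: variable count "
                f"{X.shape[1]} does not match training "
                f"({model.block_loadings[b].shape[0]})"
            )
        Xs.append(X.copy())
    n_new = Xs[0].shape[0]
    scores = np.zeros((n_new, model.n_cd))
    for k in range(model.n_cd):
        t = np.zeros(n_new)
        for b, X in enumerate(Xs):
            t += model.saliences[b, k] * (X @ model.block_loadings[b][:, k])
        t /= model.eigenvalues[k]
        scores[:, k] = t
        for b in range(len(Xs)):
            Xs[b] = Xs[b] - np.outer(t, model.block_loadings[b][:, k])
    return scores, Xs


# --------------------------------------------------------------------------
# multiblock one-class classifier
# --------------------------------------------------------------------------

@dataclass
class MultiblockOCC:
    comdim: ComDimModel
    trained_blocks: list[Block]         # normalization records for replay
    score_mean: np.ndarray
    score_cov_inv: np.ndarray
    sd_limit_95: float
    od_limit_95: float
    threshold: float = DEFAULT_THRESHOLD
    target_label: str | None = None
    od_mode: str = "concatenated"       # or "blockwise"


def _chi2_limit(values: np.ndarray, alpha: float = 0.95,
                method: str = "chi2") -> float:
    """95% limit of a positive statistic: moment-matched scaled chi-square
    (g*chi2_h) by default, empirical quantile as fallback/switch."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    var = float(values.var(ddof=1)) if values.size > 1 else 0.0
    if method == "quantile" or var <= 1e-12 * max(mean**2, 1e-300):
        return float(np.quantile(values, alpha)) or np.finfo(float).eps
    g = var / (2.0 * mean)
    h = 2.0 * mean**2 / var
    return float(g * stats.chi2.ppf(alpha, h))


def fit_mb_occ(
    blocks_target: list[Block],
    n_cd: int | None = None,
    ev_target: float = 90.0,
    target_label: str | None = None,
    limit_method: str = "chi2",
    od_mode: str = "concatenated",
    tol: float = 1e-10,
    max_iter: int = 500,
) -> MultiblockOCC:
    """Fit the ComDim-based one-class model on target-class blocks.

    ``n_cd=None`` keeps the smallest number of CDs whose cumulative explained
    variance reaches ``ev_target`` percent. SD is the Mahalanobis distance of
    a sample's CD-score vector to the target cloud; OD is the residual sum of
    squares after reconstruction from the retained CDs; 95% limits come from
    moment-matched scaled chi-square fits to the training distributions. The
    acceptance threshold starts at the sqrt(2) boundary; tune it with
    :func:`specfuse.simca.optimize_threshold` when non-target distances exist.
    """
    if od_mode not in ("concatenated", "blockwise"):
        raise ConfigError(f"unknown od_mode {od_mode!r}")
    if any(b.point_divisor is None for b in blocks_target):
        blocks_target = normalize_blocks(blocks_target)
    n = blocks_target[0].matrix.shape[0]
    if n_cd is not None and n_cd >= n:
        raise ConfigError(
            f"n_cd={n_cd} must be smaller than the target sample count {n}"
        )
    k_fit = n_cd if n_cd is not None else min(n - 1, 10)
    model = fit_comdim(blocks_target, k_fit, tol=tol, max_iter=max_iter)
    if n_cd is None:
        cum = model.cumulative_variance
        k = int(np.searchsorted(cum, ev_target) + 1)
        k = min(k, model.n_cd)
        full = model
        model = model.truncated(k)
        # recompute residuals for the truncated depth via projection
        _, residuals = project(model, [b.matrix for b in blocks_target])
        model.residual_blocks = residuals
        del full

    T = model.global_scores
    mean = T.mean(axis=0)
    cov = np.cov(T, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov_inv = np.linalg.pinv(cov)
    sd2 = np.einsum("ij,jk,ik->i", T - mean, cov_inv, T - mean)
    od = _od_from_residuals(model.residual_blocks, od_mode)

    return MultiblockOCC(
        comdim=model,
        trained_blocks=list(blocks_target),
        score_mean=mean,
        score_cov_inv=cov_inv,
        sd_limit_95=math.sqrt(_chi2_limit(sd2, method=limit_method)),
        od_limit_95=_chi2_limit(od, method=limit_method),
        target_label=target_label,
        od_mode=od_mode,
    )


def _od_from_residuals(residuals: list[np.ndarray], od_mode: str) -> np.ndarray:
    if od_mode == "blockwise":
        # per-block mean squared residual, summed: each block weighted by
        # its variable count instead of raw concatenation
        return sum(
            np.sum(R**2, axis=1) / R.shape[1] for R in residuals
        )
    return sum(np.sum(R**2, axis=1) for R in residuals)


def occ_distance(occ: MultiblockOCC, new_blocks: list[np.ndarray]) -> np.ndarray:
    """Reduced distance of new samples (raw block rows) from the target
    model: blocks are normalized with the training divisors, projected, and
    d = sqrt((SD/sd95)^2 + (OD/od95)^2)."""
    normalized = [
        apply_block_normalization(X, b)
        for X, b in zip(new_blocks, occ.trained_blocks)
    ]
    T, residuals = project(occ.comdim, normalized)
    sd2 = np.einsum(
        "ij,jk,ik->i", T - occ.score_mean, occ.score_cov_inv, T - occ.score_mean
    )
    sd = np.sqrt(np.maximum(sd2, 0.0))
    od = _od_from_residuals(residuals, occ.od_mode)
    return np.sqrt((sd / occ.sd_limit_95) ** 2 + (od / occ.od_limit_95) ** 2)


def occ_loo_distances(
    raw_blocks_target: list[np.ndarray],
    n_cd: int | None = None,
    **fit_kwargs,
) -> np.ndarray:
    """Leave-one-out reduced distances of target rows from the multiblock
    model refit without them; use these to tune the acceptance threshold."""
    n = np.asarray(raw_blocks_target[0]).shape[0]
    out = np.empty(n)
    for i in range(n):
        train = [
            Block(np.delete(np.asarray(X, dtype=float), i, axis=0), name=str(b))
            for b, X in enumerate(raw_blocks_target)
        ]
        occ = fit_mb_occ(train, n_cd=n_cd, **fit_kwargs)
        held = [np.asarray(X, dtype=float)[i] for X in raw_blocks_target]
        out[i] = occ_distance(occ, held)[0]
    return out


def evaluate_occ(
    occ: MultiblockOCC, new_blocks: list[np.ndarray], labels: np.ndarray
):
    """Confusion metrics of the one-class decision on new samples."""
    if occ.target_label is None:
        raise ConfigError("model has no target_label to evaluate against")
    d = occ_distance(occ, new_blocks)
    return confusion_metrics(d <= occ.threshold, np.asarray(labels) == occ.target_label)
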