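"""One-class SIMCA modeling.

Each target class gets its own PCA model; membership is decided by a reduced
distance combining the Q residual (distance from the PCA subspace) and the
Hotelling T^2 (leverage within it), each normalized by its 95% confidence
limit: d = sqrt((Q/Q95)^2 + (T2/T95)^2), accept iff d <= threshold. The
threshold defaults to the sqrt(2) boundary and can be tuned to maximize
sensitivity + specificity against a non-target distance set. Also here:
leave-one-out component selection (RMSECV + sensitivity), the duplex
calibration/test split with replicate grouping, a leverage/Q outlier screen,
and confusion-matrix metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .errors import ConfigError, DataError

__all__ = [
    "PCAModel",
    "SIMCAModel",
    "ClassificationMetrics",
    "fit_simca",
    "q_statistic",
    "t2_statistic",
    "reduced_distance",
    "optimize_threshold",
    "select_n_components",
    "duplex_split",
    "screen_outliers",
    "evaluate",
    "confusion_metrics",
]

DEFAULT_THRESHOLD = math.sqrt(2.0)


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray       # variables x A, orthonormal columns
    eigenvalues: np.ndarray    # retained A eigenvalues, non-increasing
    residual_eigenvalues: np.ndarray
    n_components: int
    n_train: int


@dataclass
class SIMCAModel:
    pca: PCAModel
    q_limit_95: float
    t2_limit_95: float
    threshold: float = DEFAULT_THRESHOLD
    target_label: str | None = None
    distance_form: str = "euclid"   # or "sum"


@dataclass
class ClassificationMetrics:
    """Confusion counts and the derived percentages; an empty class leaves
    the corresponding rate undefined (NaN), never zero."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else float("nan")

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


# --------------------------------------------------------------------------
# model fitting and distances
# --------------------------------------------------------------------------

def _pca(X: np.ndarray, A: int) -> PCAModel:
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if A > rank:
        raise DataError(
            f"n_components={A} exceeds the data rank ({rank})"
        )
    return PCAModel(
        mean=mean,
        loadings=Vt[:A].T,
        eigenvalues=eig[:A],
        residual_eigenvalues=eig[A:rank],
        n_components=A,
        n_train=n,
    )


def _q_limit_jackson_mudholkar(
    residual_eig: np.ndarray, alpha=0.95, scale: float = 1.0
) -> float:
    """Closed-form Q residual confidence limit from the residual eigenvalues.

    When the residual spectrum is empty or numerically zero (data lying in an
    exact A-dimensional subspace) a small positive limit — machine epsilon at
    the data's variance scale — is returned so numerically-zero Q values are
    always accepted.
    """
    th1 = float(np.sum(residual_eig))
    th2 = float(np.sum(residual_eig**2))
    th3 = float(np.sum(residual_eig**3))
    floor = max(scale, np.finfo(float).tiny) * np.finfo(float).eps
    if th1 <= floor or th2 <= 0:
        return floor
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        h0 = np.finfo(float).eps
    z = stats.norm.ppf(alpha)
    term = (
        z * np.sqrt(2.0 * th2 * h0**2) / th1
        + 1.0
        + th2 * h0 * (h0 - 1.0) / th1**2
    )
    if term <= 0:
        return th1 * np.finfo(float).eps
    return float(th1 * term ** (1.0 / h0))


def _t2_limit(n: int, A: int, alpha=0.95) -> float:
    return float(A * (n - 1) / (n - A) * stats.f.ppf(alpha, A, n - A))


def fit_simca(
    X_target: np.ndarray,
    n_components: int,
    target_label: str | None = None,
    distance_form: str = "euclid",
) -> SIMCAModel:
    """Fit the one-class model on target-class rows only.

    The data are centered internally on the target-class means; the Q limit
    uses the residual-eigenvalue closed form, the T^2 limit the F
    distribution, both at 95%.
    """
    X = np.asarray(X_target, dtype=float)
    A = int(n_components)
    if X.ndim != 2:
        raise DataError("X_target must be 2-D")
    if X.shape[0] < A + 2:
        raise DataError(
            f"need at least A+2={A + 2} rows to fit SIMCA, got {X.shape[0]}"
        )
    if distance_form not in ("euclid", "sum"):
        raise ConfigError(f"unknown distance_form {distance_form!r}")
    pca = _pca(X, A)
    return SIMCAModel(
        pca=pca,
        q_limit_95=_q_limit_jackson_mudholkar(
            pca.residual_eigenvalues, scale=float(np.sum(pca.eigenvalues))
        ),
        t2_limit_95=_t2_limit(pca.n_train, A),
        target_label=target_label,
        distance_form=distance_form,
    )


def _check_vars(model: SIMCAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.pca.mean.size:
        raise DataError(
            f"variable count {X.shape[1]} does not match the model "
            f"({model.pca.mean.size})"
        )
    return X


def q_statistic(model: SIMCAModel, X: np.ndarray) -> np.ndarray:
    X = _check_vars(model, X)
    Xc = X - model.pca.mean
    T = Xc @ model.pca.loadings
    resid = Xc - T @ model.pca.loadings.T
    return np.sum(resid**2, axis=1)


def t2_statistic(model: SIMCAModel, X: np.ndarray) -> np.ndarray:
    X = _check_vars(model, X)
    Xc = X - model.pca.mean
    T = Xc @ model.pca.loadings
    lam = np.where(model.pca.eigenvalues > 0, model.pca.eigenvalues, np.inf)
    return np.sum(T**2 / lam, axis=1)


def reduced_distance(model: SIMCAModel, X: np.ndarray) -> np.ndarray:
    """Distance of each sample from the class model; accept iff
    d <= model.threshold."""
    q = q_statistic(model, X) / model.q_limit_95
    t2 = t2_statistic(model, X) / model.t2_limit_95
    if model.distance_form == "sum":
        return q + t2
    return np.sqrt(q**2 + t2**2)


# --------------------------------------------------------------------------
# threshold tuning
# --------------------------------------------------------------------------

def optimize_threshold(
    d_target: np.ndarray, d_nontarget: np.ndarray
) -> float:
    """Pick the acceptance threshold maximizing sensitivity + specificity.

    Candidates are the midpoints between adjacent sorted distances plus one
    value below and one above everything; ties go to the candidate with
    higher sensitivity, then to the smaller threshold.
    """
    dt = np.asarray(d_target, dtype=float)
    dn = np.asarray(d_nontarget, dtype=float)
    if dt.size == 0 or dn.size == 0:
        raise DataError("both distance sets must be non-empty")
    merged = np.unique(np.concatenate([dt, dn]))
    mids = (merged[:-1] + merged[1:]) / 2.0 if merged.size > 1 else np.empty(0)
    candidates = np.concatenate(
        [[merged[0] - 1.0 if merged[0] > 1.0 else merged[0] / 2.0],
         mids, [merged[-1] + 1.0]]
    )
    best = None
    for thr in candidates:
        sens = float(np.mean(dt <= thr))
        spec = float(np.mean(dn > thr))
        key = (sens + spec, sens, -thr)
        if best is None or key > best[0]:
            best = (key, float(thr))
    return best[1]


def loo_distances(
    X_target: np.ndarray,
    n_components: int,
    distance_form: str = "euclid",
) -> np.ndarray:
    """Leave-one-out reduced distances of target samples from their own
    class model — the honest distance distribution to tune thresholds on
    (resubstitution distances are optimistically small)."""
    X = np.asarray(X_target, dtype=float)
    n = X.shape[0]
    if n < n_components + 3:
        raise DataError(
            f"need at least A+3={n_components + 3} rows for LOO distances"
        )
    out = np.empty(n)
    for i in range(n):
        model = fit_simca(
            np.delete(X, i, axis=0), n_components, distance_form=distance_form
        )
        out[i] = reduced_distance(model, X[i])[0]
    return out


# --------------------------------------------------------------------------
# component selection
# --------------------------------------------------------------------------

def select_n_components(
    X_target: np.ndarray,
    a_range=range(1, 6),
    threshold: float = DEFAULT_THRESHOLD,
    rmsecv_band: float = 0.01,
):
    """Leave-one-out selection of the PCA size.

    For each candidate A the LOO reconstruction RMSECV and the LOO sensitivity
    (fraction of held-out target samples accepted at the default boundary) are
    computed; the chosen A is the smallest one whose RMSECV lies within
    ``rmsecv_band`` (relative) of the minimum, with exact RMSECV ties broken
    toward the higher LOO sensitivity.

    Returns ``(A, table)`` with the per-A diagnostics.
    """
    X = np.asarray(X_target, dtype=float)
    a_values = sorted(a_range)
    n, p = X.shape
    if n < max(a_values) + 2:
        raise DataError(
            f"need at least max(A)+2={max(a_values) + 2} rows, got {n}"
        )
    press = {A: 0.0 for A in a_values}
    accepted = {A: 0 for A in a_values}
    for i in range(n):
        train = np.delete(X, i, axis=0)
        mean = train.mean(axis=0)
        Tc = train - mean
        _, s, Vt = np.linalg.svd(Tc, full_matrices=False)
        eig = s**2 / (train.shape[0] - 1)
        xc = X[i] - mean
        for A in a_values:
            P = Vt[:A].T
            t = xc @ P
            resid = xc - P @ t
            press[A] += float(resid @ resid)
            # acceptance of the held-out sample at the default boundary
            q = float(resid @ resid)
            lam = eig[:A]
            t2 = float(np.sum(t**2 / np.where(lam > 0, lam, np.inf)))
            qlim = _q_limit_jackson_mudholkar(eig[A:])
            tlim = _t2_limit(train.shape[0], A)
            d = math.sqrt((q / qlim) ** 2 + (t2 / tlim) ** 2)
            if d <= threshold:
                accepted[A] += 1

    import pandas as pd

    table = pd.DataFrame(
        {
            "rmsecv": [math.sqrt(press[A] / (n * p)) for A in a_values],
            "loo_sensitivity": [100.0 * accepted[A] / n for A in a_values],
        },
        index=pd.Index(a_values, name="n_components"),
    )
    rmin = table["rmsecv"].min()
    # absolute floor keeps machine-zero curves (exact low-rank data) tied
    floor = 1e-12 * math.sqrt(float(np.mean(X**2)))
    band = table.index[table["rmsecv"] <= rmin * (1.0 + rmsecv_band) + floor]
    chosen = int(band.min())
    # exact RMSECV ties at the chosen value: prefer higher LOO sensitivity
    tied = table.index[
        np.isclose(table["rmsecv"], table.loc[chosen, "rmsecv"], rtol=1e-12)
    ]
    if len(tied) > 1:
        chosen = int(table.loc[tied, "loo_sensitivity"].idxmax())
    table["chosen"] = table.index == chosen
    return chosen, table


# --------------------------------------------------------------------------
# duplex split
# --------------------------------------------------------------------------

def duplex_split(
    X: np.ndarray,
    ratio: float = 0.8,
    groups: list | np.ndarray | None = None,
):
    """Deterministic duplex calibration/test split.

    Works on Euclidean distances of the centered data: the two mutually
    farthest remaining points seed the calibration set, the next farthest
    pair the test set, alternating until the test set reaches
    ceil((1-ratio)*n); the remainder goes to calibration. With ``groups``
    (e.g. replicate ids of the same physical sample) whole groups move
    together — group distances use group centroids — so replicates never
    straddle the split.

    Returns ``(calibration_indices, test_indices)`` as sorted arrays.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise DataError(f"duplex needs at least 5 samples, got {n}")
    if not 0.0 < ratio < 1.0:
        raise ConfigError(f"ratio must be in (0, 1), got {ratio}")
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)
    if groups.shape != (n,):
        raise DataError("groups must have one entry per row")

    uniq, inv = np.unique(groups, return_inverse=True)
    centroids = np.vstack(
        [X[inv == g].mean(axis=0) for g in range(len(uniq))]
    )
    centroids = centroids - centroids.mean(axis=0)
    D = squareform(pdist(centroids)) if len(uniq) > 1 else np.zeros((1, 1))

    test_target = math.ceil((1.0 - ratio) * n)
    remaining = list(range(len(uniq)))
    cal_groups: list[int] = []
    test_groups: list[int] = []
    test_rows = 0
    turn = 0  # 0 -> calibration, 1 -> test
    while remaining and test_rows < test_target:
        if len(remaining) == 1:
            pair = (remaining[0],)
        else:
            # farthest remaining pair, lexicographic tie-break
            best = None
            for ai in range(len(remaining)):
                for bi in range(ai + 1, len(remaining)):
                    a, b = remaining[ai], remaining[bi]
                    key = (D[a, b], -a, -b)
                    if best is None or key > best[0]:
                        best = (key, (a, b))
            pair = best[1]
        if turn == 0:
            cal_groups.extend(pair)
        else:
            test_groups.extend(pair)
            test_rows += sum(int(np.sum(inv == g)) for g in pair)
        for g in pair:
            remaining.remove(g)
        turn = 1 - turn
    cal_groups.extend(remaining)

    cal_idx = np.sort(np.concatenate(
        [np.where(inv == g)[0] for g in cal_groups]
    )) if cal_groups else np.empty(0, dtype=int)
    test_idx = np.sort(np.concatenate(
        [np.where(inv == g)[0] for g in test_groups]
    )) if test_groups else np.empty(0, dtype=int)
    return cal_idx, test_idx


# --------------------------------------------------------------------------
# outlier screening
# --------------------------------------------------------------------------

def screen_outliers(
    X: np.ndarray,
    n_components: int | None = None,
    leverage_factor: float = 3.0,
):
    """Flag candidate outliers on an all-data PCA by leverage and Q residual.

    A sample is flagged when its leverage exceeds ``leverage_factor*(A+1)/n``
    or its Q residual exceeds the 95% closed-form limit. Nothing is removed:
    the caller decides. Returns ``(flagged_indices, table)``.
    """
    import pandas as pd

    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components is None:
        # components covering 95% of the variance, capped to keep residuals
        mean = X.mean(axis=0)
        _, s, _ = np.linalg.svd(X - mean, full_matrices=False)
        ev = np.cumsum(s**2) / np.sum(s**2) if np.sum(s**2) > 0 else np.ones_like(s)
        n_components = int(np.searchsorted(ev, 0.95) + 1)
        n_components = max(1, min(n_components, n - 2, p))
    A = n_components
    pca = _pca(X, A)
    Xc = X - pca.mean
    T = Xc @ pca.loadings
    lam = np.where(pca.eigenvalues > 0, pca.eigenvalues, np.inf)
    leverage = 1.0 / n + np.sum(T**2 / lam, axis=1) / (n - 1)
    resid = Xc - T @ pca.loadings.T
    q = np.sum(resid**2, axis=1)
    q_lim = _q_limit_jackson_mudholkar(pca.residual_eigenvalues)
    lev_lim = leverage_factor * (A + 1) / n
    flagged = np.where((leverage > lev_lim) | (q > q_lim))[0]
    table = pd.DataFrame(
        {
            "leverage": leverage,
            "leverage_limit": lev_lim,
            "q_residual": q,
            "q_limit_95": q_lim,
            "flagged": (leverage > lev_lim) | (q > q_lim),
        }
    )
    return flagged, table


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def confusion_metrics(accepted: np.ndarray, is_target: np.ndarray) -> ClassificationMetrics:
    accepted = np.asarray(accepted, dtype=bool)
    is_target = np.asarray(is_target, dtype=bool)
    if accepted.shape != is_target.shape:
        raise DataError("accepted and is_target must align")
    return ClassificationMetrics(
        tp=int(np.sum(accepted & is_target)),
        fn=int(np.sum(~accepted & is_target)),
        tn=int(np.sum(~accepted & ~is_target)),
        fp=int(np.sum(accepted & ~is_target)),
    )


def evaluate(
    model: SIMCAModel, X: np.ndarray, labels: np.ndarray
) -> ClassificationMetrics:
    """Accept/reject every row and tally the confusion counts against the
    model's target label."""
    labels = np.asarray(labels)
    if model.target_label is None:
        raise ConfigError("model has no target_label to evaluate against")
    d = reduced_distance(model, X)
    return confusion_metrics(d <= model.threshold, labels == model.target_label)
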