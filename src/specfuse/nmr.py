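"""NMR spectral bucketing and normalization.

Converts processed 1-D proton spectra into the sample × bucket matrix used by
the classification models: fixed-width buckets (default 0.04 ppm over
0.50-10.00 ppm) integrated by the trapezoidal rule, solvent regions
(water 4.50-5.20 ppm, methanol 3.28-3.40 ppm) excluded by whole-bucket
removal, and every row normalized to its total intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigError, DataError

__all__ = [
    "Spectrum",
    "BucketTable",
    "DEFAULT_EXCLUSIONS",
    "bucket",
    "normalize_total",
    "mean_center",
]

#: solvent residual regions excluded from the bucket table (ppm intervals)
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = ((4.50, 5.20), (3.28, 3.40))


@dataclass
class Spectrum:
    """A processed 1-D spectrum: strictly increasing ppm axis + intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise DataError(
                f"{self.row_id}: ppm and intensity must be equal-length 1-D arrays"
            )
        d = np.diff(self.ppm)
        if np.any(d <= 0):
            raise DataError(f"{self.row_id}: ppm axis must be strictly increasing")

    @property
    def row_id(self) -> str:
        return f"{self.sample_id}:{self.replicate_id}"


@dataclass
class BucketTable:
    """Sample × bucket matrix with the retained bucket intervals."""

    matrix: np.ndarray                       # (n_rows, n_buckets)
    bucket_edges: np.ndarray                 # (n_buckets, 2) ppm intervals
    excluded_regions: tuple[tuple[float, float], ...]
    row_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.bucket_edges = np.asarray(self.bucket_edges, dtype=float)
        if self.matrix.shape != (len(self.row_ids), len(self.bucket_edges)):
            raise DataError("bucket matrix shape does not match ids/edges")

    @property
    def bucket_centers(self) -> np.ndarray:
        return self.bucket_edges.mean(axis=1)

    @property
    def frame(self) -> pd.DataFrame:
        """DataFrame view, columns labeled by bucket-center ppm to 3 decimals."""
        return pd.DataFrame(
            self.matrix,
            index=self.row_ids,
            columns=[f"{c:.3f}" for c in self.bucket_centers],
        )


def _bucket_edges(lo: float, hi: float, width: float) -> np.ndarray:
    """Left-closed right-open intervals anchored at ``lo``; a trailing
    partial bucket (narrower than ``width``) is dropped."""
    n = int(np.floor((hi - lo) / width + 1e-9))
    left = lo + width * np.arange(n)
    return np.column_stack([left, left + width])


def _intersects(a: float, b: float, c: float, d: float) -> bool:
    """Does the bucket [a, b) overlap the closed exclusion [c, d]?"""
    return a < d and b > c


def bucket(
    spectra: list[Spectrum],
    width: float = 0.04,
    ppm_range: tuple[float, float] = (0.50, 10.00),
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
) -> BucketTable:
    """Integrate each spectrum over fixed-width ppm buckets.

    Bucket values are trapezoidal integrals of the intensity over each
    interval; any bucket whose interval intersects an exclusion region is
    dropped entirely, so excluded signal never leaks into a retained bucket.
    """
    if width <= 0:
        raise ConfigError(f"bucket width must be > 0, got {width}")
    lo, hi = ppm_range
    if hi <= lo:
        raise ConfigError(f"invalid ppm range {ppm_range}")

    edges = _bucket_edges(lo, hi, width)
    keep = np.array(
        [
            not any(_intersects(a, b, c, d) for (c, d) in exclusions)
            for a, b in edges
        ]
    )
    kept_edges = edges[keep]

    rows = []
    ids = []
    for sp in spectra:
        if sp.ppm[0] > lo + 1e-12 or sp.ppm[-1] < hi - 1e-12:
            raise DataError(
                f"{sp.row_id}: spectrum covers [{sp.ppm[0]:g}, {sp.ppm[-1]:g}] ppm "
                f"but buckets need [{lo:g}, {hi:g}]"
            )
        # cumulative trapezoidal integral lets every bucket be an exact
        # difference of interpolated antiderivative values
        F = np.concatenate([[0.0], cumulative_trapezoid(sp.intensity, sp.ppm)])
        right = np.interp(kept_edges[:, 1], sp.ppm, F)
        left = np.interp(kept_edges[:, 0], sp.ppm, F)
        rows.append(right - left)
        ids.append(sp.row_id)

    return BucketTable(
        matrix=np.vstack(rows),
        bucket_edges=kept_edges,
        excluded_regions=tuple(tuple(e) for e in exclusions),
        row_ids=ids,
    )


def normalize_total(table: BucketTable) -> BucketTable:
    """Divide each row by its own total over the retained buckets."""
    totals = table.matrix.sum(axis=1)
    bad = np.where(totals <= 0)[0]
    if bad.size:
        raise DataError(
            "non-positive total intensity for sample(s): "
            + ", ".join(table.row_ids[i] for i in bad)
        )
    return replace(table, matrix=table.matrix / totals[:, None], normalized=True)


def mean_center(
    matrix: np.ndarray, reference_means: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a matrix; with ``reference_means`` (test-set projection)
    those means are subtracted instead of the matrix's own.

    Returns ``(centered, means_used)``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise DataError("cannot center an empty matrix")
    if reference_means is None:
        means = X.mean(axis=0)
    else:
        means = np.asarray(reference_means, dtype=float)
        if means.shape != (X.shape[1],):
            raise DataError(
                f"reference_means length {means.shape} does not match "
                f"{X.shape[1]} columns"
            )
    return X - means, means
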