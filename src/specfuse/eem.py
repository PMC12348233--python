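"""Excitation-emission matrix (EEM) preprocessing.

Blank subtraction, Rayleigh/Raman scatter masking, shape-preserving
interpolation of the masked points, unit-variance sample-mode normalization,
cube unfolding/refolding and region cropping. The cube layout is fixed as
samples × emission × excitation; the unfolding bijection runs the emission
index fastest and every refold uses the same constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ConfigError, DataError

__all__ = [
    "EEMCube",
    "RegionSpec",
    "ScatterBands",
    "subtract_blank",
    "remove_scatter",
    "interpolate_missing",
    "normalize_sample_variance",
    "unfold",
    "refold",
    "crop_region",
]

log = logging.getLogger(__name__)


@dataclass
class EEMCube:
    """Sample × emission × excitation intensity cube with a missing mask."""

    data: np.ndarray
    em_axis: np.ndarray
    ex_axis: np.ndarray
    sample_ids: list[str] = None  # type: ignore[assignment]
    mask: np.ndarray = None       # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.em_axis = np.asarray(self.em_axis, dtype=float)
        self.ex_axis = np.asarray(self.ex_axis, dtype=float)
        if self.data.ndim != 3:
            raise DataError("cube must be samples x emission x excitation")
        n, n_em, n_ex = self.data.shape
        if n_em != self.em_axis.size or n_ex != self.ex_axis.size:
            raise DataError(
                f"cube shape {self.data.shape} does not match axes "
                f"({self.em_axis.size} em, {self.ex_axis.size} ex)"
            )
        for name, ax in (("emission", self.em_axis), ("excitation", self.ex_axis)):
            if np.any(np.diff(ax) <= 0):
                raise DataError(f"{name} axis must be strictly increasing")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:03d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length does not match the cube")
        if self.mask is None:
            self.mask = np.zeros_like(self.data, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise DataError("mask shape does not match the cube")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EEMCube":
        return EEMCube(
            data=self.data.copy(),
            em_axis=self.em_axis.copy(),
            ex_axis=self.ex_axis.copy(),
            sample_ids=list(self.sample_ids),
            mask=self.mask.copy(),
        )


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular excitation/emission window, e.g. the polyphenol Region B
    of leaf EEMs (excitation 250-400 nm, emission 370-530 nm)."""

    ex_range: tuple[float, float]
    em_range: tuple[float, float]
    name: str = ""


#: Region A (chlorophyll/pheophytin) and Region B (polyphenols, vitamins)
#: of the leaf EEM landscape.
LEAF_REGION_A = RegionSpec((300.0, 700.0), (650.0, 750.0), "Region A")
LEAF_REGION_B = RegionSpec((250.0, 400.0), (370.0, 530.0), "Region B")


@dataclass(frozen=True)
class ScatterBands:
    """Half-bandwidths (nm) of the scatter ridges to mask.

    Values are typical of EEM scatter-handling practice; the Raman band sits
    at a fixed Stokes shift (default 3400 cm^-1, water-like) from the
    excitation line.
    """

    rayleigh1: float = 10.0
    rayleigh2: float = 15.0
    raman: float = 10.0
    raman_shift_cm: float = 3400.0
    mask_below_rayleigh: bool = True

    def __post_init__(self) -> None:
        if min(self.rayleigh1, self.rayleigh2, self.raman) < 0:
            raise ConfigError("scatter bandwidths must be >= 0")


def subtract_blank(
    cube: EEMCube,
    blank: np.ndarray,
    em_axis: np.ndarray | None = None,
    ex_axis: np.ndarray | None = None,
) -> EEMCube:
    """Subtract a blank EEM (solvent-only landscape) from every sample."""
    blank = np.asarray(blank, dtype=float)
    if em_axis is not None and not np.array_equal(np.asarray(em_axis), cube.em_axis):
        raise DataError(
            f"blank emission axis differs from the cube's: "
            f"{np.asarray(em_axis)[:3]}... vs {cube.em_axis[:3]}..."
        )
    if ex_axis is not None and not np.array_equal(np.asarray(ex_axis), cube.ex_axis):
        raise DataError(
            f"blank excitation axis differs from the cube's: "
            f"{np.asarray(ex_axis)[:3]}... vs {cube.ex_axis[:3]}..."
        )
    if blank.shape != cube.data.shape[1:]:
        raise DataError(
            f"blank grid {blank.shape} does not match the cube grid "
            f"{cube.data.shape[1:]}"
        )
    out = cube.copy()
    out.data = out.data - blank[None, :, :]
    return out


def _scatter_mask(
    em_axis: np.ndarray, ex_axis: np.ndarray, bands: ScatterBands
) -> np.ndarray:
    em, ex = np.meshgrid(em_axis, ex_axis, indexing="ij")
    m = np.abs(em - ex) <= bands.rayleigh1
    m |= np.abs(em - 2.0 * ex) <= bands.rayleigh2
    raman_em = 1.0 / (1.0 / ex - bands.raman_shift_cm * 1e-7)
    m |= np.abs(em - raman_em) <= bands.raman
    if bands.mask_below_rayleigh:
        m |= em < ex
    return m


def remove_scatter(cube: EEMCube, bands: ScatterBands = ScatterBands()) -> EEMCube:
    """Flag first/second-order Rayleigh and Raman ridges as missing.

    Values are left in place; only the mask is set. The physically
    meaningless region below the first-order Rayleigh line (emission shorter
    than excitation) is flagged too unless disabled.
    """
    out = cube.copy()
    out.mask |= _scatter_mask(cube.em_axis, cube.ex_axis, bands)[None, :, :]
    return out


def interpolate_missing(
    cube: EEMCube, below_rayleigh: str = "zero"
) -> EEMCube:
    """Replace masked values by shape-preserving (PCHIP) interpolation along
    the emission mode within each excitation column, per sample.

    The below-Rayleigh region (emission < excitation) is set to zero rather
    than interpolated when ``below_rayleigh="zero"`` (the default); pass
    ``"interpolate"`` to treat it like any other gap. Interpolated values are
    clipped at zero and the mask is cleared. An excitation column with fewer
    than two observed points is left missing and reported in the log.
    """
    if below_rayleigh not in ("zero", "interpolate"):
        raise ConfigError(f"unknown below_rayleigh mode {below_rayleigh!r}")
    out = cube.copy()
    em = out.em_axis
    below = em[:, None] < out.ex_axis[None, :]  # (n_em, n_ex)
    unresolved: list[tuple[str, float]] = []
    for i in range(out.n_samples):
        for k in range(out.ex_axis.size):
            col_mask = out.mask[i, :, k].copy()
            if below_rayleigh == "zero":
                zero_here = below[:, k] & col_mask
                out.data[i, zero_here, k] = 0.0
                col_mask &= ~zero_here
            if not col_mask.any():
                out.mask[i, :, k] = False
                continue
            # zero-filled points anchor the interpolation as known values
            known = ~col_mask
            if known.sum() < 2:
                unresolved.append((out.sample_ids[i], float(out.ex_axis[k])))
                continue
            interp = PchipInterpolator(em[known], out.data[i, known, k],
                                       extrapolate=False)
            vals = interp(em[col_mask])
            # constant extrapolation beyond the observed hull
            lo, hi = em[known][0], em[known][-1]
            vals = np.where(em[col_mask] < lo, out.data[i, known, k][0], vals)
            vals = np.where(em[col_mask] > hi, out.data[i, known, k][-1], vals)
            out.data[i, col_mask, k] = np.clip(vals, 0.0, None)
            out.mask[i, :, k] = False
    if unresolved:
        log.warning(
            "interpolate_missing: %d fully masked excitation column(s) left "
            "missing: %s", len(unresolved), unresolved[:10],
        )
    return out


def normalize_sample_variance(cube: EEMCube) -> EEMCube:
    """Scale every sample slab to unit variance over its own entries."""
    out = cube.copy()
    for i in range(out.n_samples):
        sd = float(np.std(out.data[i]))
        if sd <= 0:
            raise DataError(
                f"sample {out.sample_ids[i]} has zero variance; cannot normalize"
            )
        out.data[i] = out.data[i] / sd
    return out


def unfold(cube: EEMCube) -> np.ndarray:
    """Unfold the cube to samples × (emission … excitation).

    Fixed bijection: the emission index varies fastest, i.e. column
    ``j + k * n_em`` holds (emission j, excitation k).
    """
    n = cube.n_samples
    return cube.data.transpose(0, 2, 1).reshape(n, -1)


def refold(
    vector: np.ndarray, em_axis: np.ndarray, ex_axis: np.ndarray
) -> np.ndarray:
    """Inverse of :func:`unfold` for a single unfolded row (e.g. a loading
    vector), returning an emission × excitation matrix."""
    vector = np.asarray(vector, dtype=float)
    n_em, n_ex = len(em_axis), len(ex_axis)
    if vector.size != n_em * n_ex:
        raise DataError(
            f"vector length {vector.size} != {n_em} emission x {n_ex} excitation"
        )
    return vector.reshape(n_ex, n_em).T


def crop_region(cube: EEMCube, region: RegionSpec) -> EEMCube:
    """Restrict the cube to a rectangular excitation/emission window."""
    ex_keep = (cube.ex_axis >= region.ex_range[0]) & (
        cube.ex_axis <= region.ex_range[1]
    )
    em_keep = (cube.em_axis >= region.em_range[0]) & (
        cube.em_axis <= region.em_range[1]
    )
    if not ex_keep.any() or not em_keep.any():
        raise DataError(
            f"region {region.name or region.ex_range}/{region.em_range} does "
            f"not intersect the cube axes"
        )
    return EEMCube(
        data=cube.data[:, em_keep][:, :, ex_keep].copy(),
        em_axis=cube.em_axis[em_keep].copy(),
        ex_axis=cube.ex_axis[ex_keep].copy(),
        sample_ids=list(cube.sample_ids),
        mask=cube.mask[:, em_keep][:, :, ex_keep].copy(),
    )
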