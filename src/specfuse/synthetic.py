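"""Synthetic class-structured spectroscopic datasets with known ground truth.

Emulates a three-region olive leaf/drupe authentication study: 1-D proton NMR
spectra built from Lorentzian metabolite peaks, excitation-emission fluorescence
cubes built from trilinear Gaussian fluorophore profiles plus Rayleigh/Raman
scatter ridges, and paired two-block datasets whose class contrasts can be
placed on either block or split between them.

Concentrations are log-normal per class: positivity is guaranteed and class
effects act as fold changes. Replicates share a sample's concentration vector
and differ only by measurement noise, mirroring triplicate acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .eem import EEMCube

__all__ = [
    "PeakSpec",
    "MetaboliteSpec",
    "FluorophoreSpec",
    "SyntheticConfig",
    "default_metabolite_library",
    "default_fluorophore_library",
    "generate_nmr",
    "generate_eem",
    "generate_fusion_dataset",
    "fisher_ratio",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian NMR line: center (ppm), half-width at half-maximum
    (ppm) and relative area (the line integrates to ``relative_area``)."""

    center: float
    width: float
    relative_area: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"peak width must be > 0, got {self.width}")
        if self.relative_area < 0:
            raise ConfigError(
                f"peak relative_area must be >= 0, got {self.relative_area}"
            )


@dataclass(frozen=True)
class MetaboliteSpec:
    """A named metabolite: its peak pattern plus a per-class log-normal
    concentration model (mean log-concentration per class, shared log-sd)."""

    name: str
    peaks: tuple[PeakSpec, ...]
    class_log_means: tuple[float, ...]
    log_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ConfigError(f"{self.name}: log_sd must be >= 0")
        if not self.peaks:
            raise ConfigError(f"{self.name}: at least one peak required")


@dataclass(frozen=True)
class FluorophoreSpec:
    """One fluorophore: Gaussian excitation/emission profile centers and
    widths (nm, sd) and per-class mean log-abundance."""

    name: str
    ex_center: float
    em_center: float
    ex_width: float
    em_width: float
    class_log_means: tuple[float, ...]
    log_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.ex_width <= 0 or self.em_width <= 0:
            raise ConfigError(f"{self.name}: profile widths must be > 0")
        if self.log_sd < 0:
            raise ConfigError(f"{self.name}: log_sd must be >= 0")


def default_metabolite_library(n_classes: int = 3) -> tuple[MetaboliteSpec, ...]:
    """Marker metabolites of olive leaf/drupe extracts.

    Oleuropein/ligstroside carry the dominant class contrast; mannitol,
    glucose, quinic acid and the maslinic/oleanolic triterpenes add secondary
    structure. Peak positions are the marker chemical shifts of the matrices
    being emulated.
    """
    def means(*vals: float) -> tuple[float, ...]:
        if len(vals) < n_classes:
            vals = vals + (0.0,) * (n_classes - len(vals))
        return tuple(vals[:n_classes])

    w = 0.012  # HWHM in ppm, typical processed-linewidth scale
    return (
        MetaboliteSpec(
            "oleuropein",
            (
                PeakSpec(1.64, w, 3.0),
                PeakSpec(2.80, w, 2.0),
                PeakSpec(3.71, w, 2.0),
                PeakSpec(6.73, w, 1.0),
            ),
            means(0.45, -0.25, 0.05),
        ),
        MetaboliteSpec(
            "mannitol",
            (PeakSpec(3.65, w, 2.0), PeakSpec(3.81, w, 2.0)),
            means(-0.20, 0.25, 0.00),
        ),
        MetaboliteSpec(
            "glucose",
            (PeakSpec(3.37, w, 1.0), PeakSpec(4.53, w, 0.5)),
            means(0.00, -0.10, 0.20),
        ),
        MetaboliteSpec(
            "quinic acid",
            (PeakSpec(1.96, w, 1.5),),
            means(0.15, 0.00, -0.20),
        ),
        MetaboliteSpec(
            "maslinic/oleanolic acids",
            (PeakSpec(0.90, w, 1.0), PeakSpec(1.02, w, 1.0), PeakSpec(1.13, w, 1.0)),
            means(0.00, 0.15, -0.15),
        ),
    )


#: residual solvent lines (class-independent): water inside 4.50-5.20 ppm,
#: methanol inside 3.28-3.40 ppm — the regions the bucketing step excludes.
SOLVENT_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(4.79, 0.05, 40.0),
    PeakSpec(3.31, 0.02, 25.0),
)


def default_fluorophore_library(
    matrix: str = "leaf_region_b", n_classes: int = 3
) -> tuple[FluorophoreSpec, ...]:
    """Fluorophore libraries for the two plant matrices.

    ``"drupe"``: catechin/epicatechin (280/315 nm), tocopherols (340/450 nm)
    and phenolic compounds (230/310 nm) — note the 230 nm excitation maximum
    requires an excitation grid reaching below 250 nm.

    ``"leaf_region_b"``: chlorogenic acid (320/435 nm), phenolic compounds
    (280 nm excitation, emission shoulder near 350 nm) and tocopherols
    (360/465 nm), all inside a 250-450 / 250-530 nm grid.
    """
    def means(*vals: float) -> tuple[float, ...]:
        if len(vals) < n_classes:
            vals = vals + (0.0,) * (n_classes - len(vals))
        return tuple(vals[:n_classes])

    if matrix == "drupe":
        return (
            FluorophoreSpec("catechin/epicatechin", 280.0, 315.0, 18.0, 22.0,
                            means(0.30, -0.15, 0.05)),
            FluorophoreSpec("tocopherols", 340.0, 450.0, 22.0, 30.0,
                            means(-0.15, 0.25, 0.00)),
            FluorophoreSpec("phenolic compounds", 230.0, 310.0, 15.0, 20.0,
                            means(0.05, 0.00, -0.25)),
        )
    if matrix == "leaf_region_b":
        return (
            FluorophoreSpec("chlorogenic acid", 320.0, 435.0, 20.0, 28.0,
                            means(0.30, -0.15, 0.05)),
            FluorophoreSpec("phenolic compounds", 280.0, 350.0, 16.0, 22.0,
                            means(-0.15, 0.25, 0.00)),
            FluorophoreSpec("tocopherols", 360.0, 465.0, 22.0, 30.0,
                            means(0.05, 0.00, -0.25)),
        )
    raise ConfigError(f"unknown fluorophore library {matrix!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level knobs for the generators.

    Defaults emulate the study conditions: three geographic classes, triplicate
    measurements, the marker metabolite/fluorophore libraries above, and mild
    multiplicative biological variability (log-sd 0.15 per compound).
    """

    n_classes: int = 3
    n_samples_per_class: int = 8
    n_replicates: int = 3
    metabolites: tuple[MetaboliteSpec, ...] = None  # type: ignore[assignment]
    fluorophores: tuple[FluorophoreSpec, ...] = None  # type: ignore[assignment]
    noise_sd: float = 0.002  # fraction of the max noiseless signal
    ppm_min: float = 0.0
    ppm_max: float = 10.5
    ppm_step: float = 0.002
    ex_grid: tuple[float, float, float] = (250.0, 450.0, 10.0)  # lo, hi, step nm
    em_grid: tuple[float, float, float] = (250.0, 550.0, 2.0)
    rayleigh1_amplitude: float = 2.0
    rayleigh2_amplitude: float = 0.8
    raman_amplitude: float = 0.4
    raman_shift_cm: float = 3400.0
    # ridge sd tracks the monochromator bandpass (5 nm slits -> ~7 nm FWHM)
    scatter_width_nm: float = 3.0
    class_labels: tuple[str, ...] = ("Chianti-Siena", "Grosseto", "Val d'Orcia")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.metabolites is None:
            object.__setattr__(
                self, "metabolites", default_metabolite_library(self.n_classes)
            )
        if self.fluorophores is None:
            object.__setattr__(
                self, "fluorophores", default_fluorophore_library(
                    "leaf_region_b", self.n_classes)
            )
        if min(self.n_classes, self.n_samples_per_class, self.n_replicates) < 1:
            raise ConfigError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_classes > len(self.class_labels):
            object.__setattr__(
                self,
                "class_labels",
                tuple(f"class{i}" for i in range(self.n_classes)),
            )
        for met in self.metabolites:
            if len(met.class_log_means) != self.n_classes:
                raise ConfigError(
                    f"{met.name}: {len(met.class_log_means)} class means for "
                    f"{self.n_classes} classes"
                )
        for fl in self.fluorophores:
            if len(fl.class_log_means) != self.n_classes:
                raise ConfigError(
                    f"{fl.name}: {len(fl.class_log_means)} class means for "
                    f"{self.n_classes} classes"
                )

    @property
    def ppm_axis(self) -> np.ndarray:
        n = int(round((self.ppm_max - self.ppm_min) / self.ppm_step)) + 1
        return self.ppm_min + self.ppm_step * np.arange(n)

    @property
    def ex_axis(self) -> np.ndarray:
        lo, hi, step = self.ex_grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    @property
    def em_axis(self) -> np.ndarray:
        lo, hi, step = self.em_grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line."""
    return (hwhm / np.pi) / ((x - center) ** 2 + hwhm ** 2)


def _gaussian_profile(x: np.ndarray, center: float, sd: float) -> np.ndarray:
    """Unit-maximum Gaussian profile."""
    return np.exp(-0.5 * ((x - center) / sd) ** 2)


def raman_emission(ex_nm: np.ndarray | float, shift_cm: float = 3400.0):
    """Emission wavelength (nm) of the Raman band for a given excitation,
    at a fixed Stokes wavenumber shift."""
    return 1.0 / (1.0 / np.asarray(ex_nm, dtype=float) - shift_cm * 1e-7)


def _metadata(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for c in range(config.n_classes):
        label = config.class_labels[c]
        for s in range(config.n_samples_per_class):
            sid = f"{label[:2].upper()}{s:02d}"
            for r in range(config.n_replicates):
                rows.append(
                    {
                        "row_id": f"{sid}:r{r + 1}",
                        "sample_id": sid,
                        "replicate_id": f"r{r + 1}",
                        "class_label": label,
                    }
                )
    return pd.DataFrame(rows).set_index("row_id")


def _concentrations(
    rng: np.random.Generator,
    config: SyntheticConfig,
    specs,
) -> pd.DataFrame:
    """One log-normal concentration per (sample, compound); replicates share it."""
    names = [s.name for s in specs]
    rows, index = [], []
    for c in range(config.n_classes):
        label = config.class_labels[c]
        for s in range(config.n_samples_per_class):
            sid = f"{label[:2].upper()}{s:02d}"
            conc = [
                float(np.exp(sp.class_log_means[c] + sp.log_sd * rng.standard_normal()))
                for sp in specs
            ]
            rows.append(conc)
            index.append(sid)
    return pd.DataFrame(rows, index=index, columns=names)


# --------------------------------------------------------------------------
# NMR generator
# --------------------------------------------------------------------------

def generate_nmr(config: SyntheticConfig):
    """Simulate replicate 1-D NMR spectra.

    Returns ``(spectra, metadata, concentrations)`` where each spectrum is the
    concentration-weighted sum of the metabolite Lorentzian templates plus
    solvent residual lines and additive Gaussian noise. Replicates of a sample
    share its concentration vector and differ only by noise.
    """
    from .nmr import Spectrum  # local import to avoid a cycle at import time

    ppm = config.ppm_axis
    for met in config.metabolites:
        for pk in met.peaks:
            if not (ppm[0] <= pk.center <= ppm[-1]):
                raise ConfigError(
                    f"{met.name}: peak center {pk.center} ppm outside the "
                    f"axis [{ppm[0]}, {ppm[-1]}]"
                )

    templates = np.stack(
        [
            sum(pk.relative_area * _lorentzian(ppm, pk.center, pk.width)
                for pk in met.peaks)
            for met in config.metabolites
        ]
    )  # (n_metabolites, n_points)
    solvent = sum(
        pk.relative_area * _lorentzian(ppm, pk.center, pk.width)
        for pk in SOLVENT_PEAKS
    )

    rng = np.random.default_rng(config.rng_seed)
    conc = _concentrations(rng, config, config.metabolites)
    meta = _metadata(config)

    clean = conc.to_numpy() @ templates + solvent  # (n_samples, n_points)
    scale = float(np.max(clean))
    spectra = []
    for i, sid in enumerate(conc.index):
        for r in range(config.n_replicates):
            noise = config.noise_sd * scale * rng.standard_normal(ppm.size)
            spectra.append(
                Spectrum(
                    ppm=ppm.copy(),
                    intensity=clean[i] + noise,
                    sample_id=sid,
                    replicate_id=f"r{r + 1}",
                )
            )
    return spectra, meta, conc


# --------------------------------------------------------------------------
# EEM generator
# --------------------------------------------------------------------------

def generate_eem(config: SyntheticConfig, include_scatter: bool = True):
    """Simulate a trilinear EEM cube with scatter ridges.

    Returns ``(cube, metadata, true_factors)``; ``true_factors`` holds the
    noiseless sample scores (replicate rows) and the unit-maximum emission and
    excitation profiles, for parameter-recovery tests downstream.
    """
    em, ex = config.em_axis, config.ex_axis
    for fl in config.fluorophores:
        if not (ex[0] <= fl.ex_center <= ex[-1]) or not (
            em[0] <= fl.em_center <= em[-1]
        ):
            raise ConfigError(
                f"{fl.name}: ex/em center ({fl.ex_center}, {fl.em_center}) nm "
                f"outside the grids ex[{ex[0]}, {ex[-1]}], em[{em[0]}, {em[-1]}]"
            )

    em_prof = np.stack(
        [_gaussian_profile(em, fl.em_center, fl.em_width) for fl in config.fluorophores]
    ).T  # (n_em, F)
    ex_prof = np.stack(
        [_gaussian_profile(ex, fl.ex_center, fl.ex_width) for fl in config.fluorophores]
    ).T  # (n_ex, F)

    rng = np.random.default_rng(config.rng_seed + 1)
    abund = _concentrations(rng, config, config.fluorophores)
    meta = _metadata(config)

    # replicate-level scores: replicates share the sample abundance vector
    scores = np.repeat(abund.to_numpy(), config.n_replicates, axis=0)  # (n_rows, F)
    clean = np.einsum("if,jf,kf->ijk", scores, em_prof, ex_prof)

    ridges = np.zeros((em.size, ex.size))
    if include_scatter:
        emg, exg = np.meshgrid(em, ex, indexing="ij")
        sw = config.scatter_width_nm
        ridges += config.rayleigh1_amplitude * np.exp(-0.5 * ((emg - exg) / sw) ** 2)
        ridges += config.rayleigh2_amplitude * np.exp(
            -0.5 * ((emg - 2.0 * exg) / (1.5 * sw)) ** 2
        )
        raman_em = raman_emission(ex, config.raman_shift_cm)
        ridges += config.raman_amplitude * np.exp(
            -0.5 * ((emg - raman_em[None, :]) / sw) ** 2
        )

    scale = float(np.max(clean)) if clean.size else 1.0
    data = clean + ridges[None, :, :]
    if config.noise_sd > 0:
        data = data + config.noise_sd * scale * rng.standard_normal(data.shape)

    cube = EEMCube(
        data=data,
        em_axis=em.copy(),
        ex_axis=ex.copy(),
        sample_ids=list(meta.index),
    )
    true_factors = {
        "scores": scores,
        "em_loadings": em_prof,
        "ex_loadings": ex_prof,
        "names": [fl.name for fl in config.fluorophores],
        "clean_cube": clean,
        "abundances": abund,
    }
    return cube, meta, true_factors


# --------------------------------------------------------------------------
# paired two-block datasets
# --------------------------------------------------------------------------

_CONTRAST_PRESETS = ("block1", "block2", "both", "complementary")


def _apply_contrast(config: SyntheticConfig, preset: str) -> SyntheticConfig:
    """Rewrite the compound libraries so the class signal sits on the chosen
    block(s). ``complementary`` splits it: NMR separates class 0 from class 1
    only (class 2 mimics class 0 there), EEM separates class 0 from class 2
    only — each block carries an orthogonal half of the three-class signal."""
    if preset not in _CONTRAST_PRESETS:
        raise ConfigError(f"unknown contrast preset {preset!r}")
    if config.n_classes != 3:
        raise ConfigError("contrast presets are defined for 3 classes")

    def flat(specs):
        return tuple(replace(s, class_log_means=(0.0,) * 3) for s in specs)

    def nmr_01(specs):
        # class 2 copies class 0's mean: NMR cannot tell classes 0 and 2 apart
        return tuple(
            replace(s, class_log_means=(m[0], m[1], m[0]))
            for s, m in ((s, s.class_log_means) for s in specs)
        )

    def eem_02(specs):
        # class 1 copies class 0's mean: EEM cannot tell classes 0 and 1 apart
        return tuple(
            replace(s, class_log_means=(m[0], m[0], m[2]))
            for s, m in ((s, s.class_log_means) for s in specs)
        )

    mets, fls = config.metabolites, config.fluorophores
    if preset == "block1":
        fls = flat(fls)
    elif preset == "block2":
        mets = flat(mets)
    elif preset == "complementary":
        mets, fls = nmr_01(mets), eem_02(fls)
    return replace(config, metabolites=mets, fluorophores=fls)


def generate_fusion_dataset(
    config: SyntheticConfig,
    contrast: str = "complementary",
    bucket_width: float = 0.04,
    effect_scale: float = 1.0,
):
    """Generate a paired NMR/EEM study over one sample set, fully preprocessed.

    Returns ``(bucket_table, eem_matrix, metadata, truth)``: the normalized
    bucket table, the scatter-cleaned variance-normalized unfolded EEM matrix
    (DataFrame, rows aligned with the bucket table), the shared metadata, and
    a ``truth`` dict recording the generating factors and per-block/fused
    Fisher ratios as the ground-truth separability record.
    """
    from . import eem as eemmod
    from . import nmr as nmrmod

    cfg = _apply_contrast(config, contrast)
    if effect_scale != 1.0:
        cfg = replace(
            cfg,
            metabolites=tuple(
                replace(m, class_log_means=tuple(effect_scale * v
                                                 for v in m.class_log_means))
                for m in cfg.metabolites
            ),
            fluorophores=tuple(
                replace(f, class_log_means=tuple(effect_scale * v
                                                 for v in f.class_log_means))
                for f in cfg.fluorophores
            ),
        )

    spectra, meta, conc = generate_nmr(cfg)
    table = nmrmod.bucket(spectra, width=bucket_width)
    table = nmrmod.normalize_total(table)

    cube, meta_eem, factors = generate_eem(cfg)
    if list(meta_eem.index) != list(meta.index):
        raise ConfigError("sample sets of the two blocks must match exactly")
    cube = eemmod.remove_scatter(cube)
    cube = eemmod.interpolate_missing(cube)
    cube = eemmod.normalize_sample_variance(cube)
    unfolded = eemmod.unfold(cube)
    eem_df = pd.DataFrame(unfolded, index=list(meta.index))

    if list(table.row_ids) != list(meta.index):
        raise ConfigError("sample sets of the two blocks must match exactly")

    labels = meta["class_label"].to_numpy()
    truth = {
        "concentrations": conc,
        "eem_factors": factors,
        "contrast": contrast,
        "fisher_nmr": fisher_ratio(table.matrix, labels),
        "fisher_eem": fisher_ratio(eem_df.to_numpy(), labels),
        "fisher_fused": fisher_ratio(
            np.hstack(
                [
                    table.matrix / np.linalg.norm(table.matrix),
                    eem_df.to_numpy() / np.linalg.norm(eem_df.to_numpy()),
                ]
            ),
            labels,
        ),
    }
    return table, eem_df, meta, truth


def fisher_ratio(X: np.ndarray, labels: np.ndarray, n_pc: int = 6) -> float:
    """Multi-class Fisher separability: trace(pinv(Sw) @ Sb) after compressing
    to the leading principal components (keeps the pseudo-inverse stable when
    variables outnumber samples)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    n_pc = min(n_pc, min(Xc.shape) - 1)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    T = Xc @ vt[:n_pc].T
    classes = np.unique(labels)
    grand = T.mean(axis=0)
    Sb = np.zeros((n_pc, n_pc))
    Sw = np.zeros((n_pc, n_pc))
    for c in classes:
        Tc = T[labels == c]
        mu = Tc.mean(axis=0)
        d = (mu - grand)[:, None]
        Sb += Tc.shape[0] * (d @ d.T)
        R = Tc - mu
        Sw += R.T @ R
    return float(np.trace(np.linalg.pinv(Sw) @ Sb))
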