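"""File I/O, study configuration and the end-to-end study driver.

All artifacts are plain delimited text (auditable, small): spectra as
two-column ppm/intensity files, bucket tables and metadata as CSV, EEM cubes
as a directory of per-sample matrices plus axis files and a JSON manifest.
``run_study`` reproduces the workflow shape of a two-block authentication
study on synthetic data: simulate, preprocess both blocks, PARAFAC
diagnostics, duplex-split single-block SIMCA, ComDim fusion and the
multiblock one-class classifier, ending in a train/test metrics report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import comdim as comdimmod
from . import eem as eemmod
from . import nmr as nmrmod
from . import parafac as parafacmod
from . import simca as simcamod
from . import synthetic as synthmod
from .errors import ConfigError, DataError

__all__ = [
    "StudyConfig",
    "RunReport",
    "run_study",
    "stage_seeds",
    "read_spectrum",
    "write_spectrum",
    "read_bucket_table",
    "write_bucket_table",
    "read_metadata",
    "write_metadata",
    "read_eem_cube",
    "write_eem_cube",
    "read_eem_matrix",
    "write_eem_matrix",
    "write_model_manifest",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# parsing helpers
# --------------------------------------------------------------------------

def _parse_float(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        if "," in token:
            raise DataError(
                f"{path}:{lineno}: {token!r} looks like a localized decimal "
                f"comma; use '.' as the decimal separator"
            ) from None
        raise DataError(f"{path}:{lineno}: cannot parse {token!r} as a number")


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

def write_spectrum(path, spectrum: nmrmod.Spectrum) -> None:
    """Two-column tab-delimited text: ppm, intensity."""
    with open(path, "w") as fh:
        fh.write("# ppm\tintensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")


def read_spectrum(path, sample_id: str | None = None,
                  replicate_id: str = "r1") -> nmrmod.Spectrum:
    path = Path(path)
    ppm, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            ppm.append(_parse_float(parts[0], path, lineno))
            inten.append(_parse_float(parts[1], path, lineno))
    return nmrmod.Spectrum(
        ppm=np.array(ppm),
        intensity=np.array(inten),
        sample_id=sample_id or path.stem,
        replicate_id=replicate_id,
    )


# --------------------------------------------------------------------------
# bucket tables / metadata
# --------------------------------------------------------------------------

def write_bucket_table(path, table: nmrmod.BucketTable) -> None:
    """CSV with bucket-center ppm column labels plus a JSON sidecar holding
    the bucket edges, exclusions and normalization flag."""
    path = Path(path)
    # shortest round-trip reprs keep the matrix bitwise stable through text
    with open(path, "w") as fh:
        fh.write("row_id," + ",".join(
            f"{c:.3f}" for c in table.bucket_centers) + "\n")
        for rid, row in zip(table.row_ids, table.matrix):
            fh.write(rid + "," + ",".join(repr(float(v)) for v in row) + "\n")
    meta = {
        "bucket_edges": [
            [repr(float(a)), repr(float(b))] for a, b in table.bucket_edges
        ],
        "excluded_regions": [list(e) for e in table.excluded_regions],
        "normalized": table.normalized,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1)
    )


def read_bucket_table(path) -> nmrmod.BucketTable:
    path = Path(path)
    df = pd.read_csv(path, index_col="row_id", float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise DataError(f"expected sidecar file {meta_path} next to {path}")
    meta = json.loads(meta_path.read_text())
    return nmrmod.BucketTable(
        matrix=df.to_numpy(),
        bucket_edges=np.array(
            [[float(a), float(b)] for a, b in meta["bucket_edges"]]
        ),
        excluded_regions=tuple(tuple(e) for e in meta["excluded_regions"]),
        row_ids=list(df.index),
        normalized=bool(meta["normalized"]),
    )


def write_metadata(path, meta: pd.DataFrame) -> None:
    meta.to_csv(path)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


# --------------------------------------------------------------------------
# EEM matrices and cubes
# --------------------------------------------------------------------------

def write_eem_matrix(path, matrix: np.ndarray, em_axis, ex_axis) -> None:
    """Single EEM as delimited text: header row = excitation nm, first
    column = emission nm."""
    with open(path, "w") as fh:
        fh.write("em/ex\t" + "\t".join(repr(float(x)) for x in ex_axis) + "\n")
        for j, em in enumerate(em_axis):
            fh.write(
                repr(float(em)) + "\t"
                + "\t".join(repr(float(v)) for v in matrix[j]) + "\n"
            )


def read_eem_matrix(path):
    """Returns ``(matrix, em_axis, ex_axis)``."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    ex_axis = np.array(
        [_parse_float(t, path, 1) for t in header[1:]]
    )
    em_axis, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != ex_axis.size + 1:
            raise DataError(
                f"{path}:{lineno}: expected {ex_axis.size + 1} columns, "
                f"got {len(parts)}"
            )
        em_axis.append(_parse_float(parts[0], path, lineno))
        rows.append([_parse_float(t, path, lineno) for t in parts[1:]])
    return np.array(rows), np.array(em_axis), ex_axis


def write_eem_cube(directory, cube: eemmod.EEMCube) -> None:
    """Cube as a directory: axis files, one matrix file per sample, explicit
    mask files where the mask is set, and a JSON manifest tying it together."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "em_axis.txt").write_text(
        "\n".join(repr(float(x)) for x in cube.em_axis) + "\n"
    )
    (directory / "ex_axis.txt").write_text(
        "\n".join(repr(float(x)) for x in cube.ex_axis) + "\n"
    )
    manifest = {
        "em_axis": "em_axis.txt",
        "ex_axis": "ex_axis.txt",
        "samples": [],
    }
    for i, sid in enumerate(cube.sample_ids):
        safe = sid.replace(":", "_").replace("/", "_")
        fname = f"eem_{safe}.tsv"
        with open(directory / fname, "w") as fh:
            for j in range(cube.em_axis.size):
                fh.write("\t".join(repr(float(v)) for v in cube.data[i, j]) + "\n")
        entry = {"id": sid, "file": fname}
        if cube.mask[i].any():
            mname = f"mask_{safe}.tsv"
            with open(directory / mname, "w") as fh:
                for j in range(cube.em_axis.size):
                    fh.write(
                        "\t".join(str(int(v)) for v in cube.mask[i, j]) + "\n"
                    )
            entry["mask_file"] = mname
        manifest["samples"].append(entry)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_eem_cube(directory) -> eemmod.EEMCube:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"expected manifest file {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    axes = {}
    for key in ("em_axis", "ex_axis"):
        fpath = directory / manifest[key]
        if not fpath.exists():
            raise DataError(f"expected axis file {fpath} (named in manifest)")
        axes[key] = np.array(
            [_parse_float(t, fpath, i + 1)
             for i, t in enumerate(fpath.read_text().split())]
        )
    data, mask, ids = [], [], []
    for entry in manifest["samples"]:
        fpath = directory / entry["file"]
        if not fpath.exists():
            raise DataError(f"expected sample file {fpath} (named in manifest)")
        rows = [
            [_parse_float(t, fpath, lineno) for t in line.split("\t")]
            for lineno, line in enumerate(
                fpath.read_text().strip("\n").split("\n"), start=1)
        ]
        data.append(rows)
        ids.append(entry["id"])
        if "mask_file" in entry:
            mpath = directory / entry["mask_file"]
            if not mpath.exists():
                raise DataError(f"expected mask file {mpath} (named in manifest)")
            mask.append(
                [[bool(int(t)) for t in line.split("\t")]
                 for line in mpath.read_text().strip("\n").split("\n")]
            )
        else:
            mask.append(None)
    data = np.array(data, dtype=float)
    full_mask = np.zeros(data.shape, dtype=bool)
    for i, m in enumerate(mask):
        if m is not None:
            full_mask[i] = np.array(m, dtype=bool)
    return eemmod.EEMCube(
        data=data,
        em_axis=axes["em_axis"],
        ex_axis=axes["ex_axis"],
        sample_ids=ids,
        mask=full_mask,
    )


def write_model_manifest(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# study configuration
# --------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Declarative description of a full synthetic study run."""

    seed: int = 0
    target_label: str = "Chianti-Siena"
    n_samples_per_class: int = 8
    n_replicates: int = 3
    contrast: str = "complementary"
    effect_scale: float = 1.0
    noise_sd: float = 0.002
    bucket_width: float = 0.04
    bucket_range: tuple[float, float] = (0.50, 10.00)
    exclusions: tuple[tuple[float, float], ...] = nmrmod.DEFAULT_EXCLUSIONS
    ex_grid: tuple[float, float, float] = (250.0, 450.0, 10.0)
    em_grid: tuple[float, float, float] = (250.0, 530.0, 2.0)
    include_eem: bool = True
    parafac_f_range: tuple[int, int] = (1, 4)
    parafac_n_starts: int = 4
    simca_a_max: int = 5
    split_ratio: float = 0.8
    n_cd: int | None = 3
    stage_seed_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigError("split_ratio must be in (0, 1)")
        if self.parafac_f_range[0] < 1:
            raise ConfigError("parafac_f_range must start at >= 1")
        if self.simca_a_max < 1:
            raise ConfigError("simca_a_max must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bucket_range", "ex_grid", "em_grid", "parafac_f_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "exclusions" in raw:
            raw["exclusions"] = tuple(tuple(e) for e in raw["exclusions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusions"] = [list(e) for e in self.exclusions]
        for key in ("bucket_range", "ex_grid", "em_grid", "parafac_f_range"):
            d[key] = list(d[key])
        return d


_STAGES = ("nmr", "eem", "parafac")


def stage_seeds(config: StudyConfig) -> dict:
    """Fan a single study seed out to independent per-stage seeds.

    Each stage seed is derived from (root seed, stage index) alone, so
    overriding one stage's seed leaves every other stage untouched.
    """
    seeds = {}
    for idx, stage in enumerate(_STAGES):
        ss = np.random.SeedSequence([int(config.seed), idx])
        seeds[stage] = int(ss.generate_state(1)[0] % (2**31))
    seeds.update(config.stage_seed_overrides)
    return seeds


# --------------------------------------------------------------------------
# study driver
# --------------------------------------------------------------------------

@dataclass
class RunReport:
    config: dict
    seeds: dict
    version: str
    metrics: dict              # model -> {train: {...}, test: {...}}
    parafac: dict | None
    comdim: dict | None
    simca_settings: dict
    notices: list[str]

    def metrics_frame(self) -> pd.DataFrame:
        """Train/test accuracy, sensitivity and specificity per model."""
        rows = {}
        for name, m in self.metrics.items():
            rows[name] = {
                (split, metric): m[split][metric]
                for split in ("train", "test")
                for metric in ("accuracy", "sensitivity", "specificity")
            }
        return pd.DataFrame(rows).T

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


def _synth_config(config: StudyConfig, seed: int) -> synthmod.SyntheticConfig:
    base = synthmod.SyntheticConfig(
        n_samples_per_class=config.n_samples_per_class,
        n_replicates=config.n_replicates,
        noise_sd=config.noise_sd,
        ex_grid=config.ex_grid,
        em_grid=config.em_grid,
        rng_seed=seed,
    )
    return synthmod._apply_contrast(base, config.contrast) if (
        config.contrast != "both"
    ) else base


def _simca_block(name, X_cal, X_test, labels_cal, labels_test, target, a_max):
    """Fit, tune and evaluate one single-block SIMCA model."""
    is_target = labels_cal == target
    Xt = X_cal[is_target]
    a_hi = min(a_max, Xt.shape[0] - 2)
    A, sel_table = simcamod.select_n_components(Xt, range(1, a_hi + 1))
    model = simcamod.fit_simca(Xt, A, target_label=target)
    # cross-validated target distances keep the tuned threshold honest;
    # resubstitution distances would shrink it and kill test sensitivity
    d_t = simcamod.loo_distances(Xt, A)
    d_nt = simcamod.reduced_distance(model, X_cal[~is_target])
    model.threshold = simcamod.optimize_threshold(d_t, d_nt)
    train = simcamod.evaluate(model, X_cal, labels_cal)
    test = simcamod.evaluate(model, X_test, labels_test)
    return model, A, train, test


def run_study(config: StudyConfig) -> RunReport:
    """Execute the full two-block study on synthetic data."""
    seeds = stage_seeds(config)
    notices: list[str] = []

    # ---- block 1: NMR ----------------------------------------------------
    log.info("stage nmr: simulate + bucket (seed %d)", seeds["nmr"])
    cfg_nmr = _synth_config(config, seeds["nmr"])
    spectra, meta, _ = synthmod.generate_nmr(cfg_nmr)
    table = nmrmod.bucket(
        spectra,
        width=config.bucket_width,
        ppm_range=config.bucket_range,
        exclusions=config.exclusions,
    )
    table = nmrmod.normalize_total(table)
    X_nmr = table.matrix
    labels = meta["class_label"].to_numpy()
    sample_ids = meta["sample_id"].to_numpy()

    # ---- block 2: EEM ----------------------------------------------------
    parafac_report = None
    X_eem = None
    if config.include_eem:
        log.info("stage eem: simulate + preprocess (seed %d)", seeds["eem"])
        cfg_eem = _synth_config(config, seeds["eem"])
        cube, meta_eem, _ = synthmod.generate_eem(cfg_eem)
        if list(meta_eem.index) != list(meta.index):
            raise DataError("sample sets of the two blocks must match exactly")
        cube = eemmod.remove_scatter(cube)
        cube = eemmod.interpolate_missing(cube)
        cube = eemmod.normalize_sample_variance(cube)
        X_eem = eemmod.unfold(cube)

        log.info("stage parafac: rank scan (seed %d)", seeds["parafac"])
        lo, hi = config.parafac_f_range
        chosen, ptable = parafacmod.select_components(
            cube,
            f_range=range(lo, hi + 1),
            n_starts=config.parafac_n_starts,
            seed=seeds["parafac"],
            max_iter=500,
            tol=1e-7,
        )
        parafac_report = {
            "chosen_components": chosen,
            "table": ptable.reset_index().to_dict(orient="list"),
        }
    else:
        notices.append(
            "EEM block omitted by configuration: PARAFAC diagnostics, the EEM "
            "SIMCA model and all fusion stages were skipped."
        )

    # ---- duplex split (replicates never straddle it) ---------------------
    parts = [X_nmr / np.linalg.norm(X_nmr)]
    if X_eem is not None:
        parts.append(X_eem / np.linalg.norm(X_eem))
    combined = np.hstack(parts)
    cal_idx, test_idx = simcamod.duplex_split(
        combined, ratio=config.split_ratio, groups=sample_ids
    )

    metrics: dict = {}
    target = config.target_label
    model_nmr, a_nmr, tr, te = _simca_block(
        "nmr", X_nmr[cal_idx], X_nmr[test_idx],
        labels[cal_idx], labels[test_idx], target, config.simca_a_max,
    )
    metrics["simca_nmr"] = {"train": tr.as_dict(), "test": te.as_dict()}
    simca_settings = {
        "nmr": {"n_components": a_nmr, "threshold": model_nmr.threshold,
                "q_limit_95": model_nmr.q_limit_95,
                "t2_limit_95": model_nmr.t2_limit_95},
    }

    comdim_report = None
    if X_eem is not None:
        model_eem, a_eem, tr, te = _simca_block(
            "eem", X_eem[cal_idx], X_eem[test_idx],
            labels[cal_idx], labels[test_idx], target, config.simca_a_max,
        )
        metrics["simca_eem"] = {"train": tr.as_dict(), "test": te.as_dict()}
        simca_settings["eem"] = {
            "n_components": a_eem, "threshold": model_eem.threshold,
            "q_limit_95": model_eem.q_limit_95,
            "t2_limit_95": model_eem.t2_limit_95,
        }

        # ---- fusion: exploratory ComDim + multiblock one-class ----------
        log.info("stage fusion: ComDim + multiblock one-class classifier")
        is_target_cal = labels[cal_idx] == target
        blocks_target = [
            comdimmod.Block(X_nmr[cal_idx][is_target_cal], "nmr"),
            comdimmod.Block(X_eem[cal_idx][is_target_cal], "eem"),
        ]
        occ = comdimmod.fit_mb_occ(
            blocks_target, n_cd=config.n_cd, target_label=target
        )
        d_t = comdimmod.occ_loo_distances(
            [X_nmr[cal_idx][is_target_cal], X_eem[cal_idx][is_target_cal]],
            n_cd=config.n_cd,
        )
        d_nt = comdimmod.occ_distance(
            occ, [X_nmr[cal_idx][~is_target_cal], X_eem[cal_idx][~is_target_cal]]
        )
        occ.threshold = simcamod.optimize_threshold(d_t, d_nt)
        tr = comdimmod.evaluate_occ(
            occ, [X_nmr[cal_idx], X_eem[cal_idx]], labels[cal_idx]
        )
        te = comdimmod.evaluate_occ(
            occ, [X_nmr[test_idx], X_eem[test_idx]], labels[test_idx]
        )
        metrics["comdim_occ"] = {"train": tr.as_dict(), "test": te.as_dict()}
        comdim_report = {
            "n_cd": occ.comdim.n_cd,
            "explained_variance": [float(v) for v in occ.comdim.explained_variance],
            "cumulative_variance": [float(v) for v in occ.comdim.cumulative_variance],
            "saliences": {
                name: [float(v) for v in occ.comdim.saliences[b]]
                for b, name in enumerate(occ.comdim.block_names)
            },
            "threshold": occ.threshold,
            "sd_limit_95": occ.sd_limit_95,
            "od_limit_95": occ.od_limit_95,
        }

    return RunReport(
        config=config.to_dict(),
        seeds=seeds,
        version=__version__,
        metrics=metrics,
        parafac=parafac_report,
        comdim=comdim_report,
        simca_settings=simca_settings,
        notices=notices,
    )
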