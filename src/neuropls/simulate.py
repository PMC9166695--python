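"""Synthetic two-visit cohorts with a planted imaging-clinical latent association.

The generator emulates the data model the PLS cross-correlation analysis
assumes: an imaging block ``X`` (subjects x 416 regional features, four
modalities over 104 regions) and a clinical block ``Y`` (subjects x 5
percent-change motor outcomes) share a low-rank latent structure

    X = sum_k s_k t_k u_k^T + covariate effects + noise
    Y = sum_k s_k t_k v_k^T + covariate effects + noise

with per-subject latent scores ``t_k ~ N(0, 1)``, unit-norm salience vectors
``u_k`` (imaging) and ``v_k`` (clinical) and singular strengths ``s_k``.
The standardized blocks are then mapped onto realistic measurement scales:
positive fALFF/ReHo/density values, negative Jacobian-determinant atrophy
values, integer MDS-UPDRS-range motor scores at two visits whose percent
change carries the planted clinical block.

Default cohort dimensions and clinical distributions follow the focused
-ultrasound subthalamotomy trial this pipeline targets: 35 subjects, 16/35
right-treated, baseline motor scores 37.6+-8.0 (total), 18.8+-3.7 (treated
side), 3.5+-1.0 (rigidity), 10.0+-2.7 (akinesia), 5.3+-2.5 (tremor), and
percent-change outcomes centred on -40/-57.7/-58/-47.1/-74 with SDs
18/19/30.7/27.4/30.5.

A separate small generator produces 4D voxel time-series blocks (in-band and
out-of-band sinusoids, neighbour-coupled shared signal, white noise, motion
-like confounds) for exercising the fALFF/ReHo extraction stage.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import Parcellation, VoxelBlock
from .tables import (
    MODALITIES,
    SCORE_NAMES,
    make_clinical_table,
    make_feature_table,
    read_clinical_table,
    read_feature_table,
    write_clinical_table,
    write_feature_table,
)

# Clinical study conditions (means +- SD): baseline scores, percent changes.
BASELINE_SCORE_MEANS = (37.6, 18.8, 3.5, 10.0, 5.3)
BASELINE_SCORE_SDS = (8.0, 3.7, 1.0, 2.7, 2.5)
CHANGE_MEANS_PCT = (-40.0, -57.7, -58.0, -47.1, -74.0)
CHANGE_SDS_PCT = (18.0, 19.0, 30.7, 27.4, 30.5)
#: plausible upper bounds for the treated-side MDS-UPDRS sub-scores
SCORE_UPPER_BOUNDS = (132, 80, 20, 48, 40)

AGE_MEAN, AGE_SD = 56.6, 9.5
DURATION_MEAN, DURATION_SD = 7.2, 2.8
FEMALE_FRACTION = 13 / 35
RIGHT_TREATED_FRACTION = 16 / 35

#: measurement-scale (offset, scale) per modality; atrophy is negative-valued
MODALITY_OFFSETS = {
    "fALFF": (0.30, 0.02),
    "ReHo": (0.50, 0.03),
    "GM_atrophy": (-0.50, 0.04),
    "GM_density": (0.60, 0.04),
}


@dataclass
class CohortConfig:
    """Parameters of the planted-latent cohort generator.

    ``singular_strength`` is the effect size per latent component: the
    population cross-covariance between the standardized blocks is
    ``sum_k s_k^2 u_k v_k^T`` when noise SDs are 1.
    """

    n_subjects: int = 35
    region_counts: dict = field(
        default_factory=lambda: {"cortical": 70, "subcortical": 16, "cerebellar": 18}
    )
    modalities: tuple = MODALITIES
    latent_rank: int = 1
    singular_strength: tuple = (2.5,)
    imaging_saliences: np.ndarray | None = None  # (n_features, rank), unit columns
    clinical_saliences: np.ndarray | None = None  # (5, rank), unit columns
    imaging_salience_density: float = 0.5
    noise_sd_imaging: float = 1.0
    noise_sd_clinical: float = 1.0
    covariate_effect: float = 0.3
    treated_side_fraction: float = RIGHT_TREATED_FRACTION
    change_drift_strength: float = 0.8
    change_noise_sd: float = 0.3
    min_baseline_score: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if any(c <= 0 or int(c) != c for c in self.region_counts.values()):
            raise ValueError("region counts must be positive integers")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if len(self.singular_strength) != self.latent_rank:
            raise ValueError("one singular_strength per latent component required")
        if any(s < 0 for s in self.singular_strength):
            raise ValueError("singular strengths must be nonnegative")
        if not (self.noise_sd_imaging > 0 and self.noise_sd_clinical > 0):
            raise ValueError("noise SDs must be > 0")
        if not 0 < self.imaging_salience_density <= 1:
            raise ValueError("imaging_salience_density must be in (0, 1]")
        if not 0 <= self.treated_side_fraction <= 1:
            raise ValueError("treated_side_fraction must be in [0, 1]")
        p = self.n_features
        if self.imaging_saliences is not None:
            U = np.atleast_2d(np.asarray(self.imaging_saliences, dtype=float))
            if U.shape != (p, self.latent_rank):
                raise ValueError(
                    f"imaging_saliences must have shape ({p}, {self.latent_rank}), "
                    f"got {U.shape}"
                )
            self._check_unit(U, "imaging_saliences")
        if self.clinical_saliences is not None:
            V = np.atleast_2d(np.asarray(self.clinical_saliences, dtype=float))
            if V.shape != (len(SCORE_NAMES), self.latent_rank):
                raise ValueError(
                    f"clinical_saliences must have shape ({len(SCORE_NAMES)}, "
                    f"{self.latent_rank}), got {V.shape}"
                )
            self._check_unit(V, "clinical_saliences")

    @staticmethod
    def _check_unit(M: np.ndarray, name: str) -> None:
        norms = np.linalg.norm(M, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError(f"{name} columns must have unit norm (got {norms})")

    @property
    def n_regions(self) -> int:
        return int(sum(self.region_counts.values()))

    @property
    def n_features(self) -> int:
        return self.n_regions * len(self.modalities)


@dataclass
class SyntheticCohort:
    """A generated two-visit dataset together with its planted ground truth."""

    features_baseline: pd.DataFrame
    features_month4: pd.DataFrame
    clinical_baseline: pd.DataFrame
    clinical_month4: pd.DataFrame
    covariates: pd.DataFrame
    treated_side: pd.Series
    truth: dict
    config: CohortConfig


def region_listing(region_counts: dict | None = None) -> pd.DataFrame:
    """Canonical region table: name, class, hemisphere.

    Cortical and subcortical regions come in left/right pairs; the cerebellar
    set contains eight lateralized pairs plus two midline vermis regions
    (matching the 70/16/18 default split).
    """
    counts = region_counts or {"cortical": 70, "subcortical": 16, "cerebellar": 18}
    rows = []
    for cls, prefix in (("cortical", "ctx"), ("subcortical", "subctx"), ("cerebellar", "cbl")):
        n = counts.get(cls, 0)
        n_pairs, n_mid = divmod(n, 2)
        for i in range(1, n_pairs + 1):
            for hemi in ("L", "R"):
                rows.append((f"{prefix}_{i:02d}", cls, hemi))
        # odd remainders and (for cerebellum) two vermis regions are midline
        if cls == "cerebellar" and n_pairs >= 1 and n_mid == 0 and n >= 4:
            # carve the last pair into two midline vermis regions
            rows = rows[:-2]
            rows.append((f"{prefix}_vermis_1", cls, "mid"))
            rows.append((f"{prefix}_vermis_2", cls, "mid"))
        elif n_mid:
            rows.append((f"{prefix}_mid_1", cls, "mid"))
    return pd.DataFrame(rows, columns=["region", "class", "hemisphere"])


def feature_columns(config: CohortConfig) -> list[tuple[str, str, str]]:
    """(modality, region, side) tuples in canonical order: modality-major."""
    regions = region_listing(config.region_counts)
    cols = []
    for modality in config.modalities:
        for _, r in regions.iterrows():
            cols.append((modality, r["region"], r["hemisphere"]))
    return cols


def _default_saliences(rng, p: int, rank: int, density: float) -> np.ndarray:
    """Random unit-norm salience columns with a fixed fraction of exact zeros."""
    n_active = max(rank, int(np.ceil(density * p)))
    U = np.zeros((p, rank))
    active = rng.choice(p, size=n_active, replace=False)
    G = rng.standard_normal((n_active, rank))
    Q, _ = np.linalg.qr(G)
    U[active] = Q[:, :rank]
    return U


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort from ``config``.

    The latent structure is planted on a standardized (zero-offset, unit
    -noise) scale and then mapped to measurement units per modality and to
    integer clinical scores; the returned ``truth`` dict records the planted
    scores, saliences and strengths for recovery checks.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_subjects, config.n_features, config.latent_rank
    q = len(SCORE_NAMES)

    U = (
        np.asarray(config.imaging_saliences, dtype=float).reshape(p, k)
        if config.imaging_saliences is not None
        else _default_saliences(rng, p, k, config.imaging_salience_density)
    )
    if config.clinical_saliences is not None:
        V = np.asarray(config.clinical_saliences, dtype=float).reshape(q, k)
    else:
        G = rng.standard_normal((q, k))
        V, _ = np.linalg.qr(G)
        V = V[:, :k]
    s = np.asarray(config.singular_strength, dtype=float)

    # covariates
    age = rng.normal(AGE_MEAN, AGE_SD, size=n)
    gender = (rng.random(n) < FEMALE_FRACTION).astype(int)  # 1 = female
    duration = np.clip(rng.normal(DURATION_MEAN, DURATION_SD, size=n), 0.5, None)
    treated = np.where(rng.random(n) < config.treated_side_fraction, "right", "left")
    covariates = pd.DataFrame(
        {"age": age, "gender": gender, "duration": duration},
        index=pd.RangeIndex(n, name="subject"),
    )
    C = (covariates.values - covariates.values.mean(0)) / covariates.values.std(0)

    # latent scores and standardized blocks
    t = rng.standard_normal((n, k))
    Bx = config.covariate_effect * _unit_rows(rng.standard_normal((3, p)))
    By = config.covariate_effect * _unit_rows(rng.standard_normal((3, q)))
    X_std = (t * s) @ U.T + C @ Bx + config.noise_sd_imaging * rng.standard_normal((n, p))
    Y_std = (t * s) @ V.T + C @ By + config.noise_sd_clinical * rng.standard_normal((n, q))

    # month-4 imaging drift: latent-linked direction + small noise
    W = _default_saliences(rng, p, k, config.imaging_salience_density)
    s_rel = s / s.max() if s.max() > 0 else np.zeros_like(s)
    drift = config.change_drift_strength * (t * s_rel) @ W.T
    drift += config.change_noise_sd * rng.standard_normal((n, p))
    X4_std = X_std + drift

    cols = feature_columns(config)
    Xb = _to_measurement_scale(X_std, cols)
    X4 = _to_measurement_scale(X4_std, cols)
    features_baseline = make_feature_table(Xb, cols)
    features_month4 = make_feature_table(X4, cols)

    # clinical scores: integer baseline, month-4 via planted percent change
    mu = np.array(BASELINE_SCORE_MEANS)
    sd = np.array(BASELINE_SCORE_SDS)
    upper = np.array(SCORE_UPPER_BOUNDS, dtype=float)
    baseline = np.clip(
        np.round(rng.normal(mu, sd, size=(n, q))), config.min_baseline_score, upper
    )
    pct = np.array(CHANGE_MEANS_PCT) + np.array(CHANGE_SDS_PCT) * Y_std
    month4 = np.clip(np.round(baseline * (1 + pct / 100.0)), 0, upper)

    clinical_baseline = make_clinical_table(baseline)
    clinical_month4 = make_clinical_table(month4)

    # Population saliences on the scale the analysis sees: the pipeline
    # z-scores every column, so the population cross-covariance of the
    # standardized blocks is D_y (V diag(s^2) U') D_x with D the inverse
    # per-column SDs; its SVD gives the recoverable directions.
    var_x = (U**2) @ (s**2) + (Bx**2).sum(axis=0) + config.noise_sd_imaging**2
    var_y = (V**2) @ (s**2) + (By**2).sum(axis=0) + config.noise_sd_clinical**2
    R_std = (V * s**2) @ U.T / np.sqrt(var_y)[:, None] / np.sqrt(var_x)[None, :]
    Vs, s_std, Ust = np.linalg.svd(R_std, full_matrices=False)
    truth = {
        "latent_scores": t,
        "imaging_saliences": U,
        "clinical_saliences": V,
        "singular_strengths": s,
        "imaging_saliences_std": Ust[:k].T,
        "clinical_saliences_std": Vs[:, :k],
        "singular_strengths_std": s_std[:k],
        "change_saliences": W,
        "planted_pct_change": pct,
    }
    return SyntheticCohort(
        features_baseline=features_baseline,
        features_month4=features_month4,
        clinical_baseline=clinical_baseline,
        clinical_month4=clinical_month4,
        covariates=covariates,
        treated_side=pd.Series(treated, index=covariates.index, name="treated_side"),
        truth=truth,
        config=config,
    )


def _unit_rows(M: np.ndarray) -> np.ndarray:
    return M / np.linalg.norm(M, axis=1, keepdims=True)


def _to_measurement_scale(Z: np.ndarray, cols) -> np.ndarray:
    """Map standardized features onto per-modality offsets/scales and signs."""
    out = np.empty_like(Z)
    modalities = np.array([c[0] for c in cols])
    for modality, (offset, scale) in MODALITY_OFFSETS.items():
        m = modalities == modality
        if not m.any():
            continue
        vals = offset + scale * Z[:, m]
        # sign conventions: atrophy <= 0, functional/density >= 0
        vals = np.minimum(vals, 0.0) if modality == "GM_atrophy" else np.maximum(vals, 0.0)
        out[:, m] = vals
    return out


# ---------------------------------------------------------------------------
# voxel time-series blocks


@dataclass
class TimeseriesConfig:
    """Synthetic 4D voxel-block parameters for testing the fMRI metrics."""

    grid_shape: tuple = (4, 4, 4)
    n_volumes: int = 450
    repetition_time: float = 2.0
    in_band_frequency: float = 0.04
    out_band_frequency: float = 0.15
    in_band_amplitude: float = 1.0
    out_band_amplitude: float = 0.5
    noise_sd: float = 0.5
    neighbor_coupling: float = 0.3
    drop_initial: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed 10 (initial-volume drop)")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be > 0")
        nyquist = 0.5 / self.repetition_time
        for f in (self.in_band_frequency, self.out_band_frequency):
            if f >= nyquist:
                raise ValueError(
                    f"signal frequency {f} Hz at or above Nyquist {nyquist} Hz "
                    f"for TR={self.repetition_time}s"
                )
        if not 0 <= self.neighbor_coupling <= 1:
            raise ValueError("neighbor_coupling must be in [0, 1]")


def generate_voxel_block(config: TimeseriesConfig | None = None) -> VoxelBlock:
    """Generate a 4D voxel block plus motion-like confound series.

    Every voxel's series mixes a grid-shared component (weight
    ``neighbor_coupling``) with a voxel-private component (weight
    ``1 - neighbor_coupling``); each component is the sum of one sinusoid
    inside the 0.01-0.08 Hz band and one outside it, with random phases.
    White noise is added on top.  Six smooth random-walk confounds mimic
    motion parameters.
    """
    config = config or TimeseriesConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.grid_shape
    nt = config.n_volumes
    tgrid = np.arange(nt) * config.repetition_time
    c = config.neighbor_coupling

    def sinusoid_pair(phases_in, phases_out):
        sig = config.in_band_amplitude * np.sin(
            2 * np.pi * config.in_band_frequency * tgrid + phases_in
        )
        sig = sig + config.out_band_amplitude * np.sin(
            2 * np.pi * config.out_band_frequency * tgrid + phases_out
        )
        return sig

    shared = sinusoid_pair(rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi))
    n_vox = nx * ny * nz
    private = np.stack(
        [
            sinusoid_pair(ph_in, ph_out)
            for ph_in, ph_out in zip(
                rng.uniform(0, 2 * np.pi, n_vox), rng.uniform(0, 2 * np.pi, n_vox)
            )
        ]
    )
    series = c * shared[None, :] + (1 - c) * private
    series = series + config.noise_sd * rng.standard_normal((n_vox, nt))
    data = series.reshape(nx, ny, nz, nt)

    confounds = np.cumsum(0.05 * rng.standard_normal((nt, 6)), axis=0)
    return VoxelBlock(
        data=data,
        repetition_time=config.repetition_time,
        confounds=confounds,
        drop_initial=config.drop_initial,
    )


def make_parcellation(grid_shape: tuple, region_counts: dict | None = None) -> Parcellation:
    """Label a small grid with the canonical region set, one or more voxels each.

    Voxels are assigned to the 104 (by default) regions in flat index order;
    any surplus voxels wrap around so every region gets at least one voxel
    when the grid is large enough.
    """
    regions = region_listing(region_counts)
    n_regions = len(regions)
    n_vox = int(np.prod(grid_shape))
    if n_vox < n_regions:
        raise ValueError(
            f"grid of {n_vox} voxels cannot host {n_regions} regions"
        )
    labels = (np.arange(n_vox) % n_regions + 1).reshape(grid_shape)
    table = regions.copy()
    table.insert(0, "label", np.arange(1, n_regions + 1))
    return Parcellation(labels=labels, region_table=table)


# ---------------------------------------------------------------------------
# cohort I/O


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("imaging_saliences", "clinical_saliences"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["singular_strength"] = list(d["singular_strength"])
    d["modalities"] = list(d["modalities"])
    return d


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a cohort directory of CSV tables + truth.json + manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(cohort.features_baseline, outdir / "features_baseline.csv")
    write_feature_table(cohort.features_month4, outdir / "features_month4.csv")
    write_clinical_table(cohort.clinical_baseline, outdir / "clinical_baseline.csv")
    write_clinical_table(cohort.clinical_month4, outdir / "clinical_month4.csv")
    cov = cohort.covariates.copy()
    cov["treated_side"] = cohort.treated_side
    cov.to_csv(outdir / "covariates.csv")
    truth = {key: np.asarray(val).tolist() for key, val in cohort.truth.items()}
    (outdir / "truth.json").write_text(json.dumps(truth))
    manifest = {"config": _config_to_jsonable(cohort.config), "seed": cohort.config.seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def read_cohort(indir) -> SyntheticCohort:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    cfg = manifest["config"]
    for key in ("imaging_saliences", "clinical_saliences"):
        if cfg.get(key) is not None:
            cfg[key] = np.asarray(cfg[key])
    cfg["singular_strength"] = tuple(cfg["singular_strength"])
    cfg["modalities"] = tuple(cfg["modalities"])
    config = CohortConfig(**cfg)
    truth_path = indir / "truth.json"
    truth = {}
    if truth_path.exists():
        truth = {k: np.asarray(v) for k, v in json.loads(truth_path.read_text()).items()}
    cov = pd.read_csv(indir / "covariates.csv", index_col=0)
    treated = cov.pop("treated_side")
    return SyntheticCohort(
        features_baseline=read_feature_table(indir / "features_baseline.csv"),
        features_month4=read_feature_table(indir / "features_month4.csv"),
        clinical_baseline=read_clinical_table(indir / "clinical_baseline.csv"),
        clinical_month4=read_clinical_table(indir / "clinical_month4.csv"),
        covariates=cov,
        treated_side=treated,
        truth=truth,
        config=config,
    )
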