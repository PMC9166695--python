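"""Regional imaging features from voxel-level inputs.

Four regional measures feed the multivariate analysis:

* **fALFF** — fractional amplitude of low-frequency fluctuation: the share of
  a voxel time-series' spectral amplitude (square-rooted periodogram power)
  falling inside 0.01-0.08 Hz, relative to all positive frequencies.
* **ReHo** — regional homogeneity: Kendall's coefficient of concordance W
  among the time-series ranks of a voxel's 27-voxel cubic neighbourhood,
  averaged over the voxels of a region.
* **GM density / atrophy** — regional means of caller-supplied voxel maps
  (gray-matter probability and Jacobian-determinant maps respectively);
  deformation fields themselves are upstream of this package.

Time-series conditioning follows the conventional resting-state recipe:
drop unstable leading volumes, remove each voxel's linear trend and
motion-confound contributions in one least-squares step, and (for
connectivity-style metrics, not for fALFF) keep only the 0.01-0.08 Hz band.
fALFF must see the unfiltered spectrum — on band-limited data the ratio is
identically 1 — so band-pass filtering is applied only on request.

Feature tables can finally be mirrored so every subject's columns read
treated-side / untreated-side (TS/US) regardless of which hemisphere was
treated, and differenced across visits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import FEATURE_LEVELS, FLIPPED_SIDES, MIDLINE, RAW_SIDES, check_aligned

DEFAULT_BAND = (0.01, 0.08)
DEFAULT_DROP_INITIAL = 10


@dataclass
class VoxelBlock:
    """A 4D (x, y, z, t) array with repetition time and confound series."""

    data: np.ndarray
    repetition_time: float
    confounds: np.ndarray | None = None
    drop_initial: int = DEFAULT_DROP_INITIAL

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("VoxelBlock data must be 4D (x, y, z, t)")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be > 0")
        if self.data.shape[3] <= self.drop_initial:
            raise ValueError(
                f"{self.data.shape[3]} volumes cannot survive dropping "
                f"{self.drop_initial} initial volumes"
            )
        if self.confounds is not None:
            self.confounds = np.atleast_2d(np.asarray(self.confounds, dtype=float))
            if self.confounds.shape[0] not in (
                self.data.shape[3],
                self.data.shape[3] - self.drop_initial,
            ):
                raise ValueError(
                    "confound rows must match volumes before or after the "
                    "initial-volume drop"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def to_nifti(self, path, confounds_path=None) -> None:
        """Write as NIfTI with the TR recorded in the header zooms."""
        import nibabel as nib

        img = nib.Nifti1Image(self.data, affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, self.repetition_time))
        nib.save(img, str(path))
        if confounds_path is not None and self.confounds is not None:
            pd.DataFrame(self.confounds).to_csv(confounds_path, sep="\t", index=False)

    @classmethod
    def from_nifti(cls, path, confounds_path=None, repetition_time=None,
                   drop_initial=DEFAULT_DROP_INITIAL) -> "VoxelBlock":
        import nibabel as nib

        img = nib.load(str(path))
        tr = repetition_time
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) >= 4 else 0.0
        if not tr or tr <= 0:
            raise ValueError(
                "repetition time not present in NIfTI header; pass repetition_time"
            )
        confounds = None
        if confounds_path is not None:
            confounds = pd.read_csv(confounds_path, sep="\t").values
        return cls(np.asarray(img.dataobj, dtype=float), tr, confounds, drop_initial)


@dataclass
class Parcellation:
    """3D integer label volume plus a label -> (region, class, hemisphere) table."""

    labels: np.ndarray
    region_table: pd.DataFrame  # columns: label, region, class, hemisphere

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        known = set(self.region_table["label"])
        missing = present - known
        if missing:
            raise ValueError(f"labels missing from region table: {sorted(missing)[:5]}")


def condition_timeseries(
    block: VoxelBlock,
    band: tuple[float, float] | None = None,
) -> VoxelBlock:
    """Drop initial volumes, detrend, regress confounds; optionally band-pass.

    Detrending and confound regression are a single least-squares projection
    onto [intercept, linear ramp, confounds], so a series exactly equal to a
    confound column (or to a ramp, or constant) leaves a zero residual.
    Pass ``band`` to additionally apply an ideal frequency-domain band-pass —
    do **not** do this upstream of fALFF.
    """
    drop = block.drop_initial
    data = block.data[..., drop:]
    nt = data.shape[-1]
    confounds = block.confounds
    if confounds is not None:
        if confounds.shape[0] == block.n_volumes:
            confounds = confounds[drop:]
    else:
        confounds = np.empty((nt, 0))

    if band is not None:
        _check_band(band, block.repetition_time, nt)

    ramp = np.linspace(-1.0, 1.0, nt)
    design = np.column_stack([np.ones(nt), ramp, confounds])
    flat = data.reshape(-1, nt).T  # time x voxels
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta

    if band is not None:
        resid = bandpass(resid, block.repetition_time, band, axis=0)

    out = resid.T.reshape(data.shape)
    return VoxelBlock(out, block.repetition_time, confounds, drop_initial=0)


def bandpass(x: np.ndarray, repetition_time: float, band=DEFAULT_BAND, axis=-1):
    """Ideal (frequency-domain) band-pass: zero every bin outside [low, high]."""
    x = np.asarray(x, dtype=float)
    nt = x.shape[axis]
    _check_band(band, repetition_time, nt)
    freqs = np.fft.rfftfreq(nt, d=repetition_time)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(x, axis=axis)
    spec = np.apply_along_axis(lambda s: np.where(keep, s, 0), axis, spec)
    return np.fft.irfft(spec, n=nt, axis=axis)


def _check_band(band, repetition_time, nt):
    low, high = band
    nyquist = 0.5 / repetition_time
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    if high >= nyquist:
        raise ValueError(
            f"band upper edge {high} Hz reaches the Nyquist frequency "
            f"{nyquist} Hz for TR={repetition_time}s"
        )
    freqs = np.fft.rfftfreq(nt, d=repetition_time)
    if not ((freqs >= low) & (freqs <= high)).any():
        raise ValueError(f"band {band} contains no frequency bins at length {nt}")


def falff(
    series: np.ndarray, repetition_time: float, band=DEFAULT_BAND
) -> float:
    """Fractional amplitude of low-frequency fluctuation of one time-series.

    Ratio of summed spectral amplitudes (square roots of periodogram power)
    inside ``band`` to the sum over all positive frequencies.  The series
    should be detrended/confound-regressed but **not** band-filtered.
    Returns 0 for an identically-zero series.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 32:
        raise ValueError("series too short for a stable spectrum (need >= 32)")
    _check_band(band, repetition_time, x.size)
    freqs = np.fft.rfftfreq(x.size, d=repetition_time)
    amps = np.abs(np.fft.rfft(x))
    positive = freqs > 0
    total = amps[positive].sum()
    if total == 0:
        return 0.0
    in_band = positive & (freqs >= band[0]) & (freqs <= band[1])
    return float(amps[in_band].sum() / total)


def kendall_w(neighborhood: np.ndarray) -> float:
    """Kendall's coefficient of concordance among K time-series, tie-corrected.

    With K series over t time points, ranks are assigned within each series,
    ``S`` is the sum of squared deviations of per-time-point rank sums from
    their mean, and

        W = 12 S / (K^2 (t^3 - t) - K * sum_j T_j),

    where ``T_j = sum (m^3 - m)`` over tie groups of size ``m`` in series j.
    If every series is constant the statistic is degenerate; 1 is returned
    with a warning.
    """
    M = np.atleast_2d(np.asarray(neighborhood, dtype=float))
    K, t = M.shape
    if K < 2 or t < 3:
        raise ValueError("need at least 2 series of length >= 3")
    ranks = np.apply_along_axis(rankdata, 1, M)
    rank_sums = ranks.sum(axis=0)
    S = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in M:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = K**2 * (t**3 - t) - K * tie_term
    if denom <= 0:
        warnings.warn("all series constant; concordance undefined, returning 1")
        return 1.0
    return 12.0 * S / denom


# keep the field-standard alias
reho = kendall_w


def voxelwise_reho(data4d: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Kendall's W of each voxel's cubic (<=27-voxel) neighbourhood.

    Edge voxels use their in-bounds neighbours.  Voxels outside ``mask``
    (and neighbours outside it) are excluded; masked-out voxels get NaN.
    """
    data4d = np.asarray(data4d, dtype=float)
    nx, ny, nz, _ = data4d.shape
    if mask is None:
        mask = np.ones((nx, ny, nz), dtype=bool)
    out = np.full((nx, ny, nz), np.nan)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                sl = (
                    slice(max(i - 1, 0), min(i + 2, nx)),
                    slice(max(j - 1, 0), min(j + 2, ny)),
                    slice(max(k - 1, 0), min(k + 2, nz)),
                )
                nb_mask = mask[sl]
                series = data4d[sl][nb_mask]
                if series.shape[0] < 2:
                    continue
                out[i, j, k] = kendall_w(series)
    return out


def regional_summary(
    voxel_map: np.ndarray, parcellation: Parcellation, statistic: str = "mean"
) -> pd.Series:
    """Per-region summary (mean) of a 3D voxel map; empty regions get NaN."""
    if statistic != "mean":
        raise ValueError(f"unsupported statistic {statistic!r}")
    voxel_map = np.asarray(voxel_map, dtype=float)
    labels = parcellation.labels
    if voxel_map.shape != labels.shape:
        raise ValueError(
            f"map shape {voxel_map.shape} does not match labels {labels.shape}"
        )
    if not (labels > 0).any():
        raise ValueError("parcellation has no nonzero labels")
    table = parcellation.region_table
    values = []
    index = []
    missing = []
    for _, row in table.iterrows():
        m = labels == row["label"]
        index.append((row["region"], row["hemisphere"]))
        if m.any():
            values.append(float(np.nanmean(voxel_map[m])))
        else:
            values.append(np.nan)
            missing.append(row["region"])
    if missing:
        warnings.warn(f"regions with no voxels: {missing[:5]}")
    idx = pd.MultiIndex.from_tuples(index, names=["region", "side"])
    return pd.Series(values, index=idx, name=statistic)


def extract_functional_features(
    block: VoxelBlock, parcellation: Parcellation, band=DEFAULT_BAND
) -> pd.DataFrame:
    """Regional fALFF and ReHo for one subject's voxel block.

    The block is conditioned (drop, detrend, confound regression) once;
    fALFF is computed on the unfiltered conditioned data and ReHo on the
    band-passed version, both then averaged within regions.
    """
    conditioned = condition_timeseries(block)
    falff_map = np.apply_along_axis(
        falff, 3, conditioned.data, conditioned.repetition_time, band
    )
    filtered = bandpass(conditioned.data, conditioned.repetition_time, band, axis=-1)
    mask = parcellation.labels > 0
    reho_map = voxelwise_reho(filtered, mask=mask)
    return pd.DataFrame(
        {
            "fALFF": regional_summary(falff_map, parcellation),
            "ReHo": regional_summary(reho_map, parcellation),
        }
    )


# ---------------------------------------------------------------------------
# feature-table operations


def flip_sides(table: pd.DataFrame, treated_side: pd.Series) -> pd.DataFrame:
    """Mirror right-treated subjects so columns read treated/untreated side.

    Lateralized L/R column pairs are swapped for right-treated subjects and
    relabeled TS (treated side) / US (untreated side); left-treated subjects
    keep their values and are only relabeled.  Midline columns pass through
    with side ``mid``.  Applying the function to an already-flipped (TS/US)
    table swaps TS/US values again, so two applications on an all-right
    -treated cohort restore the original values.
    """
    treated_side = treated_side.reindex(table.index)
    if treated_side.isna().any():
        missing = table.index[treated_side.isna()].tolist()
        raise ValueError(f"treated side missing for subjects {missing[:5]}")
    bad = ~treated_side.isin(["left", "right"])
    if bad.any():
        raise ValueError(
            f"treated side must be 'left'/'right', got {treated_side[bad].unique()}"
        )

    sides = set(table.columns.get_level_values("side")) - {MIDLINE}
    if sides <= set(RAW_SIDES):
        first, second = RAW_SIDES  # L treated for left-treated subjects
    elif sides <= set(FLIPPED_SIDES):
        first, second = FLIPPED_SIDES
    else:
        raise ValueError(f"mixed side labels {sorted(sides)}")

    # homologue check + column ordering
    pairs = {}
    for modality, region, side in table.columns:
        if side == MIDLINE:
            continue
        pairs.setdefault((modality, region), set()).add(side)
    for (modality, region), got in pairs.items():
        if got != {first, second}:
            raise ValueError(
                f"lateralized region {region!r} ({modality}) lacks a homologue: "
                f"has sides {sorted(got)}"
            )

    right = (treated_side == "right").values
    out = table.copy()
    new_cols = []
    for modality, region, side in table.columns:
        if side == MIDLINE:
            new_cols.append((modality, region, MIDLINE))
            continue
        other = second if side == first else first
        homologue = (modality, region, other)
        out.loc[right, (modality, region, side)] = table.loc[
            right, homologue
        ].values
        new_side = "TS" if side == first else "US"
        new_cols.append((modality, region, new_side))
    out.columns = pd.MultiIndex.from_tuples(new_cols, names=FEATURE_LEVELS)
    return out


def compute_changes(baseline: pd.DataFrame, month4: pd.DataFrame) -> pd.DataFrame:
    """Element-wise month4 - baseline with annotations preserved."""
    check_aligned(baseline, month4, "feature tables")
    return month4 - baseline
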