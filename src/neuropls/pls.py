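"""PLS cross-correlation (PLS-SVD) with permutation and bootstrap inference.

The method finds paired linear combinations — *saliences* — of an imaging
block ``X`` (subjects x features) and a clinical block ``Y`` (subjects x
outcomes) whose covariance is maximal.  After regressing age, gender and
disease duration out of both blocks and z-scoring every column, the
cross-block matrix

    R = Y' X / (n - 1)

is decomposed by SVD, ``R = V S U'``.  Each latent variable (LV) pairs a
clinical salience vector ``v_k`` with an imaging salience vector ``u_k``;
its singular value ``s_k`` measures the imaging-clinical covariance it
captures, and ``s_k^2 / sum_j s_j^2`` is the fraction of total covariance
explained.  Inference:

* **permutation FWE p-values** — subject rows of ``Y`` are permuted, the
  chain re-run, and each observed ``s_k`` compared with the permutation
  distribution of the *maximum* singular value (max-statistic family-wise
  control); the add-one estimator keeps p >= 1/(P+1).
* **bootstrap salience ratios** — subjects are resampled with replacement,
  the chain re-run, resampled saliences aligned to the original by
  orthogonal Procrustes rotation, and each salience divided by its
  bootstrap SE (a pseudo-z); percentile 95% CIs flag robust features.

The user-facing surface is a statsmodels-style pair: :class:`PLSCorrelation`
(the model, built from arrays or annotated tables) whose :meth:`fit` returns
a :class:`PLSResults` carrying estimates, p-values, bootstrap diagnostics,
``summary()`` and writers.  The individual pipeline stages are module-level
functions usable on bare arrays.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

__all__ = [
    "PLSConfig",
    "PLSCorrelation",
    "PLSResults",
    "residualize",
    "zscore_columns",
    "pls_svd",
    "permutation_test",
    "bootstrap_saliences",
    "select_top",
    "modality_contribution",
    "run_analysis",
]

_SD_TOL = 1e-12


@dataclass
class PLSConfig:
    """Inference settings for the PLS pipeline."""

    n_permutations: int = 1000
    n_bootstrap: int = 1000
    alpha: float = 0.05
    top_fraction: float = 0.05
    seed: int = 0
    covariate_names: tuple = ("age", "gender", "duration")
    permute: str = "residual"  # shuffle standardized residuals ('residual') or raw rows
    contribution: str = "sum"
    require_robust: bool = True

    def validate(self) -> None:
        if self.n_permutations < 1 or self.n_bootstrap < 1:
            raise ValueError("iteration counts must be >= 1")
        if not 0 < self.top_fraction < 1 and self.top_fraction != 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.permute not in ("residual", "raw"):
            raise ValueError("permute must be 'residual' or 'raw'")
        if self.contribution not in ("sum", "mean"):
            raise ValueError("contribution must be 'sum' or 'mean'")


# ---------------------------------------------------------------------------
# pipeline stages


def residualize(block: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Replace each column by its least-squares residual on [1, covariates]."""
    X = np.asarray(block, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        return X - X.mean(axis=0)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != X.shape[0]:
        raise ValueError("covariates and block have different numbers of subjects")
    design = np.column_stack([np.ones(X.shape[0]), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(
            f"covariate design is rank-deficient (rank {rank} of {design.shape[1]}); "
            f"collinear design columns (0 = intercept): {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def _collinear_columns(design: np.ndarray) -> list[int]:
    bad = []
    for j in range(1, design.shape[1]):
        others = np.delete(design, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
        resid = design[:, j] - others @ beta
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(design[:, j]), 1.0):
            bad.append(j)
    return bad


def zscore_columns(block: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize columns to mean 0, SD 1 (unbiased SD); constants are an error."""
    X = np.asarray(block, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd <= _SD_TOL)
    if bad.size:
        raise ValueError(
            f"constant (zero-variance) columns cannot be standardized: "
            f"indices {bad[:10].tolist()}"
        )
    return (X - mu) / sd


def _zscore_lenient(X: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, int]:
    """z-score, but recenter-only degenerate columns; returns count of those."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    bad = sd <= _SD_TOL
    sd = np.where(bad, 1.0, sd)
    return (X - mu) / sd, int(bad.sum())


@dataclass
class PLSModelFit:
    """Point estimates of one PLS-SVD decomposition."""

    imaging_saliences: np.ndarray  # (p, K), unit orthogonal columns
    clinical_saliences: np.ndarray  # (q, K)
    singular_values: np.ndarray  # (K,), non-increasing
    covariance_explained: np.ndarray  # (K,), sums to 1
    x_scores: np.ndarray  # (n, K)
    y_scores: np.ndarray  # (n, K)


def pls_svd(X: np.ndarray, Y: np.ndarray, n_components: int | None = None) -> PLSModelFit:
    """SVD of the cross-block matrix R = Y'X/(n-1) of standardized blocks.

    ``X`` (imaging) and ``Y`` (clinical) must already be residualized and
    z-scored and share the subject dimension.  Components are capped at
    ``min(p, q)`` (at most the number of clinical outcomes).  A deterministic
    sign convention makes each LV's largest-magnitude clinical salience
    positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"blocks disagree on subjects: {X.shape[0]} vs {Y.shape[0]}"
        )
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.any(X) or not np.any(Y):
        raise ValueError("all-zero block")
    R = Y.T @ X / (n - 1)
    V, s, Ut = np.linalg.svd(R, full_matrices=False)
    U = Ut.T
    K = min(R.shape)
    if n_components is not None:
        K = min(K, n_components)
    # covariance explained uses the full spectrum; truncation only drops columns
    explained = s**2 / (s**2).sum()
    U, V, s, explained = U[:, :K], V[:, :K], s[:K], explained[:K]
    # sign convention: anchor on the largest-|.| clinical salience per LV
    for k in range(K):
        anchor = np.argmax(np.abs(V[:, k]))
        if V[anchor, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return PLSModelFit(
        imaging_saliences=U,
        clinical_saliences=V,
        singular_values=s,
        covariance_explained=explained,
        x_scores=X @ U,
        y_scores=Y @ V,
    )


def _prepare_blocks(X, Y, covariates):
    Xs = zscore_columns(residualize(X, covariates))
    Ys = zscore_columns(residualize(Y, covariates))
    return Xs, Ys


@dataclass
class PermutationResult:
    null_singular_values: np.ndarray  # (P, K)
    fwe_p: np.ndarray  # (K,)


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    covariates: np.ndarray | None,
    config: PLSConfig,
    rng: np.random.Generator | None = None,
    fit: PLSModelFit | None = None,
) -> PermutationResult:
    """Max-statistic permutation FWE p-values for every latent variable.

    Rows of the clinical block are permuted (imaging fixed), the
    residualize -> z-score -> SVD chain is re-run, and

        p_k = (1 + #{perm : max_j s_j^perm >= s_k}) / (1 + P).

    With ``config.permute == 'residual'`` (default) the shuffling happens in
    an orthonormal basis of the covariate-orthogonal residual subspace
    (Huh-Jhun style): both blocks' residuals are confined to that
    (n - rank) - dimensional subspace, and permuting plain residual rows
    would systematically deflate the null singular values (an
    anticonservative test).  In the transformed basis the rows are
    exchangeable and the observed statistic is unchanged.  ``'raw'``
    shuffles the raw clinical rows and re-runs covariate removal per
    permutation.
    """
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    Xs, Ys = _prepare_blocks(X, Y, covariates)
    if fit is None:
        fit = pls_svd(Xs, Ys)
    n = Xs.shape[0]
    K = fit.singular_values.size
    P = config.n_permutations
    null = np.empty((P, K))
    if config.permute == "residual":
        from scipy.linalg import null_space

        if covariates is None or np.size(covariates) == 0:
            design = np.ones((n, 1))
        else:
            design = np.column_stack([np.ones(n), np.atleast_2d(covariates)])
        Q = null_space(design.T)  # n x (n - rank), orthonormal
        Xh, Yh = Q.T @ Xs, Q.T @ Ys
        m = Xh.shape[0]
        for b in range(P):
            Yp = Yh[rng.permutation(m)]
            sv = np.linalg.svd(Yp.T @ Xh / (n - 1), compute_uv=False)
            null[b] = sv[:K]
    else:
        for b in range(P):
            perm = rng.permutation(n)
            Yp, _ = _zscore_lenient(residualize(np.asarray(Y, float)[perm], covariates))
            sv = np.linalg.svd(Yp.T @ Xs / (n - 1), compute_uv=False)
            null[b] = sv[:K]
    max_null = null.max(axis=1)
    fwe_p = np.array(
        [(1 + (max_null >= s).sum()) / (1 + P) for s in fit.singular_values]
    )
    return PermutationResult(null_singular_values=null, fwe_p=fwe_p)


@dataclass
class BootstrapResult:
    """Bootstrap reliability diagnostics for both blocks' saliences."""

    imaging_ratio: np.ndarray  # (p, K): original salience / bootstrap SE
    clinical_ratio: np.ndarray  # (q, K)
    imaging_ci: tuple  # (low, high), each (p, K)
    clinical_ci: tuple  # (low, high), each (q, K)
    imaging_robust: np.ndarray  # CI excludes zero
    clinical_robust: np.ndarray
    n_degenerate_resamples: int


def bootstrap_saliences(
    X: np.ndarray,
    Y: np.ndarray,
    covariates: np.ndarray | None,
    fit: PLSModelFit,
    config: PLSConfig,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Subject-resampling bootstrap of the saliences, Procrustes-aligned.

    Each resample re-runs the full residualize -> z-score -> SVD chain; the
    resampled clinical saliences are rotated onto the originals by
    orthogonal Procrustes (rotation applied to both blocks), which prevents
    sign and axis flips from inflating the SEs.  Resampled columns that come
    out constant are recentered only and counted.
    """
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    n = X.shape[0]
    K = fit.singular_values.size
    B = config.n_bootstrap
    U0, V0 = fit.imaging_saliences, fit.clinical_saliences
    u_samples = np.empty((B, *U0.shape))
    v_samples = np.empty((B, *V0.shape))
    n_degenerate = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Cb = None if C is None else C[idx]
        try:
            Xb = residualize(X[idx], Cb)
            Yb = residualize(Y[idx], Cb)
        except ValueError:
            # duplicated subjects can make covariates collinear; drop them
            Xb = residualize(X[idx], None)
            Yb = residualize(Y[idx], None)
            n_degenerate += 1
        Xb, dx = _zscore_lenient(Xb)
        Yb, dy = _zscore_lenient(Yb)
        n_degenerate += int(dx > 0 or dy > 0)
        fb = pls_svd(Xb, Yb, n_components=K)
        # align on singular-value-weighted clinical saliences: an unweighted
        # Procrustes is degenerate when the resampled V spans the full
        # outcome space (q = K) and would map it exactly onto V0
        rot, _ = orthogonal_procrustes(
            fb.clinical_saliences * fb.singular_values,
            V0 * fit.singular_values,
        )
        u_samples[b] = fb.imaging_saliences @ rot
        v_samples[b] = fb.clinical_saliences @ rot

    def summarize(samples, original):
        se = samples.std(axis=0, ddof=1)
        se = np.where(se <= _SD_TOL, np.nan, se)
        ratio = original / se
        low = np.percentile(samples, 2.5, axis=0)
        high = np.percentile(samples, 97.5, axis=0)
        robust = low * high > 0
        return ratio, (low, high), robust

    u_ratio, u_ci, u_rob = summarize(u_samples, U0)
    v_ratio, v_ci, v_rob = summarize(v_samples, V0)
    return BootstrapResult(
        imaging_ratio=u_ratio,
        clinical_ratio=v_ratio,
        imaging_ci=u_ci,
        clinical_ci=v_ci,
        imaging_robust=u_rob,
        clinical_robust=v_rob,
        n_degenerate_resamples=n_degenerate,
    )


def select_top(
    boot: BootstrapResult,
    fraction: float = 0.05,
    component: int = 0,
    require_robust: bool = True,
) -> np.ndarray:
    """Indices of the top-|bootstrap ratio| imaging features for one LV.

    The top ``ceil(fraction * n_features)`` features by absolute bootstrap
    ratio are taken (ties broken deterministically by column order), then —
    by default — intersected with the features whose bootstrap CI excludes
    zero.
    """
    ratios = np.abs(boot.imaging_ratio[:, component])
    ratios = np.nan_to_num(ratios, nan=0.0)
    p = ratios.size
    n_sel = int(np.ceil(fraction * p))
    if n_sel < 1:
        raise ValueError(f"fraction {fraction} selects no features out of {p}")
    order = np.argsort(-ratios, kind="stable")  # stable: ties keep column order
    top = order[:n_sel]
    if n_sel < p and ratios[order[n_sel - 1]] == ratios[order[n_sel]]:
        warnings.warn("tied bootstrap ratios at the selection cutoff; "
                      "ties broken by column order")
    if require_robust:
        top = top[boot.imaging_robust[top, component]]
    return np.sort(top)


def modality_contribution(
    boot: BootstrapResult,
    selection: np.ndarray,
    modality_labels,
    component: int = 0,
    how: str = "sum",
    modalities: tuple | None = None,
) -> pd.Series:
    """Fraction of total contribution per modality among selected features.

    For every modality the |bootstrap ratio| of its selected features is
    aggregated (``how='sum'``, default, or ``'mean'``) and the vector is
    normalized to sum to 1; modalities with no selected features get exactly
    0.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    labels = np.asarray(modality_labels)
    if modalities is None:
        modalities = tuple(pd.unique(labels))
    ratios = np.abs(boot.imaging_ratio[:, component])
    agg = {}
    for modality in modalities:
        sel = [i for i in selection if labels[i] == modality]
        if not sel:
            agg[modality] = 0.0
        elif how == "sum":
            agg[modality] = float(ratios[sel].sum())
        else:
            agg[modality] = float(ratios[sel].mean())
    out = pd.Series(agg, name="contribution")
    total = out.sum()
    if total > 0:
        out = out / total
    return out


# ---------------------------------------------------------------------------
# model / results objects


class PLSCorrelation:
    """PLS cross-correlation model between an imaging and a clinical block.

    Parameters
    ----------
    imaging : (n, p) array or annotated DataFrame
        Imaging feature block (columns may carry a (modality, region, side)
        MultiIndex, used for labeling and modality contributions).
    clinical : (n, q) array or DataFrame
        Clinical outcome block (e.g. percent-change motor scores).
    covariates : (n, c) array or DataFrame, optional
        Nuisance variables regressed out of *both* blocks before
        standardization.
    """

    def __init__(self, imaging, clinical, covariates=None):
        self.feature_index = getattr(imaging, "columns", None)
        self.outcome_index = getattr(clinical, "columns", None)
        self.subjects = getattr(imaging, "index", pd.RangeIndex(len(imaging)))
        self.X = np.asarray(imaging, dtype=float)
        self.Y = np.asarray(clinical, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("imaging and clinical blocks disagree on subjects")
        if isinstance(imaging, pd.DataFrame) and isinstance(clinical, pd.DataFrame):
            if not imaging.index.equals(clinical.index):
                raise ValueError("imaging and clinical tables have different subjects")
        if covariates is None:
            self.C = None
            self.covariate_names = ()
        else:
            if isinstance(covariates, pd.DataFrame):
                if isinstance(imaging, pd.DataFrame) and not covariates.index.equals(
                    imaging.index
                ):
                    raise ValueError("covariates index does not match the blocks")
                self.covariate_names = tuple(covariates.columns)
            else:
                self.covariate_names = tuple(
                    f"c{i}" for i in range(np.atleast_2d(covariates).shape[1])
                )
            self.C = np.asarray(covariates, dtype=float)

    @classmethod
    def from_tables(
        cls,
        features: pd.DataFrame,
        outcomes: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        covariate_names: tuple = ("age", "gender", "duration"),
    ) -> "PLSCorrelation":
        """Build from annotated tables, subsetting covariate columns by name."""
        if covariates is not None:
            missing = [c for c in covariate_names if c not in covariates.columns]
            if missing:
                raise ValueError(f"covariates table lacks columns {missing}")
            covariates = covariates.loc[features.index, list(covariate_names)]
        outcomes = outcomes.loc[features.index]
        if outcomes.isna().any().any():
            n_bad = int(outcomes.isna().sum().sum())
            warnings.warn(
                f"{n_bad} missing outcome cells imputed with the column mean "
                "for the multivariate analysis"
            )
            outcomes = outcomes.fillna(outcomes.mean())
        return cls(features, outcomes, covariates)

    @property
    def modality_labels(self) -> np.ndarray | None:
        if self.feature_index is not None and getattr(
            self.feature_index, "nlevels", 1
        ) >= 2:
            return np.asarray(self.feature_index.get_level_values(0))
        return None

    def fit(self, config: PLSConfig | None = None, **overrides) -> "PLSResults":
        """Run the full chain: residualize, z-score, SVD, permutation, bootstrap."""
        config = dataclasses.replace(config or PLSConfig(), **overrides)
        config.validate()
        Xs, Ys = _prepare_blocks(self.X, self.Y, self.C)
        fit = pls_svd(Xs, Ys)
        perm_rng, boot_rng = (
            np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(2)
        )
        perm = permutation_test(self.X, self.Y, self.C, config, rng=perm_rng, fit=fit)
        boot = bootstrap_saliences(self.X, self.Y, self.C, fit, config, rng=boot_rng)
        return PLSResults(self, config, fit, perm, boot)


class PLSResults:
    """Fitted PLS cross-correlation: estimates, inference and reporting."""

    def __init__(self, model, config, fit, permutation, bootstrap):
        self.model = model
        self.config = config
        self._fit = fit
        self.permutation = permutation
        self.bootstrap = bootstrap

    # -- estimates ---------------------------------------------------------
    @property
    def n_components(self) -> int:
        return self._fit.singular_values.size

    @property
    def singular_values(self) -> np.ndarray:
        return self._fit.singular_values

    @property
    def covariance_explained(self) -> np.ndarray:
        return self._fit.covariance_explained

    @property
    def fwe_pvalues(self) -> np.ndarray:
        return self.permutation.fwe_p

    def _lv_cols(self):
        return [f"LV{k + 1}" for k in range(self.n_components)]

    @property
    def imaging_saliences(self) -> pd.DataFrame:
        idx = self.model.feature_index
        return pd.DataFrame(self._fit.imaging_saliences, index=idx, columns=self._lv_cols())

    @property
    def clinical_saliences(self) -> pd.DataFrame:
        idx = self.model.outcome_index
        return pd.DataFrame(self._fit.clinical_saliences, index=idx, columns=self._lv_cols())

    @property
    def latent_scores(self) -> pd.DataFrame:
        cols = self._lv_cols()
        x = pd.DataFrame(
            self._fit.x_scores, index=self.model.subjects,
            columns=[f"imaging_{c}" for c in cols],
        )
        y = pd.DataFrame(
            self._fit.y_scores, index=self.model.subjects,
            columns=[f"clinical_{c}" for c in cols],
        )
        return pd.concat([x, y], axis=1)

    @property
    def significant_components(self) -> np.ndarray:
        return np.flatnonzero(self.fwe_pvalues <= self.config.alpha)

    # -- selection / contributions ----------------------------------------
    def select_top(self, fraction=None, component=0, require_robust=None) -> np.ndarray:
        return select_top(
            self.bootstrap,
            fraction if fraction is not None else self.config.top_fraction,
            component,
            self.config.require_robust if require_robust is None else require_robust,
        )

    def modality_contribution(
        self, component: int = 0, selection=None, how=None
    ) -> pd.Series:
        labels = self.model.modality_labels
        if labels is None:
            raise ValueError("feature columns carry no modality annotations")
        if selection is None:
            selection = self.select_top(component=component)
        from .tables import MODALITIES

        known = tuple(m for m in MODALITIES if m in set(labels))
        modalities = known if known else None
        return modality_contribution(
            self.bootstrap, selection, labels,
            component=component, how=how or self.config.contribution,
            modalities=modalities,
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "PLS Cross-Correlation Results",
            "=" * 64,
            f"subjects: {self.model.X.shape[0]}    imaging features: "
            f"{self.model.X.shape[1]}    clinical outcomes: {self.model.Y.shape[1]}",
            f"covariates removed: {', '.join(self.model.covariate_names) or 'none'}",
            f"permutations: {self.config.n_permutations}    bootstrap: "
            f"{self.config.n_bootstrap}    seed: {self.config.seed}",
            "-" * 64,
            f"{'LV':>3} {'singular':>10} {'cov.expl.%':>11} {'FWE p':>9}",
        ]
        for k in range(self.n_components):
            star = " *" if self.fwe_pvalues[k] <= self.config.alpha else ""
            lines.append(
                f"{k + 1:>3} {self.singular_values[k]:>10.4f} "
                f"{100 * self.covariance_explained[k]:>11.2f} "
                f"{self.fwe_pvalues[k]:>9.4f}{star}"
            )
        lines.append("-" * 64)
        lines.append("clinical saliences (LV1) with bootstrap ratio and 95% CI:")
        v = self._fit.clinical_saliences[:, 0]
        r = self.bootstrap.clinical_ratio[:, 0]
        lo, hi = (c[:, 0] for c in self.bootstrap.clinical_ci)
        names = (
            list(self.model.outcome_index)
            if self.model.outcome_index is not None
            else [f"y{j}" for j in range(v.size)]
        )
        for j, name in enumerate(names):
            flag = " *" if self.bootstrap.clinical_robust[j, 0] else ""
            lines.append(
                f"  {str(name):<22} {v[j]:>8.3f}  BSR {r[j]:>7.2f}  "
                f"[{lo[j]:>7.3f}, {hi[j]:>7.3f}]{flag}"
            )
        if self.bootstrap.n_degenerate_resamples:
            lines.append(
                f"note: {self.bootstrap.n_degenerate_resamples} bootstrap resamples "
                "had degenerate columns (recentered only)"
            )
        lines.append("* FWE p <= alpha / bootstrap 95% CI excludes zero")
        return "\n".join(lines)

    def top_features(self, component: int = 0) -> pd.DataFrame:
        """Selected top-fraction features with their saliences and ratios."""
        sel = self.select_top(component=component)
        df = pd.DataFrame(
            {
                "salience": self._fit.imaging_saliences[sel, component],
                "bootstrap_ratio": self.bootstrap.imaging_ratio[sel, component],
                "ci_low": self.bootstrap.imaging_ci[0][sel, component],
                "ci_high": self.bootstrap.imaging_ci[1][sel, component],
            }
        )
        if self.model.feature_index is not None:
            df.index = self.model.feature_index[sel]
        else:
            df.index = sel
        return df.sort_values("bootstrap_ratio", key=np.abs, ascending=False)

    def save(self, outdir) -> Path:
        """Write the round-trippable results directory (CSV tables + manifest)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lv = self._lv_cols()
        sal = pd.concat(
            [
                self.clinical_saliences.set_axis(
                    [str(c) for c in self.clinical_saliences.index]
                ).assign(block="clinical"),
                self.imaging_saliences.set_axis(
                    [" | ".join(map(str, c)) if isinstance(c, tuple) else str(c)
                     for c in self.imaging_saliences.index]
                ).assign(block="imaging"),
            ]
        )
        sal.index.name = "variable"
        sal.to_csv(outdir / "saliences.csv")

        def block_frame(arr, which):
            idx = sal.index[sal["block"] == which]
            return pd.DataFrame(arr, index=idx, columns=lv)

        ratios = pd.concat(
            [
                block_frame(self.bootstrap.clinical_ratio, "clinical").assign(block="clinical"),
                block_frame(self.bootstrap.imaging_ratio, "imaging").assign(block="imaging"),
            ]
        )
        ratios.index.name = "variable"
        ratios.to_csv(outdir / "bootstrap_ratios.csv")

        ci_parts = []
        for which, (lo, hi) in (
            ("clinical", self.bootstrap.clinical_ci),
            ("imaging", self.bootstrap.imaging_ci),
        ):
            lo_f = block_frame(lo, which).add_suffix("_low")
            hi_f = block_frame(hi, which).add_suffix("_high")
            ci_parts.append(pd.concat([lo_f, hi_f], axis=1).assign(block=which))
        ci = pd.concat(ci_parts)
        ci.index.name = "variable"
        ci.to_csv(outdir / "ci.csv")

        perm = pd.DataFrame(self.permutation.null_singular_values, columns=lv)
        perm.index.name = "permutation"
        perm.to_csv(outdir / "permutation.csv")
        pd.DataFrame(
            {
                "singular_value": self.singular_values,
                "covariance_explained": self.covariance_explained,
                "fwe_p": self.fwe_pvalues,
            },
            index=pd.Index(lv, name="component"),
        ).to_csv(outdir / "components.csv")

        try:
            contrib = self.modality_contribution()
            contrib.rename_axis("modality").to_csv(outdir / "contributions.csv")
        except ValueError:
            pass

        scores = self.latent_scores
        scores.index.name = "subject"
        scores.to_csv(outdir / "latent_scores.csv")

        manifest = {
            "config": dataclasses.asdict(self.config),
            "n_subjects": int(self.model.X.shape[0]),
            "n_features": int(self.model.X.shape[1]),
            "n_outcomes": int(self.model.Y.shape[1]),
        }
        manifest["config"]["covariate_names"] = list(self.config.covariate_names)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return outdir

    def plot_scores(self, component: int = 0, color=None, path=None):
        """Scatter of imaging vs clinical latent scores for one LV."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        x = self._fit.x_scores[:, component]
        y = self._fit.y_scores[:, component]
        sc = ax.scatter(x, y, c=color, cmap="viridis")
        if color is not None:
            fig.colorbar(sc, ax=ax)
        ax.set_xlabel(f"imaging LV{component + 1} score")
        ax.set_ylabel(f"clinical LV{component + 1} score")
        ax.set_title(
            f"LV{component + 1}: {100 * self.covariance_explained[component]:.1f}% "
            f"covariance, FWE p = {self.fwe_pvalues[component]:.3g}"
        )
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def run_analysis(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    config: PLSConfig | None = None,
    mode: str = "baseline",
) -> PLSResults:
    """Fit the full pipeline on annotated tables.

    ``mode`` is a bookkeeping label: pass the baseline feature table for
    ``'baseline'`` (Analysis 1) and the month4-baseline differenced table
    (see :func:`neuropls.features.compute_changes`) for ``'changes'``
    (Analysis 2); the statistical chain is identical.
    """
    if mode not in ("baseline", "changes"):
        raise ValueError("mode must be 'baseline' or 'changes'")
    config = config or PLSConfig()
    model = PLSCorrelation.from_tables(
        features, outcomes, covariates, covariate_names=config.covariate_names
    )
    return model.fit(config)
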