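"""Treatment-outcome variables and descriptive/paired statistics.

Clinical improvement is quantified per subject and score as the percent
change from baseline to the month-4 visit,

    (score_month4 - score_baseline) / score_baseline * 100,

so negative values mean improvement.  Summaries report the mean of these
per-subject ratios (not the ratio of visit means — the two differ whenever
baselines vary).  Paired t-tests compare visits per score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import check_aligned


def percent_change(baseline: pd.DataFrame, month4: pd.DataFrame) -> pd.DataFrame:
    """Per-subject percent change per score; zero baselines yield NaN.

    A zero baseline makes the ratio undefined; the cell is flagged missing
    with a warning and the subject is retained for the other scores.
    """
    check_aligned(baseline, month4, "clinical tables")
    b = baseline.astype(float)
    zero = b == 0
    if zero.any().any():
        n_bad = int(zero.sum().sum())
        warnings.warn(
            f"{n_bad} zero-baseline cells; percent change undefined there (set to NaN)"
        )
    out = (month4 - b) / b.where(~zero) * 100.0
    return out


@dataclass
class PairedTestResult:
    """Per-score paired t-test on visit differences (df = n - 1)."""

    table: pd.DataFrame  # columns: t, p, df, mean_diff, sd_diff, zero_variance

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def paired_test(baseline: pd.DataFrame, month4: pd.DataFrame) -> PairedTestResult:
    """Classical paired t-test per score between the two visits.

    Scores whose visit differences have zero variance are flagged
    (``zero_variance``) and reported with NaN p, rather than erroring.
    """
    check_aligned(baseline, month4, "clinical tables")
    rows = {}
    for score in baseline.columns:
        d = (month4[score] - baseline[score]).dropna().values
        n = d.size
        if n < 3:
            raise ValueError(f"score {score!r} has fewer than 3 paired observations")
        sd = d.std(ddof=1)
        if sd == 0:
            rows[score] = dict(
                t=np.nan, p=np.nan, df=n - 1, mean_diff=d.mean(), sd_diff=0.0,
                zero_variance=True,
            )
            continue
        res = stats.ttest_rel(month4[score], baseline[score], nan_policy="omit")
        rows[score] = dict(
            t=float(res.statistic), p=float(res.pvalue), df=n - 1,
            mean_diff=float(d.mean()), sd_diff=float(sd), zero_variance=False,
        )
    return PairedTestResult(pd.DataFrame(rows).T)


def cohort_summary(
    baseline: pd.DataFrame,
    month4: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    treated_side: pd.Series | None = None,
) -> dict:
    """Descriptive report: demographics, per-visit scores, percent changes.

    Returns a dict of DataFrames mirroring the layout of a standard trial
    descriptives table: ``demographics`` (mean +- SD / counts), ``scores``
    (per score, per visit) and ``changes`` (mean +- SD of per-subject percent
    changes, with the count of defined cells).
    """
    check_aligned(baseline, month4, "clinical tables")
    one_subject = len(baseline) < 2

    def msd(x):
        x = pd.Series(x).dropna()
        sd = x.std(ddof=1) if len(x) > 1 else np.nan
        return float(x.mean()), float(sd) if sd == sd else np.nan

    scores = []
    for score in baseline.columns:
        mb, sb = msd(baseline[score])
        m4, s4 = msd(month4[score])
        scores.append((score, mb, sb, m4, s4))
    scores = pd.DataFrame(
        scores, columns=["score", "baseline_mean", "baseline_sd", "month4_mean", "month4_sd"]
    ).set_index("score")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pct = percent_change(baseline, month4)
    changes = pd.DataFrame(
        {
            "mean_pct_change": pct.mean(),
            "sd_pct_change": pct.std(ddof=1),
            "n_defined": pct.notna().sum(),
        }
    )
    if one_subject:
        scores[["baseline_sd", "month4_sd"]] = np.nan
        changes["sd_pct_change"] = np.nan

    demo_rows = []
    if covariates is not None:
        for col in ("age", "duration"):
            if col in covariates:
                m, s = msd(covariates[col])
                demo_rows.append((col, f"{m:.1f} ± {s:.1f}"))
        if "gender" in covariates:
            n_f = int((covariates["gender"] == 1).sum())
            demo_rows.append(("gender", f"{len(covariates) - n_f} male, {n_f} female"))
    if treated_side is not None:
        n_r = int((treated_side == "right").sum())
        demo_rows.append(
            ("treated_side", f"{n_r} right, {len(treated_side) - n_r} left")
        )
    demographics = pd.DataFrame(demo_rows, columns=["item", "value"]).set_index("item")

    return {"demographics": demographics, "scores": scores, "changes": changes}


def format_summary(summary: dict) -> str:
    """Human-readable text rendering of :func:`cohort_summary`."""
    parts = []
    if len(summary["demographics"]):
        parts.append("Demographics\n" + summary["demographics"].to_string())
    sc = summary["scores"]
    lines = ["Clinical assessments (mean ± SD)"]
    for score, row in sc.iterrows():
        lines.append(
            f"  {score}: baseline {row.baseline_mean:.1f} ± {row.baseline_sd:.1f}"
            f", month 4 {row.month4_mean:.1f} ± {row.month4_sd:.1f}"
        )
    parts.append("\n".join(lines))
    ch = summary["changes"]
    lines = ["Clinical changes (%)"]
    for score, row in ch.iterrows():
        lines.append(
            f"  {score}: {row.mean_pct_change:.1f} ± {row.sd_pct_change:.1f}"
            f" (n={int(row.n_defined)})"
        )
    parts.append("\n".join(lines))
    return "\n\n".join(parts)
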