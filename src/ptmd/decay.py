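"""First-order decay kinetics and score-stratified stability testing.

Labeled-fraction time courses (metabolic-labeling chase, e.g. 4sU pulse
followed by a uridine chase sampled at 0/1/2/4/8/12 h) and reporter
time courses (transcription shut-off sampled at 0/2/4/6 h) are fit with a
single-exponential model y(t) = exp(-k t) by least squares on ln(y) vs t;
t1/2 = ln2 / k.  Half-life fold-changes between conditions feed a
one-sided Wilcoxon rank-sum comparison of a transcript stratum (e.g. the
top weighted-score mRNAs) against the background distribution, the test
behind cumulative-distribution plots of stabilization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))

REPORTER_TIMEPOINTS = (0.0, 2.0, 4.0, 6.0)


@dataclass(frozen=True)
class HalfLifeFit:
    k: float  # decay rate per hour
    t_half: float  # hours; inf when flagged stable
    r_squared: float
    n_points: int
    status: str  # 'ok', 'stable' or 'unfit'


def fit_half_life(
    timepoints: Sequence[float],
    values: Sequence[float],
    floor: float = 0.01,
) -> HalfLifeFit:
    """Fit y(t) = exp(-k t) by log-linear least squares.

    Values are first normalized to the mean of the t=0 observations (warning
    and normalization to the earliest timepoint if 0 h is absent).  Points at
    or below ``floor`` after normalization are excluded before taking logs;
    fewer than 3 surviving points, or a non-positive fitted rate, yields an
    'unfit'/'stable' flag instead of a half-life.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("timepoints and values must have equal length")
    if len(np.unique(t)) < 3:
        raise ValueError("need measurements at >= 3 distinct timepoints")
    if not np.any(t == 0):
        warnings.warn("no t=0 measurement; normalizing to the earliest timepoint")
        t0 = t.min()
    else:
        t0 = 0.0
    baseline = y[t == t0].mean()
    if baseline <= 0:
        return HalfLifeFit(np.nan, np.nan, np.nan, 0, "unfit")
    yn = y / baseline
    keep = yn > floor
    if keep.sum() < 3:
        return HalfLifeFit(np.nan, np.nan, np.nan, int(keep.sum()), "unfit")
    fit = stats.linregress(t[keep], np.log(yn[keep]))
    k = -float(fit.slope)
    r2 = float(fit.rvalue**2)
    if k <= 0:
        return HalfLifeFit(k, np.inf, r2, int(keep.sum()), "stable")
    return HalfLifeFit(k, LN2 / k, r2, int(keep.sum()), "ok")


def fit_decay_table(measurements: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """Fit every (transcript, condition) time course in a measurement table.

    Replicates are averaged per timepoint before fitting.  Failed fits are
    kept with their status flag, never dropped.
    """
    required = {"transcript_id", "condition", "timepoint_h", "labeled_fraction"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurement table must have columns {sorted(required)}")
    rows = []
    grouped = measurements.groupby(["transcript_id", "condition"], sort=True)
    for (tid, cond), grp in grouped:
        avg = grp.groupby("timepoint_h")["labeled_fraction"].mean()
        fit = fit_half_life(avg.index.to_numpy(), avg.to_numpy(), floor=floor)
        rows.append(
            {
                "transcript_id": tid,
                "condition": cond,
                "k": fit.k,
                "t_half": fit.t_half,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "status": fit.status,
            }
        )
    return pd.DataFrame(rows)


def half_life_fold_change(
    table_control: pd.DataFrame, table_perturbed: pd.DataFrame
) -> pd.DataFrame:
    """log2(t1/2 perturbed / t1/2 control) per transcript.

    Transcripts not fit with status 'ok' in both conditions are excluded;
    the exclusion tally is kept in ``DataFrame.attrs['excluded']``.
    """
    ctrl = table_control.loc[table_control["status"] == "ok", ["transcript_id", "t_half"]]
    pert = table_perturbed.loc[table_perturbed["status"] == "ok", ["transcript_id", "t_half"]]
    merged = ctrl.merge(pert, on="transcript_id", suffixes=("_control", "_perturbed"))
    merged["log2_fold_change"] = np.log2(merged["t_half_perturbed"] / merged["t_half_control"])
    n_all = len(set(table_control["transcript_id"]) | set(table_perturbed["transcript_id"]))
    merged.attrs["excluded"] = n_all - len(merged)
    return merged


# ---------------------------------------------------------------------------
# stratified CDF comparison
# ---------------------------------------------------------------------------

@dataclass
class StratifiedTestResult:
    w_statistic: float  # rank-sum of the stratum
    u_statistic: float
    p_value: float
    n_stratum: int
    n_background: int
    method: str
    alternative: str
    ecdf: pd.DataFrame = field(repr=False, default=None)


def _ecdf_frame(values: np.ndarray, group: str) -> pd.DataFrame:
    x = np.sort(values)
    return pd.DataFrame(
        {"value": x, "ecdf": np.arange(1, len(x) + 1) / len(x), "group": group}
    )


def stratified_cdf_test(
    fold_changes: Mapping[str, float] | pd.Series,
    stratum_ids: Iterable[str],
    background_ids: Iterable[str] | None = None,
    alternative: str = "greater",
    exact_max_n: int = 12,
) -> StratifiedTestResult:
    """One-sided Wilcoxon rank-sum comparison of a stratum vs background.

    ``alternative='greater'`` asks whether the stratum's fold-changes are
    stochastically larger than the background's (the stabilization question).
    Background defaults to all non-stratum transcripts; any overlap with the
    stratum is removed.  The exact null distribution is used when both
    samples are small and tie-free, otherwise the normal approximation with
    midrank tie correction and continuity correction.  ECDF coordinates for
    both groups are returned for CDF plotting.
    """
    fc = pd.Series(fold_changes, dtype=float).dropna()
    stratum_ids = [i for i in stratum_ids if i in fc.index]
    if not stratum_ids:
        raise ValueError("empty stratum")
    stratum_set = set(stratum_ids)
    if background_ids is None:
        background_ids = [i for i in fc.index if i not in stratum_set]
    else:
        background_ids = [i for i in background_ids if i in fc.index and i not in stratum_set]
    if not background_ids:
        raise ValueError("empty background")
    x = fc.loc[stratum_ids].to_numpy()
    y = fc.loc[background_ids].to_numpy()
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # rank-sum form
    ecdf = pd.concat(
        [_ecdf_frame(x, "stratum"), _ecdf_frame(y, "background")], ignore_index=True
    )
    return StratifiedTestResult(
        w_statistic=w,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_stratum=len(x),
        n_background=len(y),
        method=method,
        alternative=alternative,
        ecdf=ecdf,
    )


def top_score_ids(score_table: pd.DataFrame, n: int = 1000) -> list[str]:
    """Ids of the n transcripts with the highest weighted codon score."""
    ordered = score_table.sort_values("score", ascending=False, kind="stable")
    return ordered["transcript_id"].head(n).tolist()


def exclude_top_scores(
    ids: Iterable[str], score_table: pd.DataFrame, n: int = 1000
) -> list[str]:
    """Remove transcripts that also carry a top-n weighted score.

    Used when testing a codon-defined stratum (e.g. mRNAs rich in the other
    arginine codons) so that overlap with the high-score set cannot carry
    the signal.
    """
    top = set(top_score_ids(score_table, n))
    return [i for i in ids if i not in top]


# ---------------------------------------------------------------------------
# reporter time courses
# ---------------------------------------------------------------------------

def fit_reporter_decay(
    abundances: pd.DataFrame,
    floor: float = 0.01,
) -> pd.DataFrame:
    """Fit reporter mRNA decay from relative-abundance time courses.

    Expects columns (reporter, condition, timepoint_h, relative_abundance);
    values are normalized to t=0 inside the exponential fit.  Returns one
    row per reporter x condition with k, t1/2 and fit diagnostics.
    """
    required = {"reporter", "condition", "timepoint_h", "relative_abundance"}
    if not required.issubset(abundances.columns):
        raise ValueError(f"reporter table must have columns {sorted(required)}")
    renamed = abundances.rename(
        columns={"reporter": "transcript_id", "relative_abundance": "labeled_fraction"}
    )
    out = fit_decay_table(renamed, floor=floor)
    return out.rename(columns={"transcript_id": "reporter"})
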