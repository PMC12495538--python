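"""Cohort statistics of skin reflection measurements.

All statistics operate on dB-magnitude values of the reflection
coefficient (a log-normal magnitude is a normal dB value, which is the
distributional model the pipeline tests).  The aggregation order is fixed:
the three consecutive repeats of each site measurement are averaged first,
then sites of the same stratum-corneum class within a subject are averaged,
and only then are cross-subject statistics formed per frequency.

No multiple-testing correction is applied across frequencies: results are
reported per frequency, mirroring how such cohort tables are presented.
Two-sample comparisons use the classic pooled t-test, with Bartlett's test
checking the variance-homogeneity assumption first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "THIN_SITES",
    "THICK_SITES",
    "CohortDataset",
    "subject_values",
    "summarize",
    "normality_pvalue",
    "paired_diff_test",
    "normalize_by_frequency_mean",
    "group_comparison",
    "coverage_curves",
]

#: Site codes by stratum-corneum class (forehead/arms/face are thin;
#: palm and inner-finger sites are thick).
THIN_SITES = frozenset({"1F", "6R", "6L", "7L", "7R", "8L", "8R"})
THICK_SITES = frozenset({"1L", "1R", "2L", "2R", "3L", "3R", "4L", "4R", "5L", "5R"})

REQUIRED_COLUMNS = [
    "subject_id", "age_years", "sex", "group", "site_code", "sc_class",
    "probe", "f_hz", "repeat_index", "s11_db",
]


@dataclass
class CohortDataset:
    """Tidy per-repeat reflection measurements of a volunteer cohort.

    One row per (subject, site, frequency, repeat).  ``sc_class`` must be
    consistent with the site-code taxonomy and every (subject, site,
    frequency) cell must hold repeats 1..3.
    """
    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        site_ok = (
            (self.df["site_code"].isin(THIN_SITES) & (self.df["sc_class"] == "thin"))
            | (self.df["site_code"].isin(THICK_SITES) & (self.df["sc_class"] == "thick"))
        )
        if not site_ok.all():
            bad = self.df.loc[~site_ok, ["site_code", "sc_class"]].drop_duplicates()
            raise ValueError(f"sc_class inconsistent with site codes:\n{bad}")

    def __len__(self):
        return len(self.df)


def _as_df(dataset) -> pd.DataFrame:
    return dataset.df if isinstance(dataset, CohortDataset) else dataset


def subject_values(dataset, missing: str = "strict") -> pd.DataFrame:
    """Per-subject dB value for each (sc_class, probe, frequency).

    Repeats are averaged per site, then sites of the same class averaged
    within the subject.  ``missing='strict'`` raises if any site cell does
    not hold exactly three repeats; ``missing='mean'`` averages whatever
    repeats are present.
    """
    df = _as_df(dataset)
    counts = df.groupby(["subject_id", "site_code", "probe", "f_hz"])["s11_db"].count()
    if missing == "strict":
        if not (counts == 3).all():
            bad = counts[counts != 3]
            raise ValueError(
                f"{len(bad)} site cells without exactly 3 repeats (missing='strict')")
    elif missing != "mean":
        raise ValueError("missing policy must be 'strict' or 'mean'")
    site_means = (df.groupby(
        ["subject_id", "sc_class", "site_code", "probe", "f_hz"], as_index=False)
        ["s11_db"].mean())
    subj = (site_means.groupby(
        ["subject_id", "sc_class", "probe", "f_hz"], as_index=False)
        ["s11_db"].mean())
    meta = df[["subject_id", "age_years", "sex", "group"]].drop_duplicates("subject_id")
    return subj.merge(meta, on="subject_id", validate="many_to_one")


def summarize(dataset, missing: str = "strict") -> pd.DataFrame:
    """Cross-subject mean and standard deviation per (sc_class, frequency).

    Returns a tidy frame with columns ``sc_class, probe, f_hz, mean_db,
    sd_db, n`` (ddof=1 standard deviation across subjects).
    """
    subj = subject_values(dataset, missing=missing)
    out = (subj.groupby(["sc_class", "probe", "f_hz"], as_index=False)
           .agg(mean_db=("s11_db", "mean"), sd_db=("s11_db", "std"),
                n=("s11_db", "count")))
    if (out["n"] < 2).any():
        raise ValueError("need at least two subjects per cell for a standard deviation")
    return out


def normality_pvalue(values) -> float:
    """Shapiro-Wilk p-value for a per-frequency dB sample.

    ``p > 0.05`` is read as compatible with dB-normality (log-normal
    magnitude).  Degenerate samples (n < 3 or zero variance) raise
    ``ValueError``; a p-value for a constant sample is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance; normality test undefined")
    return float(sps.shapiro(x).pvalue)


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff_db: float
    ci95_lo: float
    ci95_hi: float
    p: float
    t: float
    dof: int


def paired_diff_test(thin, thick) -> PairedTestResult:
    """Two-sided paired t-test of thin-minus-thick dB values by subject.

    Returns the mean difference with its 95% confidence interval.  A
    positive mean difference means thin-SC sites reflect more strongly
    (less absorption) than thick-SC sites.
    """
    a = np.asarray(thin, dtype=float)
    b = np.asarray(thick, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # all differences identical: degenerate CI at the constant
        p = 1.0 if mean == 0.0 else 0.0
        return PairedTestResult(mean, mean, mean, p, math_inf_sign(mean), n - 1)
    res = sps.ttest_rel(a, b)
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return PairedTestResult(mean, mean - half, mean + half,
                            float(res.pvalue), float(res.statistic), n - 1)


def math_inf_sign(x):
    return float("inf") if x > 0 else (float("-inf") if x < 0 else 0.0)


def normalize_by_frequency_mean(subject_table: pd.DataFrame,
                                value_col: str = "s11_db") -> pd.DataFrame:
    """Remove the per-frequency group mean from per-subject values.

    Operates on the output of :func:`subject_values`; the residual column
    ``resid_db`` has zero mean within every (sc_class, probe, f_hz) cell,
    which removes the frequency dependence before factor comparisons.
    Applying the operation to its own output changes nothing.
    """
    df = subject_table.copy()
    grp = df.groupby(["sc_class", "probe", "f_hz"])[value_col]
    df["resid_db"] = df[value_col] - grp.transform("mean")
    return df


@dataclass(frozen=True)
class GroupComparison:
    t_p: float
    bartlett_p: float
    mean_diff_db: float
    n_a: int
    n_b: int


def group_comparison(residuals_a, residuals_b) -> GroupComparison:
    """Pooled two-sample t-test plus Bartlett variance-homogeneity test.

    Intended for frequency-normalized residuals split by a factor such as
    sex or age group.  The pooled (classic) t-test is used because variance
    homogeneity is checked alongside via Bartlett's test.
    """
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t_res = sps.ttest_ind(a, b, equal_var=True)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        bart_p = 1.0
    else:
        bart_p = float(sps.bartlett(a, b).pvalue)
    return GroupComparison(float(t_res.pvalue), bart_p,
                           float(a.mean() - b.mean()), a.size, b.size)


def coverage_curves(summary: pd.DataFrame, k: float) -> pd.DataFrame:
    """Population-coverage curve ``mean_db - k * sd_db`` per frequency.

    ``k = 1`` and ``k = 2`` are conventionally labeled "68% coverage" and
    "95% coverage" after the two-sided normal mass within +-k sd; as
    one-sided exceedance levels they actually cover about 84% and 97.7% of
    a normal population.  The conventional labels are kept.
    """
    out = summary.copy()
    out["coverage_db"] = out["mean_db"] - k * out["sd_db"]
    out["k"] = k
    out["label"] = {0: "mean", 1: "68% coverage", 2: "95% coverage"}.get(
        k, f"mean-{k:g}sd")
    return out
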