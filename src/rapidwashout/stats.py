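"""Agreement and comparison statistics for the two-modality study design.

Implements the statistics used to compare wash-out volumetry with perfusion
volumetry: inter-rater ICC(2,k) (two-way random effects, absolute agreement,
average measures, with F-based 95% confidence bounds and Koo–Li
interpretation bands), Pearson correlation, Tukey's HSD across subgroups,
paired/two-sample t-tests, and Likert agreement summaries on the 0–100%
scale.

The ICC is computed from the two-way ANOVA decomposition written out
explicitly (targets × raters), so it can be verified cell-by-cell against a
from-scratch sum-of-squares oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RatingTable",
    "ICCResult",
    "icc2k",
    "icc",
    "pearson",
    "tukey_hsd",
    "compare_volumes",
    "likert_agreement_summary",
]


@dataclass
class RatingTable:
    """Targets × raters measurement table with optional subgroup labels.

    ``values``: 2-D array-like or DataFrame, one row per target (lesion or
    case), one column per rater; cells hold measured volumes (mm³) or Likert
    scores.  ``subgroup``: one label per row (e.g. diagnosis × timepoint).
    """

    values: pd.DataFrame
    subgroup: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        if self.subgroup is not None:
            self.subgroup = pd.Series(list(self.subgroup), index=self.values.index)
            if len(self.subgroup) != len(self.values):
                raise ValueError("one subgroup label per row is required")

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    value: float
    ci95: tuple[float, float]
    form: str
    msr: float
    msc: float
    mse: float
    n_targets: int
    n_raters: int
    interpretation: str
    degenerate: bool = False  # zero between-target variance


def _koo_li_band(v: float) -> str:
    if v < 0.5:
        return "poor"
    if v < 0.75:
        return "moderate"
    if v < 0.9:
        return "good"
    return "excellent"


def _anova_ms(x: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows=targets, columns=raters, error) of a two-way table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc(table: RatingTable | pd.DataFrame | np.ndarray, form: str = "2k",
        alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation from the two-way ANOVA decomposition.

    Supported forms (Shrout–Fleiss notation): ``"2k"`` — two-way random
    effects, absolute agreement, average of k raters (the study's inter-rater
    statistic); ``"3k"`` — two-way mixed, consistency, average measures.

    95% confidence bounds for ICC(2,k) follow the F-distribution construction
    for the single-measure coefficient, converted to average measures by the
    Spearman–Brown step.
    """
    if isinstance(table, RatingTable):
        x = table.values.to_numpy(dtype=float)
    else:
        x = pd.DataFrame(table).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("ICC requires a complete table (no missing cells)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 targets and 2 raters")
    msr, msc, mse = _anova_ms(x)
    degenerate = msr <= mse  # no usable between-target variance

    if form == "3k":
        value = (msr - mse) / msr if msr > 0 else float("nan")
        lo = hi = float("nan")  # CI not implemented for the consistency form
        return ICCResult(value, (lo, hi), form, msr, msc, mse, n, k,
                         _koo_li_band(value), degenerate)
    if form != "2k":
        raise ValueError(f"unsupported ICC form {form!r}")

    denom = msr + (msc - mse) / n
    if denom == 0:  # fully constant table: no variance of any kind
        return ICCResult(float("nan"), (float("nan"), float("nan")), "2k",
                         msr, msc, mse, n, k, "poor", True)
    value = (msr - mse) / denom

    # single-measure ICC(2,1) and its F-based bounds, then Spearman-Brown
    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    fj = msc / mse if mse > 0 else np.inf
    vn = (k - 1) * (n - 1) * (k * icc21 * fj + n * (1 + (k - 1) * icc21) - k * icc21) ** 2
    vd = ((n - 1) * k**2 * icc21**2 * fj**2
          + (n * (1 + (k - 1) * icc21) - k * icc21) ** 2)
    v = vn / vd if vd > 0 else 1.0
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    lo = lo1 * k / (1 + lo1 * (k - 1))
    hi = hi1 * k / (1 + hi1 * (k - 1))
    return ICCResult(float(value), (float(lo), float(hi)), "2k", msr, msc, mse,
                     n, k, _koo_li_band(float(value)), degenerate)


def icc2k(table: RatingTable | pd.DataFrame | np.ndarray) -> ICCResult:
    """ICC(2,k): two-way random effects, absolute agreement, average measures."""
    return icc(table, form="2k")


def pearson(x, y) -> tuple[float, float, float]:
    """Product-moment correlation: returns (r, R², two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def tukey_hsd(groups: dict[str, np.ndarray] | list[np.ndarray]) -> pd.DataFrame:
    """Tukey's HSD: all pairwise mean comparisons, family-wise adjusted.

    Returns one row per pair with the mean difference, the studentized-range
    adjusted p-value and the 95% family-wise confidence interval.
    """
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[nm], dtype=float) for nm in names]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i + 1}" for i in range(len(samples))]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("Tukey's test needs >= 2 groups with n >= 2 each")
    res = sps.tukey_hsd(*samples)
    ci = res.confidence_interval(0.95)
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        rows.append({
            "group_a": names[i], "group_b": names[j],
            "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
            "p_adj": float(res.pvalue[i, j]),
            "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j]),
        })
    return pd.DataFrame(rows)


def compare_volumes(
    perfusion_mm3,
    washout_mm3,
    paired: bool = True,
    subgroup=None,
) -> pd.DataFrame:
    """Perfusion-vs-wash-out volume comparison per subgroup.

    Paired t-test (default; per-lesion pairing) or two-sample t-test, with
    mean ± SD descriptives per subgroup.
    """
    perf = np.asarray(perfusion_mm3, dtype=float)
    wash = np.asarray(washout_mm3, dtype=float)
    if perf.shape != wash.shape:
        raise ValueError("paired volume lists must have equal length")
    if subgroup is None:
        subgroup = ["all"] * len(perf)
    df = pd.DataFrame({"perfusion": perf, "washout": wash, "subgroup": list(subgroup)})
    rows = []
    for name, grp in df.groupby("subgroup", sort=False):
        if len(grp) < 2:
            raise ValueError(f"subgroup {name!r}: need at least 2 pairs for a t-test")
        if paired:
            if np.allclose(grp["perfusion"], grp["washout"]):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(grp["perfusion"], grp["washout"])
        else:
            t, p = sps.ttest_ind(grp["perfusion"], grp["washout"])
        rows.append({
            "subgroup": name, "n": len(grp),
            "perfusion_mean_mm3": grp["perfusion"].mean(),
            "perfusion_sd_mm3": grp["perfusion"].std(ddof=1),
            "washout_mean_mm3": grp["washout"].mean(),
            "washout_sd_mm3": grp["washout"].std(ddof=1),
            "t": float(t), "p": float(p), "paired": paired,
        })
    return pd.DataFrame(rows)


def likert_agreement_summary(table: RatingTable, ddof: int = 1) -> pd.DataFrame:
    """Per-subgroup mean ± SD of 0–10 Likert scores on the 0–100% scale.

    Scores are multiplied by 10 (0–100% agreement).  SD uses the sample
    (n−1) convention by default; ``ddof=0`` selects the population
    convention.  Single-row subgroups report SD = 0 with ``sd_flagged=True``.
    """
    scores = table.values.to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError("Likert table contains missing cells")
    if ((scores < 0) | (scores > 10) | (scores != np.round(scores))).any():
        raise ValueError("Likert scores must be integers in [0, 10]")
    pct = scores * 10.0
    sub = table.subgroup if table.subgroup is not None else pd.Series(
        ["all"] * table.n_targets, index=table.values.index)
    rows = []
    for name, idx in sub.groupby(sub).groups.items():
        vals = pct[[table.values.index.get_loc(i) for i in idx]].ravel()
        flagged = vals.size <= ddof
        sd = 0.0 if flagged else float(np.std(vals, ddof=ddof))
        rows.append({
            "subgroup": name, "n_rows": len(idx), "n_scores": vals.size,
            "mean_pct": float(vals.mean()), "sd_pct": sd, "sd_flagged": flagged,
        })
    return pd.DataFrame(rows)
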