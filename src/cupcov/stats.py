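"""Cohort statistics: normality, correlation/regression, group comparison.

Mirrors the original analysis plan: a one-sample Kolmogorov-Smirnov check
of the distribution pattern, Pearson correlation with simple linear
regression (R² = r² for simple regression — the identity the summary table
relies on), a TUCR-threshold group split with a two-sample comparison of
acetabular height and A-P diameter, and a descriptive table.

Notes on deliberate choices: the K-S test is run against a normal with the
*sample* mean/SD, as named in the plan; estimating the parameters inflates
the p-value (the Lilliefors caveat) and we document rather than substitute.
The group comparison uses Welch's t (the plan names no test; the groups are
unequal and variance equality is unverified).  No multiple-testing
correction is applied, matching the plan; the report footer says so.
Bilateral hips are treated as independent records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class ZeroVarianceError(ValueError):
    """A statistic requiring variance was asked of a constant sample."""


@dataclass(frozen=True)
class HipRecord:
    """One hip's measurements feeding the cohort table."""

    hip_id: str
    asucr: float
    aiucr: float
    psucr: float
    piucr: float
    tucr: float
    height_mm: float
    ap_diameter_mm: float
    volume_proxy_mm3: float

    def __post_init__(self):
        for name in ("asucr", "aiucr", "psucr", "piucr", "tucr"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 1]")
        s = self.asucr + self.aiucr + self.psucr + self.piucr
        if abs(s - self.tucr) > 1e-6:
            raise ValueError("segmental UCRs must sum to the TUCR")


@dataclass(frozen=True)
class StatsResult:
    """Pearson + simple-regression result for one variable pair."""

    pearson_r: float
    p_value: float
    r_squared: float
    slope: float
    intercept: float
    n: int


def pearson_regression(x, y) -> StatsResult:
    """Sample Pearson r, OLS slope/intercept, R² = r², two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("both series must have non-zero variance")
    res = sps.linregress(x, y)
    r = float(res.rvalue)
    return StatsResult(
        pearson_r=r,
        p_value=float(res.pvalue),
        r_squared=r * r,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=n,
    )


def ks_normality(x) -> tuple[float, float]:
    """One-sample K-S statistic/p against N(sample mean, sample SD)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("need at least 5 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ZeroVarianceError("sample is constant; K-S against a normal undefined")
    stat, p = sps.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return float(stat), float(p)


def welch_two_sample(x, y) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ZeroVarianceError(
            "both samples constant with different means; t undefined"
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


_VARIABLES = (
    "asucr",
    "aiucr",
    "psucr",
    "piucr",
    "tucr",
    "height_mm",
    "ap_diameter_mm",
    "volume_proxy_mm3",
)


@dataclass(frozen=True)
class CohortSummary:
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    group_counts: dict
    group_tests: pd.DataFrame
    n: int
    alpha: float
    footer: str = (
        "No multiple-testing correction applied; bilateral hips treated as "
        "independent records."
    )

    def report(self) -> str:
        lines = [
            f"Cohort summary (n = {self.n} hips, two-tailed alpha = {self.alpha})",
            "",
            "Descriptives (mean, SD, range, mean +/- 1.96 SD/sqrt(n)):",
            self.descriptives.to_string(),
            "",
            "Pairwise Pearson / simple regression (R^2 = r^2):",
            self.correlations.to_string(index=False),
            "",
            f"Group split at TUCR {self.group_counts['threshold']}: "
            f"{self.group_counts['n_low']} at or below, "
            f"{self.group_counts['n_high']} above.",
            self.group_tests.to_string(index=False),
            "",
            self.footer,
        ]
        return "\n".join(lines)


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {**{v: getattr(r, v) for v in _VARIABLES}, "hip_id": r.hip_id}
        for r in records
    ]
    return pd.DataFrame(rows).set_index("hip_id")


def cohort_summary(
    records,
    group_split_tucr: float = 0.3,
    alpha: float = 0.05,
    plot_dir=None,
) -> CohortSummary:
    """Descriptives, all pairwise correlations, and the TUCR group split.

    Pairs where either variable is constant are reported as not-applicable
    rather than raising.  ``plot_dir`` (optional) receives one scatter PNG
    per significantly correlated pair.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    df = records_to_frame(records)
    n = len(df)

    desc_rows = []
    for v in _VARIABLES:
        x = df[v].to_numpy()
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n) if n > 1 else 0.0
        try:
            ks_stat, ks_p = ks_normality(x)
        except (ValueError, ZeroVarianceError):
            ks_stat, ks_p = np.nan, np.nan
        desc_rows.append(
            {
                "variable": v,
                "mean": mean,
                "sd": sd,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
                "sem_ci_low": mean - half,
                "sem_ci_high": mean + half,
                "ks_stat": ks_stat,
                "ks_p": ks_p,
            }
        )
    descriptives = pd.DataFrame(desc_rows).set_index("variable")

    corr_rows = []
    for i, v1 in enumerate(_VARIABLES):
        for v2 in _VARIABLES[i + 1 :]:
            try:
                res = pearson_regression(df[v1].to_numpy(), df[v2].to_numpy())
                flag = "**" if res.p_value < 0.01 else ("*" if res.p_value < alpha else "")
                corr_rows.append(
                    {
                        "var1": v1,
                        "var2": v2,
                        "r": res.pearson_r,
                        "r_squared": res.r_squared,
                        "p": res.p_value,
                        "sig": flag,
                    }
                )
            except (ZeroVarianceError, ValueError):
                corr_rows.append(
                    {"var1": v1, "var2": v2, "r": np.nan, "r_squared": np.nan,
                     "p": np.nan, "sig": "n/a"}
                )
    correlations = pd.DataFrame(corr_rows)

    low = df[df["tucr"] <= group_split_tucr]
    high = df[df["tucr"] > group_split_tucr]
    group_counts = {
        "threshold": group_split_tucr,
        "n_low": int(len(low)),
        "n_high": int(len(high)),
    }
    test_rows = []
    for v in ("height_mm", "ap_diameter_mm"):
        if len(low) >= 2 and len(high) >= 2:
            try:
                t, dof, p = welch_two_sample(low[v].to_numpy(), high[v].to_numpy())
                test_rows.append({"variable": v, "t": t, "df": dof, "p": p})
            except ZeroVarianceError:
                test_rows.append({"variable": v, "t": np.nan, "df": np.nan, "p": np.nan})
        else:
            test_rows.append({"variable": v, "t": np.nan, "df": np.nan, "p": np.nan})
    group_tests = pd.DataFrame(test_rows)

    summary = CohortSummary(
        descriptives=descriptives,
        correlations=correlations,
        group_counts=group_counts,
        group_tests=group_tests,
        n=n,
        alpha=alpha,
    )
    if plot_dir is not None:
        _scatter_plots(df, correlations, plot_dir, alpha)
    return summary


def _scatter_plots(df, correlations, plot_dir, alpha):
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(plot_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig = correlations[(correlations["p"] < alpha) & correlations["r"].notna()]
    for _, row in sig.iterrows():
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(df[row["var1"]], df[row["var2"]], s=12)
        ax.set_xlabel(row["var1"])
        ax.set_ylabel(row["var2"])
        ax.set_title(f"r = {row['r']:.3f}, R² = {row['r_squared']:.3f}")
        fig.tight_layout()
        fig.savefig(out / f"scatter_{row['var1']}_{row['var2']}.png", dpi=100)
        plt.close(fig)
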