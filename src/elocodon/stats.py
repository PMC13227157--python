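"""Two-group testing, multiple-testing correction and percentiles.

The comparisons throughout the pipeline all go through one dispatch rule:
each group is first checked for normality (Shapiro–Wilk for n <= 5000,
Anderson–Darling above that, where Shapiro–Wilk loses power and scipy's
implementation is no longer calibrated); if both groups look normal the
groups are compared with Welch's t-test, otherwise with the two-sided
Wilcoxon–Mann–Whitney test.  P-values from families of related hypotheses
are adjusted with the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PhenotypeComparison",
    "two_group_test",
    "bh_adjust",
    "percentile",
    "phenotype_percent_difference",
    "analyze_phenotype_table",
]

#: number of observations above which Anderson–Darling replaces Shapiro–Wilk
SHAPIRO_MAX_N = 5000

#: sample size at or below which the Wilcoxon–Mann–Whitney p-value is exact
WMW_EXACT_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    """Outcome of a normality-dispatched two-group comparison."""

    statistic: float
    pvalue: float
    method: str  # "welch_t" | "wilcoxon_mann_whitney"
    normality_a: bool
    normality_b: bool
    normality_test: str  # "shapiro_wilk" | "anderson_darling"
    n_a: int
    n_b: int


@dataclass
class PhenotypeComparison:
    """Per-observation percent differences of a trait versus a control group."""

    trait: str
    group: str
    values_d: list[float]
    mean_d: float
    sd_d: float
    test_vs_control: TestResult
    test_vs_wt: TestResult | None = field(default=None)


def _is_normal(x: np.ndarray, alpha: float) -> tuple[bool, str]:
    """Normality verdict for one sample plus the name of the test used."""
    n = x.size
    test = "shapiro_wilk" if n <= SHAPIRO_MAX_N else "anderson_darling"
    if np.ptp(x) == 0:
        # a constant sample carries no distributional information; treat as
        # non-normal so the rank test (which copes with ties) is used
        return False, test
    if test == "shapiro_wilk":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = sps.shapiro(x).pvalue
    else:
        _, p = normal_ad(x)
    return bool(p > alpha), test


def two_group_test(
    x,
    y,
    alpha_norm: float = 0.05,
    method: str = "auto",
) -> TestResult:
    """Compare two samples with the normality-dispatched two-sided test.

    Parameters
    ----------
    x, y
        The two samples; each must contain at least 3 finite values.
    alpha_norm
        Significance level of the per-group normality check.  Both groups
        must pass for Welch's t-test to be used.
    method
        ``"auto"`` applies the dispatch rule; ``"welch_t"`` or
        ``"wilcoxon_mann_whitney"`` force a branch (normality is still
        reported for the record).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 3 or y.size < 3:
        raise ValueError(
            f"each group needs >= 3 observations (got {x.size} and {y.size})"
        )
    norm_x, ntest = _is_normal(x, alpha_norm)
    norm_y, _ = _is_normal(y, alpha_norm)

    if method == "auto":
        chosen = "welch_t" if (norm_x and norm_y) else "wilcoxon_mann_whitney"
    elif method in ("welch_t", "wilcoxon_mann_whitney"):
        chosen = method
    else:
        raise ValueError(f"unknown method {method!r}")

    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        # degenerate: both groups constant and equal — no evidence of difference
        return TestResult(0.0, 1.0, chosen, norm_x, norm_y, ntest, x.size, y.size)

    if chosen == "welch_t":
        res = sps.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        exact = min(x.size, y.size) <= WMW_EXACT_MAX_N and not ties
        res = sps.mannwhitneyu(
            x, y,
            alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(stat, min(p, 1.0), chosen, norm_x, norm_y, ntest, x.size, y.size)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving.

    Missing values (NaN) are passed through unchanged and do not count
    toward the number of hypotheses.  Adjusted values are clipped at 1.
    Note the procedure is not idempotent: re-adjusting already adjusted
    values generally inflates them further.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    valid = p[mask]
    if valid.size and (valid.min() < 0 or valid.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if valid.size:
        out[mask] = multipletests(valid, method="fdr_bh")[1]
    return out


def percentile(values, q: float) -> float:
    """Percentile by linear interpolation between order statistics.

    The cut sits at position ``1 + (q/100)*(n-1)`` of the sorted sample
    (1-based), so ``q=0`` is the minimum and ``q=100`` the maximum.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("percentile of an empty sample")
    if not 0 <= q <= 100:
        raise ValueError(f"q must be in [0, 100], got {q}")
    return float(np.percentile(v, q))


def phenotype_percent_difference(treated, control, trait: str = "", group: str = "") -> PhenotypeComparison:
    """Per-observation percent difference of a treated group versus control.

    For each treated observation ``F_a`` the statistic is
    ``D = 100 * (F_a - mean(control)) / mean(control)``; the comparison also
    carries the dispatch test between the raw treated and control values.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 3 or c.size < 3:
        raise ValueError("both samples need >= 3 observations")
    cbar = float(c.mean())
    if cbar == 0 or not math.isfinite(cbar):
        raise ValueError("control mean is zero or non-finite; percent difference undefined")
    d = 100.0 * (t - cbar) / cbar
    return PhenotypeComparison(
        trait=trait,
        group=group,
        values_d=[float(v) for v in d],
        mean_d=float(d.mean()),
        sd_d=float(d.std(ddof=1)),
        test_vs_control=two_group_test(t, c),
    )


def analyze_phenotype_table(
    df,
    control_treatment: str = "control",
    wt_genotype: str = "WT",
):
    """Percent-difference analysis of a long-format phenotype table.

    Expects columns ``seedling_id, genotype, treatment, trait, value``.
    For every (trait, genotype, non-control treatment) cell the treated
    observations are compared with that genotype's control group; the
    per-observation D values of each mutant are additionally tested
    against the wild type's D values under the same treatment.  P-values
    of each contrast family are BH-adjusted per trait.
    """
    import pandas as pd

    required = {"genotype", "treatment", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing column(s) {sorted(missing)}")
    rows = []
    d_values: dict[tuple, np.ndarray] = {}
    for (trait, genotype, treatment), sub in df.groupby(["trait", "genotype", "treatment"]):
        if treatment == control_treatment:
            continue
        control = df[
            (df["trait"] == trait)
            & (df["genotype"] == genotype)
            & (df["treatment"] == control_treatment)
        ]["value"]
        if len(sub) < 3 or len(control) < 3:
            continue
        cmp = phenotype_percent_difference(
            sub["value"], control, trait=trait, group=f"{genotype}/{treatment}"
        )
        d_values[(trait, genotype, treatment)] = np.asarray(cmp.values_d)
        rows.append({
            "trait": trait,
            "genotype": genotype,
            "treatment": treatment,
            "n": len(sub),
            "mean_d": cmp.mean_d,
            "sd_d": cmp.sd_d,
            "p_vs_control": cmp.test_vs_control.pvalue,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    p_vs_wt = []
    for _, r in out.iterrows():
        key_wt = (r["trait"], wt_genotype, r["treatment"])
        key = (r["trait"], r["genotype"], r["treatment"])
        if r["genotype"] != wt_genotype and key_wt in d_values:
            p_vs_wt.append(two_group_test(d_values[key], d_values[key_wt]).pvalue)
        else:
            p_vs_wt.append(np.nan)
    out["p_vs_wt"] = p_vs_wt
    out["padj_vs_control"] = np.nan
    out["padj_vs_wt"] = np.nan
    for trait, idx in out.groupby("trait").groups.items():
        out.loc[idx, "padj_vs_control"] = bh_adjust(out.loc[idx, "p_vs_control"])
        out.loc[idx, "padj_vs_wt"] = bh_adjust(out.loc[idx, "p_vs_wt"])
    return out
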