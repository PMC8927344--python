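"""Clinical cohort statistics for two-arm (cSI vs cSII/III) comparisons.

Exact and asymptotic tests for the characteristics table of a two-arm
cohort: the two-sided Fisher exact test on 2x2 tables (minimum-likelihood
rule: the two-sided p sums the probabilities of all margin-consistent
tables no more probable than the observed one), the Pearson chi-square
test, t-tests from printed summary statistics (pooled Student by default,
which is what small clinical tables conventionally report), the
Mann-Whitney U test for non-normal variables, and the ddCt relative
quantification used for qPCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("contingency cells must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("contingency cells must be integers")
        arr = np.round(arr).astype(int)
    return arr


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher exact p for a 2x2 table.

    Two-sided p follows the minimum-likelihood rule; ``alternative`` may
    also be "greater" or "less" for one-tailed hypergeometric tails.  A
    table with an empty margin carries no information: p = 1.
    """
    arr = _as_2x2(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table: (statistic, p), df = 1.

    ``yates`` applies the continuity correction.  Zero expected counts are
    an error — use the exact test for such tables.
    """
    arr = _as_2x2(table)
    expected = stats.contingency.expected_freq(arr)
    if (expected == 0).any():
        raise ValueError("zero expected count; use fisher_exact_2x2 instead")
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupSummary:
    """Printed per-arm summary: mean, SD and n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be non-negative")
        if self.n < 2:
            raise ValueError("summary t-test needs n >= 2 per group")


def t_test_from_summary(
    a: GroupSummary, b: GroupSummary, pooled: bool = True
) -> tuple[float, float, float]:
    """Two-sided t-test from summary statistics: (t, df, p).

    Pooled-variance Student by default; ``pooled=False`` gives Welch.
    Both SDs zero with equal means gives t = 0, p = 1.
    """
    if a.sd == 0.0 and b.sd == 0.0:
        df = float(a.n + b.n - 2)
        if a.mean == b.mean:
            return 0.0, df, 1.0
        return float(np.sign(a.mean - b.mean) * np.inf), df, 0.0
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled
    )
    if pooled:
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U, p).

    Exact enumeration when both groups have n <= 8, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CtQuadruple:
    """qPCR cycle thresholds: target and reference gene in case and control."""

    target_case: float
    ref_case: float
    target_control: float
    ref_control: float

    def __post_init__(self) -> None:
        for v in (self.target_case, self.ref_case, self.target_control, self.ref_control):
            if v <= 0:
                raise ValueError("CT values must be positive")


def delta_delta_ct(ct: CtQuadruple) -> float:
    """Relative expression fold change by the ddCt method.

    dCt = Ct_target - Ct_reference per condition; ddCt = dCt_case -
    dCt_control; fold change = 2**(-ddCt).
    """
    d_case = ct.target_case - ct.ref_case
    d_control = ct.target_control - ct.ref_control
    return float(2.0 ** -(d_case - d_control))


@dataclass(frozen=True)
class VariableSpec:
    """Declares how one clinical variable is summarized and tested."""

    name: str
    kind: str  # "categorical" | "continuous" | "nonparametric"

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous", "nonparametric"):
            raise ValueError(f"unknown variable kind {self.kind!r}")


def build_table_one(
    records: pd.DataFrame,
    specs: Sequence[VariableSpec],
    arm_column: str = "stage",
) -> pd.DataFrame:
    """Characteristics table with one row per variable level and per-arm p.

    Categorical variables get level counts (and percents) per arm with a
    chi-square p, automatically replaced by the Fisher exact test when the
    table is 2x2 and any expected cell is below 5.  Continuous variables
    get mean +- SD per arm with a pooled t-test p; nonparametric ones a
    Mann-Whitney p.  Exactly two arms are required.
    """
    arms = sorted(records[arm_column].dropna().unique())
    if len(arms) != 2:
        raise ValueError(f"need exactly 2 arms, got {arms}")
    arm_a, arm_b = arms
    grp_a = records[records[arm_column] == arm_a]
    grp_b = records[records[arm_column] == arm_b]

    rows = []
    for spec in specs:
        col = spec.name
        if col not in records.columns:
            raise ValueError(f"variable {col!r} not in records")
        if spec.kind == "categorical":
            ct = pd.crosstab(records[col], records[arm_column])
            ct = ct.reindex(columns=arms, fill_value=0)
            test = "chi2"
            if ct.shape == (2, 2):
                expected = stats.contingency.expected_freq(ct.to_numpy())
                if (expected < 5).any():
                    test = "fisher"
            if test == "fisher":
                p = fisher_exact_2x2(ct.to_numpy())
            else:
                p = float(stats.chi2_contingency(ct.to_numpy()).pvalue)
            for i, level in enumerate(ct.index):
                na, nb = ct.loc[level, arm_a], ct.loc[level, arm_b]
                rows.append(
                    {
                        "variable": col,
                        "level": str(level),
                        arm_a: f"{na} ({100 * na / max(len(grp_a), 1):.1f})",
                        arm_b: f"{nb} ({100 * nb / max(len(grp_b), 1):.1f})",
                        "test": test,
                        "p": p if i == 0 else np.nan,
                    }
                )
        else:
            va = grp_a[col].dropna().astype(float)
            vb = grp_b[col].dropna().astype(float)
            if spec.kind == "continuous":
                summary_a = GroupSummary(va.mean(), va.std(ddof=1), len(va))
                summary_b = GroupSummary(vb.mean(), vb.std(ddof=1), len(vb))
                _, _, p = t_test_from_summary(summary_a, summary_b, pooled=True)
                test = "t"
            else:
                _, p = mann_whitney(va, vb)
                test = "mann-whitney"
            rows.append(
                {
                    "variable": col,
                    "level": "mean±SD",
                    arm_a: f"{va.mean():.1f} ± {va.std(ddof=1):.1f}",
                    arm_b: f"{vb.mean():.1f} ± {vb.std(ddof=1):.1f}",
                    "test": test,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
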