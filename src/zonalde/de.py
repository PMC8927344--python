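"""Two-group differential expression per tumour zone.

Each contrast compares the non-metastatic arm (cSI) against the metastatic
arm (cSII/III) within one zone (TF or TC).  Tests run on log2(normalized
count + 1); fold changes are reported on the linear normalized scale with
the signed convention r when r >= 1 and -1/r otherwise, so "FC > +-2"
means |signed FC| > 2.  Three selection regimes are flagged per gene:
|FC| >= 1.5 & p <= 0.05 (heatmap/pathway input), |FC| > 2 & p < 0.05
(immune subset / regulator input), and BH-FDR q < 0.05 & |FC| > 1.5
(enrichment input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from zonalde.rcc import CodeClass, CountMatrix, SampleAnnotation


def log2_transform(values: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log2(value + offset); values must be non-negative."""
    if (values.to_numpy() < 0).any():
        raise ValueError("log2_transform requires non-negative values")
    return np.log2(values + offset)


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Linear ratio mean_b/mean_a as a signed fold change.

    Returns r when r >= 1 and -1/r otherwise, so the magnitude is always
    >= 1 and the sign gives the direction of group b relative to group a.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("signed fold change needs positive means")
    r = mean_b / mean_a
    return r if r >= 1.0 else -1.0 / r


def welch_t(values_a, values_b, pooled: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t-test: (t, df, p).

    Welch (unequal-variance, Satterthwaite df) by default; ``pooled=True``
    gives the classical pooled-variance Student variant.  Groups with both
    variances zero and equal means give t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(b.mean() - a.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(b, a, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ContrastSpec:
    """One zone's two-arm comparison; fold changes point group_b vs group_a."""

    region: str  # "TF" or "TC"
    group_a: str = "cSI"
    group_b: str = "cSII_III"

    @property
    def name(self) -> str:
        return f"{self.region}_{self.group_a}_vs_{self.group_b}"


@dataclass(frozen=True)
class DEThresholds:
    """The three selection regimes applied to a DE table."""

    regime1_fc: float = 1.5   # |FC| >= fc and p <= p (inclusive)
    regime1_p: float = 0.05
    regime2_fc: float = 2.0   # |FC| > fc and p < p (strict)
    regime2_p: float = 0.05
    regime3_fc: float = 1.5   # |FC| > fc and q < q (strict)
    regime3_q: float = 0.05


@dataclass
class DEResult:
    spec: ContrastSpec
    table: pd.DataFrame
    thresholds: DEThresholds

    def genes(self, regime: int) -> list[str]:
        return list(self.table.index[self.table[f"pass_regime{regime}"]])

    def directions(self, regime: int) -> pd.Series:
        sel = self.table[self.table[f"pass_regime{regime}"]]
        return np.sign(sel["fc"]).astype(int)


def run_contrast(
    matrix: CountMatrix,
    annotation: SampleAnnotation,
    spec: ContrastSpec,
    expressed: list[str] | None = None,
    thresholds: DEThresholds = DEThresholds(),
    pooled: bool = False,
    mean_floor: float = 1.0,
) -> DEResult:
    """Differential expression over the expressed endogenous genes of one zone.

    ``matrix`` must be normalized.  Group means for the fold change are
    computed on the linear normalized scale and floored at ``mean_floor``
    (background subtraction can zero a group mean); t-tests run on
    log2(count + 1).  BH correction spans exactly the tested genes.
    """
    if not matrix.normalized:
        raise ValueError("run_contrast requires a normalized matrix")
    ids_a = annotation.samples_for(region=spec.region, stage=spec.group_a)
    ids_b = annotation.samples_for(region=spec.region, stage=spec.group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"contrast {spec.name}: each group needs n >= 2 "
            f"(got {len(ids_a)}, {len(ids_b)})"
        )
    genes = expressed if expressed is not None else matrix.class_probes(
        CodeClass.ENDOGENOUS
    )
    sub = matrix.counts.loc[genes]
    lin_a, lin_b = sub[ids_a], sub[ids_b]
    log_a = log2_transform(lin_a).to_numpy()
    log_b = log2_transform(lin_b).to_numpy()

    mean_a = lin_a.mean(axis=1).clip(lower=mean_floor)
    mean_b = lin_b.mean(axis=1).clip(lower=mean_floor)
    fc = np.array(
        [signed_fold_change(a, b) for a, b in zip(mean_a, mean_b)]
    )
    res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=pooled)
    t = np.asarray(res.statistic, dtype=float)
    df = np.asarray(res.df, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # rows with zero variance in both groups: t=0, p=1 when means agree
    degenerate = ~np.isfinite(t)
    for i in np.where(degenerate)[0]:
        t[i], df[i], p[i] = welch_t(log_a[i], log_b[i], pooled=pooled)
    q = benjamini_hochberg(p)

    th = thresholds
    table = pd.DataFrame(
        {
            "code_class": matrix.code_class.loc[genes],
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
        },
        index=pd.Index(genes, name="gene"),
    )
    table["pass_regime1"] = (np.abs(fc) >= th.regime1_fc) & (p <= th.regime1_p)
    table["pass_regime2"] = (np.abs(fc) > th.regime2_fc) & (p < th.regime2_p)
    table["pass_regime3"] = (np.abs(fc) > th.regime3_fc) & (q < th.regime3_q)
    return DEResult(spec=spec, table=table, thresholds=th)


def select_by_thresholds(
    fc, p, fc_min: float, p_max: float, strict: bool = False
):
    """Boolean mask for a |FC|/p threshold regime (inclusive or strict)."""
    fc = np.asarray(fc, dtype=float)
    p = np.asarray(p, dtype=float)
    if strict:
        return (np.abs(fc) > fc_min) & (p < p_max)
    return (np.abs(fc) >= fc_min) & (p <= p_max)
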