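"""Three-step nCounter normalization and the expression-presence filter.

The raw count matrix is processed sequentially: (1) per-sample background
subtraction using the negative-control probes, with threshold
``multiplier * (mean + 2*SD)`` of the negative counts (multiplier 2 by
default); (2) a positive-control normalization factor — the ratio of the
cohort-average geometric mean of the positive probes to each sample's
geometric mean, flagged when outside the 0.3-3.0 acceptance band; (3) a
housekeeping (CodeSet content) factor built the same way over reference
genes selected by the geNorm stability algorithm.  Endogenous genes then
pass a presence filter: at least ``min_count`` counts in at least
``min_frac`` of the samples of one of the contrast groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from zonalde.rcc import CodeClass, CountMatrix

POSITIVE_FACTOR_BAND = (0.3, 3.0)


def background_thresholds(matrix: CountMatrix, multiplier: float = 2.0) -> pd.Series:
    """Per-sample background threshold from that sample's Negative probes.

    T_s = multiplier * (mean_s + 2 * SD_s), with the sample (n-1) SD.
    Requires at least two Negative probes per sample.
    """
    neg = matrix.class_counts(CodeClass.NEGATIVE)
    if len(neg) < 2:
        raise ValueError("need >=2 Negative probes to estimate background SD")
    t = multiplier * (neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1))
    t.name = "background_threshold"
    return t


def subtract_background(matrix: CountMatrix, thresholds: pd.Series) -> CountMatrix:
    """Subtract each sample's threshold from its Endogenous and Housekeeping
    counts, flooring at zero; control probes are left untouched."""
    missing = [s for s in matrix.samples if s not in thresholds.index]
    if missing:
        raise ValueError(f"thresholds missing for samples: {missing}")
    counts = matrix.counts.astype(float).copy()
    rows = matrix.class_probes(CodeClass.ENDOGENOUS) + matrix.class_probes(
        CodeClass.HOUSEKEEPING
    )
    sub = counts.loc[rows].sub(thresholds[matrix.samples], axis=1)
    counts.loc[rows] = sub.clip(lower=0.0)
    return matrix.copy_with(counts)


def _geomean(df: pd.DataFrame) -> pd.Series:
    return np.exp(np.log(df).mean(axis=0))


def positive_factor(
    matrix: CountMatrix, band: tuple[float, float] = POSITIVE_FACTOR_BAND
) -> tuple[pd.Series, pd.Series]:
    """Positive-control factor per sample and its acceptance-band flag.

    f_s = (arithmetic mean over samples of the positive-probe geometric
    means) / (this sample's geometric mean).  The flag is True when f_s
    falls outside ``band`` (default 0.3-3.0).
    """
    pos = matrix.class_counts(CodeClass.POSITIVE)
    if pos.empty:
        raise ValueError("no Positive probes")
    if (pos.to_numpy() <= 0).any():
        bad = pos.columns[(pos <= 0).any(axis=0)].tolist()
        raise ValueError(f"zero positive-control count in samples {bad}")
    g = _geomean(pos)
    factors = g.mean() / g
    factors.name = "positive_factor"
    lo, hi = band
    flags = (factors < lo) | (factors > hi)
    flags.name = "positive_factor_out_of_band"
    return factors, flags


def genorm_stability(expression: pd.DataFrame) -> pd.Series:
    """geNorm stability M per candidate reference gene.

    ``expression`` holds strictly positive linear expression values,
    candidates as rows and samples as columns.  For candidate j,
    M_j = mean over all other candidates k of the across-sample SD of the
    log2 ratio log2 x_j - log2 x_k; lower M means more stable.
    """
    if len(expression) < 2:
        raise ValueError("geNorm needs >=2 candidate genes")
    if expression.shape[1] < 2:
        raise ValueError("geNorm needs >=2 samples")
    if (expression.to_numpy() <= 0).any():
        raise ValueError("geNorm requires strictly positive expression values")
    log2x = np.log2(expression.to_numpy(dtype=float))
    n = len(expression)
    # pairwise SDs of log-ratios; diff of gene j and k across samples
    m = np.empty(n)
    for j in range(n):
        diffs = log2x[j][None, :] - log2x  # n x samples
        sds = diffs.std(axis=1, ddof=1)
        m[j] = np.delete(sds, j).mean()
    return pd.Series(m, index=expression.index, name="M")


@dataclass
class GeNormResult:
    """Outcome of iterative geNorm selection.

    ``stability`` holds the first-round M per candidate, ``final_stability``
    the M of the selected set in the last round; candidates in
    ``exclusion_order`` were removed first-to-last.
    """

    stability: pd.Series
    final_stability: pd.Series
    exclusion_order: list[str]
    selected: list[str]

    def report(self) -> pd.DataFrame:
        rows = []
        for i, probe in enumerate(self.exclusion_order, start=1):
            rows.append((probe, self.stability[probe], i))
        for probe in self.selected:
            rows.append((probe, self.stability[probe], 0))
        df = pd.DataFrame(rows, columns=["probe", "M", "round_excluded"])
        return df.sort_values(["round_excluded", "probe"]).reset_index(drop=True)


def genorm_select(
    expression: pd.DataFrame,
    stop: str = "m_threshold",
    m_max: float = 0.5,
    min_genes: int = 3,
    keep_n: int | None = None,
) -> GeNormResult:
    """Iteratively exclude the least stable candidate until the stop rule holds.

    Two stop rules: ``"m_threshold"`` (default) stops when every remaining M
    is below ``m_max``, never going below ``min_genes`` genes;
    ``"keep_n"`` stops at exactly ``keep_n`` genes.  Ties on the maximal M
    are broken lexicographically by probe name (the first name is excluded),
    so selection is deterministic.
    """
    if stop not in ("m_threshold", "keep_n"):
        raise ValueError(f"unknown stop rule {stop!r}")
    if stop == "keep_n":
        if keep_n is None:
            raise ValueError("keep_n stop rule requires keep_n")
        if keep_n < 2:
            raise ValueError("cannot keep fewer than 2 reference genes")
        if keep_n > len(expression):
            raise ValueError(
                f"keep_n={keep_n} exceeds {len(expression)} candidates"
            )
    if min_genes < 2:
        raise ValueError("min_genes must be >=2")

    initial = genorm_stability(expression)
    remaining = expression.copy()
    excluded: list[str] = []
    while True:
        m = genorm_stability(remaining)
        if stop == "keep_n":
            if len(remaining) == keep_n:
                break
        else:
            if (m < m_max).all() or len(remaining) <= min_genes:
                break
        if len(remaining) == 2:
            break  # never drop below a usable pair
        worst = m[m == m.max()].index.min()  # lexicographic tie-break
        excluded.append(worst)
        remaining = remaining.drop(index=worst)
    return GeNormResult(
        stability=initial,
        final_stability=m,
        exclusion_order=excluded,
        selected=sorted(remaining.index),
    )


def housekeeping_factor(
    matrix: CountMatrix,
    selected: Sequence[str],
    positive: pd.Series | None = None,
) -> pd.Series:
    """Housekeeping (CodeSet content) factor over the selected references.

    Same geometric-mean-ratio construction as the positive factor.  The
    steps are sequential, so when the per-sample positive factors are
    passed the reference counts are first put on the positive-normalized
    scale; otherwise the sample scale would be corrected twice when both
    factors are applied.  Counts of zero (possible after background
    subtraction) enter the geometric mean as 1 for the factor computation
    only; the matrix is unchanged.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("no reference genes selected")
    missing = [g for g in selected if g not in matrix.counts.index]
    if missing:
        raise ValueError(f"reference genes absent from matrix: {missing}")
    refs = matrix.counts.loc[selected].clip(lower=1.0)
    if positive is not None:
        refs = refs.mul(positive[matrix.samples], axis=1)
    g = _geomean(refs)
    factors = g.mean() / g
    factors.name = "housekeeping_factor"
    return factors


@dataclass
class NormalizationFactors:
    """Per-sample positive and housekeeping factors plus QC flags."""

    positive: pd.Series
    housekeeping: pd.Series
    out_of_band: pd.Series
    band: tuple[float, float] = POSITIVE_FACTOR_BAND

    def __post_init__(self) -> None:
        if (self.positive <= 0).any() or (self.housekeeping <= 0).any():
            raise ValueError("normalization factors must be positive")

    def report(self, thresholds: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "f_pos": self.positive,
                "band_flag": self.out_of_band,
                "f_hk": self.housekeeping,
            }
        )
        if thresholds is not None:
            df.insert(0, "T_s", thresholds)
        df.index.name = "sample_id"
        return df


def apply_normalization(
    matrix: CountMatrix, factors: NormalizationFactors
) -> CountMatrix:
    """Scale every count by its sample's combined factor f_pos * f_hk.

    Refuses to run on a matrix already flagged as normalized.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    combined = factors.positive[matrix.samples] * factors.housekeeping[matrix.samples]
    counts = matrix.counts.astype(float).mul(combined, axis=1)
    return matrix.copy_with(counts, normalized=True)


@dataclass
class PresenceFilterResult:
    """Expressed endogenous genes and the per-gene per-group pass fractions."""

    expressed: list[str]
    pass_fraction: pd.DataFrame  # genes x groups
    min_count: float
    min_frac: float


def presence_filter(
    matrix: CountMatrix,
    groups: Mapping[str, Sequence[str]],
    min_count: float = 40.0,
    min_frac: float = 0.25,
) -> PresenceFilterResult:
    """Keep endogenous genes detected in at least one group.

    A gene passes when the fraction of samples with count >= ``min_count``
    reaches ``min_frac`` in at least one group (default: 40 counts in 25%
    of samples).
    """
    for name, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"empty group {name!r}")
    endo = matrix.class_counts(CodeClass.ENDOGENOUS)
    fractions = pd.DataFrame(
        {
            name: (endo[list(ids)] >= min_count).mean(axis=1)
            for name, ids in groups.items()
        }
    )
    keep = fractions.ge(min_frac).any(axis=1)
    return PresenceFilterResult(
        expressed=list(fractions.index[keep]),
        pass_fraction=fractions,
        min_count=min_count,
        min_frac=min_frac,
    )
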