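import numpy as np
import pandas as pd
import pytest

from zonalde.rcc import CountMatrix, SampleAnnotation


RCC_TEXT = """<Header>
FileVersion,1.7
SoftwareVersion,4.0.0.3
</Header>
<Sample_Attributes>
ID,S01
Owner,lab
</Sample_Attributes>
<Lane_Attributes>
ID,1
FovCount,280
FovCounted,275
BindingDensity,0.75
</Lane_Attributes>
<Code_Summary>
CodeClass,Name,Accession,Count
Endogenous,IL6,NM_000600.3,42
Endogenous,IL1B,NM_000576.2,7
Housekeeping,ACTB,NM_001101.3,900
Positive,POS_A,ERCC_00117.1,12000
Positive,POS_B,ERCC_00112.1,3000
Negative,NEG_A,ERCC_00096.1,3
Negative,NEG_B,ERCC_00041.1,5
</Code_Summary>
<Messages>
</Messages>
"""


@pytest.fixture
def rcc_text():
    return RCC_TEXT


def make_matrix(counts: dict, classes: dict, normalized=False) -> CountMatrix:
    df = pd.DataFrame(counts, dtype=float)
    return CountMatrix(df, pd.Series(classes), normalized=normalized)


@pytest.fixture
def tiny_matrix():
    """2 endogenous + 2 HK + 2 positive + 2 negative probes, 3 samples."""
    counts = {
        "S1": [100, 50, 200, 400, 1000, 250, 4, 6],
        "S2": [120, 40, 210, 390, 1100, 260, 5, 5],
        "S3": [90, 60, 190, 410, 900, 240, 6, 4],
    }
    index = ["GENE1", "GENE2", "HK1", "HK2", "POS_A", "POS_B", "NEG_A", "NEG_B"]
    classes = dict(
        zip(
            index,
            [
                "Endogenous",
                "Endogenous",
                "Housekeeping",
                "Housekeeping",
                "Positive",
                "Positive",
                "Negative",
                "Negative",
            ],
        )
    )
    df = pd.DataFrame(counts, index=index, dtype=float)
    return CountMatrix(df, pd.Series(classes))


@pytest.fixture
def two_group_annotation():
    rows = []
    for i in range(1, 5):
        stage = "cSI" if i <= 2 else "cSII_III"
        for region in ("TF", "TC"):
            rows.append(
                {
                    "sample_id": f"P{i}_{region}",
                    "patient_id": f"P{i}",
                    "region": region,
                    "stage": stage,
                }
            )
    return SampleAnnotation(pd.DataFrame(rows))


# ---- independent oracles -------------------------------------------------


def hypergeom_prob(a, r1, r2, c1):
    """P of a 2x2 table [[a, r1-a], [c1-a, r2-c1+a]] given all margins."""
    from math import comb

    n = r1 + r2
    return comb(r1, a) * comb(r2, c1 - a) / comb(n, c1)


def fisher_two_sided_oracle(table):
    """Minimum-likelihood two-sided Fisher by complete enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    p_obs = hypergeom_prob(a, r1, r2, c1)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom_prob(aa, r1, r2, c1)
        if p <= p_obs * (1 + 1e-10):
            total += p
    return min(total, 1.0)


def fisher_right_oracle(table):
    """Right tail P(X >= a) by enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    return sum(
        hypergeom_prob(aa, r1, r2, c1)
        for aa in range(a, min(r1, c1) + 1)
    )


def bh_oracle(p):
    """Step-up BH q-values computed literally from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q_sorted[rank - 1] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def genorm_m_oracle(expression: pd.DataFrame) -> pd.Series:
    """Brute-force geNorm M: double loop over candidate pairs."""
    import statistics

    log2x = np.log2(expression)
    out = {}
    for j in expression.index:
        sds = []
        for k in expression.index:
            if k == j:
                continue
            ratios = (log2x.loc[j] - log2x.loc[k]).tolist()
            sds.append(statistics.stdev(ratios))
        out[j] = sum(sds) / len(sds)
    return pd.Series(out)
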