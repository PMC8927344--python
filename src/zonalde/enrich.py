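"""Gene-set enrichment and upstream-regulator activation statistics.

Reimplements the statistics of knowledge-base pathway tools against
user-supplied content: the overlap ratio (dataset genes mapping to a set
divided by the set's size), a right-tailed Fisher/hypergeometric
enrichment p, and the activation z-score over a signed regulator->target
network — z = (agreements - disagreements)/sqrt(n) across the n network
edges whose targets are in the differentially expressed selection, with
|z| >= 2 calling a regulator Activated or Inhibited.  Symbol matching is
exact (case-sensitive, whitespace-stripped): silent fuzzy matching breeds
irreproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-derived); names unique, sets nonempty."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(stream) -> GeneSetCollection:
    """Parse GMT text (tab-separated: name, description, genes...)."""
    text = stream if isinstance(stream, str) else stream.read()
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
        name, desc, *genes = fields
        name = name.strip()
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        cleaned = [g.strip() for g in genes if g.strip()]
        if not cleaned:
            raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
        sets[name] = frozenset(cleaned)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection) -> str:
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "")
        genes = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{desc}\t{genes}")
    return "\n".join(lines) + "\n"


@dataclass
class RegulatorNetwork:
    """Signed regulator->target edges; optional per-edge weights.

    ``edges`` columns: regulator, target, sign (+1/-1) and optionally
    weight (> 0); one row per (regulator, target) pair.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"regulator", "target", "sign"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"network missing columns: {sorted(missing)}")
        if self.edges.duplicated(subset=["regulator", "target"]).any():
            dup = self.edges[self.edges.duplicated(subset=["regulator", "target"])]
            raise ValueError(
                f"duplicate edges: {dup[['regulator', 'target']].values.tolist()}"
            )
        if not self.edges["sign"].isin([1, -1]).all():
            raise ValueError("edge signs must be +1 or -1")
        if "weight" not in self.edges.columns:
            self.edges = self.edges.assign(weight=1.0)
        elif (self.edges["weight"] <= 0).any():
            raise ValueError("edge weights must be positive")
        self.edges = self.edges.reset_index(drop=True)

    @property
    def regulators(self) -> list[str]:
        return sorted(self.edges["regulator"].unique())

    def targets_of(self, regulator: str) -> pd.DataFrame:
        return self.edges[self.edges["regulator"] == regulator]

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegulatorNetwork":
        return cls(pd.read_csv(path, sep="\t"))


def overlap_ratio(de_genes: Iterable[str], gene_set: Iterable[str]) -> float:
    """|de_genes ∩ set| / |set| — the 'Ratio' column of enrichment tables."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    return len(set(de_genes) & gene_set) / len(gene_set)


def fisher_enrichment(
    de_genes: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> float:
    """Right-tailed Fisher p for over-representation of ``gene_set``.

    Hypergeometric tail P(X >= overlap) on the 2x2 of set membership vs
    dataset membership, with the set first intersected with the universe.
    """
    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    in_set = set(gene_set) & universe
    overlap = len(de & in_set)
    # P(X >= overlap), X ~ Hypergeom(N=|universe|, K=|set|, n=|de|)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(in_set), len(de)))


def activation_zscore(
    directions: Mapping[str, int], edges: pd.DataFrame
) -> tuple[float, int]:
    """Activation z of one regulated entity against observed directions.

    ``directions`` maps differentially expressed genes to their observed
    direction (+1 up, -1 down); ``edges`` holds this entity's target rows
    (columns target, sign and optionally weight).  Over the n edges whose
    targets appear in ``directions``, agreement a_i = sign_i * dir_i and
    z = sum(w_i a_i)/sqrt(sum(w_i^2)) (all w_i = 1 unless given).  Returns
    (z, n); z is NaN when no target is in the dataset.
    """
    hits = edges[edges["target"].isin(directions.keys())]
    n = len(hits)
    if n == 0:
        return float("nan"), 0
    sign = hits["sign"].to_numpy(dtype=float)
    obs = np.array([directions[t] for t in hits["target"]], dtype=float)
    w = (
        hits["weight"].to_numpy(dtype=float)
        if "weight" in hits.columns
        else np.ones(n)
    )
    z = float((w * sign * obs).sum() / math.sqrt((w**2).sum()))
    return z, n


def enrichment_table(
    de_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    directions: Mapping[str, int] | None = None,
    network: RegulatorNetwork | None = None,
) -> pd.DataFrame:
    """Per-set enrichment: overlap, ratios, Fisher p, -log10 p and z.

    ``ratio_full`` divides by the full set size (the convention of printed
    pathway tables); ``ratio_universe`` by the set restricted to the
    universe.  The activation z is computed when ``network`` carries signed
    edges whose regulator is the set name, otherwise NaN.
    """
    de = set(de_genes)
    universe = set(universe)
    rows = []
    for name, genes in collection.items():
        in_universe = genes & universe
        overlap = sorted(de & in_universe)
        p = fisher_enrichment(de, genes, universe)
        z, n_edges = float("nan"), 0
        if network is not None and directions is not None:
            z, n_edges = activation_zscore(directions, network.targets_of(name))
        rows.append(
            {
                "set": name,
                "n_set": len(genes),
                "n_overlap": len(overlap),
                "ratio_full": len(overlap) / len(genes),
                "ratio_universe": (
                    len(overlap) / len(in_universe) if in_universe else 0.0
                ),
                "p": p,
                "minus_log10_p": -math.log10(p) if p > 0 else math.inf,
                "z": z,
                "n_edges": n_edges,
                "molecules": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows).set_index("set")
    return df.sort_values(["p", "set"], kind="mergesort")


ACTIVATED = "Activated"
INHIBITED = "Inhibited"
UNDETERMINED = "Undetermined"


def upstream_regulator_table(
    de_table: pd.DataFrame,
    network: RegulatorNetwork,
    universe: Iterable[str],
    z_min: float = 2.0,
    fc_min: float = 2.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Rank candidate upstream regulators by activation z-score.

    ``de_table`` is a per-gene frame with ``fc`` and ``p`` columns (a
    :class:`zonalde.de.DEResult` table).  Genes passing |FC| > fc_min and
    p < p_max form the regulated selection; each regulator in the network
    is scored by activation_zscore over its targets in that selection and
    by the Fisher overlap p of its full target set.  State is Activated
    when z >= z_min, Inhibited when z <= -z_min, else Undetermined.
    Sorted by z descending (NaN last), ties broken by regulator name.
    """
    universe = set(universe)
    mask = (de_table["fc"].abs() > fc_min) & (de_table["p"] < p_max)
    selected = de_table.index[mask]
    directions = {
        g: int(np.sign(de_table.at[g, "fc"])) for g in selected
    }
    rows = []
    for reg in network.regulators:
        edges = network.targets_of(reg)
        z, n_edges = activation_zscore(directions, edges)
        targets_in_universe = set(edges["target"]) & universe
        p = fisher_enrichment(set(directions), targets_in_universe, universe)
        if math.isnan(z):
            state = UNDETERMINED
        elif z >= z_min:
            state = ACTIVATED
        elif z <= -z_min:
            state = INHIBITED
        else:
            state = UNDETERMINED
        overlap = sorted(targets_in_universe & set(directions))
        rows.append(
            {
                "regulator": reg,
                "z": z,
                "n_targets_in_dataset": n_edges,
                "overlap_p": p,
                "state": state,
                "target_molecules": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows).set_index("regulator")
    df["_zkey"] = df["z"].fillna(-math.inf)
    df = df.sort_values(["_zkey", "regulator"], ascending=[False, True]).drop(
        columns="_zkey"
    )
    return df


def comparison_matrix(
    results: Mapping[str, pd.DataFrame],
    z_min: float = 2.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Align per-contrast enrichment tables and classify set specificity.

    ``results`` maps a contrast label (e.g. "TF", "TC") to its
    :func:`enrichment_table` output.  A set counts as significant in a
    contrast when |z| > z_min and p < p_max there; classification is the
    sorted '+'-join of the significant contrasts ("TF", "TC", "TC+TF") or
    "none".  Sets missing from a contrast get NaN columns there.
    """
    if len(results) < 2:
        raise ValueError("comparison needs >=2 contrasts")
    all_sets = sorted(set().union(*(df.index for df in results.values())))
    out = pd.DataFrame(index=pd.Index(all_sets, name="set"))
    sig = {}
    for label, df in results.items():
        out[f"z_{label}"] = df["z"].reindex(all_sets)
        out[f"p_{label}"] = df["p"].reindex(all_sets)
        sig[label] = (
            (df["z"].abs() > z_min) & (df["p"] < p_max)
        ).reindex(all_sets, fill_value=False)
    def classify(s):
        labels = sorted(lbl for lbl in results if sig[lbl][s])
        return "+".join(labels) if labels else "none"
    out["classification"] = [classify(s) for s in all_sets]
    return out
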