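"""Synthetic two-zone, two-arm nCounter cohorts with recorded planted truth.

Emulates the design the analysis assumes: 21 non-metastatic (cSI) and 14
metastatic (cSII/III) patients, each profiled in the invasive front (TF)
and tumour centre (TC), on a panel of 740 endogenous genes, 30
housekeeping candidates, 6 positive and 8 negative control probes.
Negative controls are Poisson background; positive controls follow the
standard six-level geometric titration scaled by a per-sample scale
factor; housekeeping genes are lognormal with per-gene noise (a stable
and an unstable subset, for geNorm recovery tests); endogenous genes are
negative-binomial with per-gene dispersion, per-sample scale factors and
planted log2 effects in the metastatic arm of configured zones.  Every
random quantity that recovery tests need is recorded in
:class:`PlantedTruth`; all output is deterministic in (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from zonalde.enrich import GeneSetCollection, RegulatorNetwork
from zonalde.rcc import (
    CountMatrix,
    ProbeRecord,
    RCCSample,
    SampleAnnotation,
    write_rcc,
)

_STREAM_COHORT, _STREAM_COUNTS, _STREAM_NETWORK = 1, 2, 3


@dataclass
class SimulationConfig:
    """Cohort design and generative parameters (seed mandatory).

    Arm sizes, probe-class counts and the planted-effect structure default
    to the two-arm two-zone design described in the module docstring.
    """

    seed: int
    # cohort design
    n_cs1: int = 21
    n_cs2: int = 14
    # panel composition
    n_endogenous: int = 740
    n_housekeeping: int = 30
    n_positive: int = 6
    n_negative: int = 8
    # controls
    lambda_negative: float = 6.0
    positive_levels: tuple[float, ...] = (128, 32, 8, 2, 0.5, 0.125)
    positive_base: float = 200.0
    # per-sample scale factors (log-uniform)
    scale_low: float = 0.4
    scale_high: float = 2.5
    # endogenous baseline and dispersion
    baseline_log2_mean: float = 7.5
    baseline_log2_sd: float = 2.0
    min_planted_baseline_log2: float = 6.0
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05
    # planted differential expression (metastatic arm vs cSI)
    de_fraction: float = 0.10
    log2_effect: float = 1.0
    up_fraction: float = 0.9
    tc_effect_fraction: float = 0.5
    # housekeeping structure
    n_stable_hk: int = 23
    hk_baseline_log2_mean: float = 9.0
    hk_baseline_log2_sd: float = 1.0
    stable_hk_noise_sd: float = 0.05
    unstable_hk_noise_sd: float = 1.0
    # regulator network / gene sets
    n_regulators: int = 5
    n_decoy_regulators: int = 15
    targets_per_regulator: int = 20
    sign_consistency: float = 0.9
    n_signal_sets: int = 5
    n_null_sets: int = 10
    set_size: int = 20
    signal_set_planted_fraction: float = 0.5

    def validate(self) -> list[str]:
        issues: list[str] = []
        for name in ("n_cs1", "n_cs2", "n_endogenous", "n_housekeeping"):
            if getattr(self, name) < 1:
                issues.append(f"{name}: must be >= 1")
        if self.n_positive < 1:
            issues.append("n_positive: must be >= 1")
        if self.n_negative < 2:
            issues.append("n_negative: need >= 2 for a background SD")
        for name in (
            "de_fraction",
            "up_fraction",
            "tc_effect_fraction",
            "sign_consistency",
            "signal_set_planted_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                issues.append(f"{name}: must be in [0, 1]")
        if not np.isfinite(self.log2_effect):
            issues.append("log2_effect: must be finite")
        if not 0 < self.scale_low <= self.scale_high:
            issues.append("scale_low/scale_high: need 0 < low <= high")
        if not 0 <= self.n_stable_hk <= self.n_housekeeping:
            issues.append("n_stable_hk: must be within [0, n_housekeeping]")
        if self.lambda_negative < 0:
            issues.append("lambda_negative: must be >= 0")
        if len(self.positive_levels) != self.n_positive:
            issues.append("positive_levels: length must equal n_positive")
        if not isinstance(self.seed, (int, np.integer)):
            issues.append("seed: required integer")
        return issues

    def checked(self) -> "SimulationConfig":
        issues = self.validate()
        if issues:
            raise ValueError("invalid SimulationConfig: " + "; ".join(issues))
        return self


@dataclass
class PlantedTruth:
    """Ground truth recorded at generation time for recovery testing."""

    effects: pd.DataFrame  # index: gene; columns: direction, log2fc_TF, log2fc_TC
    baseline_log2: pd.Series  # per endogenous gene
    hk_baseline_log2: pd.Series
    hk_noise_sd: pd.Series
    stable_hk: list[str]
    unstable_hk: list[str]
    regulators: dict[str, dict]  # name -> {"direction", "targets", "active"}
    scale_factors: pd.Series  # per sample

    @property
    def planted_genes(self) -> list[str]:
        return list(self.effects.index)

    def planted_in(self, region: str, min_abs_log2fc: float = 0.0) -> list[str]:
        col = f"log2fc_{region}"
        mask = self.effects[col].abs() >= max(min_abs_log2fc, 1e-12)
        return list(self.effects.index[mask])

    def active_regulators(self) -> list[str]:
        return sorted(n for n, r in self.regulators.items() if r["active"])

    def to_json(self) -> str:
        payload = {
            "effects": self.effects.reset_index().to_dict(orient="list"),
            "baseline_log2": self.baseline_log2.to_dict(),
            "hk_baseline_log2": self.hk_baseline_log2.to_dict(),
            "hk_noise_sd": self.hk_noise_sd.to_dict(),
            "stable_hk": self.stable_hk,
            "unstable_hk": self.unstable_hk,
            "regulators": self.regulators,
            "scale_factors": self.scale_factors.to_dict(),
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        effects = pd.DataFrame(d["effects"]).set_index("gene")
        effects = effects[["direction", "log2fc_TF", "log2fc_TC"]]
        return cls(
            effects=effects,
            baseline_log2=pd.Series(d["baseline_log2"]),
            hk_baseline_log2=pd.Series(d["hk_baseline_log2"]),
            hk_noise_sd=pd.Series(d["hk_noise_sd"]),
            stable_hk=d["stable_hk"],
            unstable_hk=d["unstable_hk"],
            regulators=d["regulators"],
            scale_factors=pd.Series(d["scale_factors"]),
        )


def _gene_names(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        "endogenous": [f"GENE{i:04d}" for i in range(1, config.n_endogenous + 1)],
        "housekeeping": [f"HK{i:02d}" for i in range(1, config.n_housekeeping + 1)],
        "positive": [f"POS_{chr(65 + i)}" for i in range(config.n_positive)],
        "negative": [f"NEG_{chr(65 + i)}" for i in range(config.n_negative)],
    }


def generate_cohort(
    config: SimulationConfig,
) -> tuple[SampleAnnotation, pd.DataFrame, PlantedTruth]:
    """Draw the cohort: annotations, clinical covariates and planted truth.

    Each patient contributes one TF and one TC sample.  Clinical
    covariates are drawn per arm from distributions chosen to resemble a
    two-arm seminoma cohort (age, tumour size, lymphovascular and venous
    invasion with metastasis-associated rates).  Differential-expression
    effects are planted in genes whose baseline is detectable
    (>= ``min_planted_baseline_log2``): every planted gene carries the TF
    effect, a configured fraction also carries it in TC.
    """
    config.checked()
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    names = _gene_names(config)

    patients = [f"P{i:03d}" for i in range(1, config.n_cs1 + config.n_cs2 + 1)]
    stages = ["cSI"] * config.n_cs1 + ["cSII_III"] * config.n_cs2
    ann_rows = []
    for pid, stage in zip(patients, stages):
        for region in ("TF", "TC"):
            ann_rows.append(
                {
                    "sample_id": f"{pid}_{region}",
                    "patient_id": pid,
                    "region": region,
                    "stage": stage,
                }
            )
    annotation = SampleAnnotation(pd.DataFrame(ann_rows))

    # clinical covariates, arm-specific
    is_met = np.array([s == "cSII_III" for s in stages])
    age = np.where(
        is_met, rng.normal(38.0, 7.5, len(patients)), rng.normal(38.6, 10.1, len(patients))
    )
    size = np.where(
        is_met,
        rng.normal(44.4, 32.6, len(patients)),
        rng.normal(29.1, 17.2, len(patients)),
    ).clip(min=3.0)
    lymph = np.where(
        is_met,
        rng.random(len(patients)) < 5 / 14,
        rng.random(len(patients)) < 1 / 21,
    ).astype(int)
    vein = np.where(
        is_met,
        rng.random(len(patients)) < 3 / 14,
        rng.random(len(patients)) < 0.02,
    ).astype(int)
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "stage": stages,
            "age": np.round(age, 1),
            "tumour_size": np.round(size, 1),
            "size_gt_4cm": (size > 40).astype(int),
            "lymphovascular_invasion": lymph,
            "vein_invasion": vein,
        }
    )

    # gene-level ground truth
    endo = names["endogenous"]
    baseline = pd.Series(
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(endo)),
        index=endo,
        name="baseline_log2",
    )
    eligible = [g for g in endo if baseline[g] >= config.min_planted_baseline_log2]
    n_planted = min(int(round(config.de_fraction * len(endo))), len(eligible))
    planted = sorted(rng.choice(eligible, size=n_planted, replace=False))
    direction = np.where(rng.random(n_planted) < config.up_fraction, 1, -1)
    in_tc = rng.random(n_planted) < config.tc_effect_fraction
    effects = pd.DataFrame(
        {
            "direction": direction,
            "log2fc_TF": direction * config.log2_effect,
            "log2fc_TC": np.where(in_tc, direction * config.log2_effect, 0.0),
        },
        index=pd.Index(planted, name="gene"),
    )

    hk = names["housekeeping"]
    hk_baseline = pd.Series(
        rng.normal(
            config.hk_baseline_log2_mean, config.hk_baseline_log2_sd, len(hk)
        ),
        index=hk,
        name="hk_baseline_log2",
    )
    stable = sorted(rng.choice(hk, size=config.n_stable_hk, replace=False))
    unstable = sorted(set(hk) - set(stable))
    hk_sd = pd.Series(
        [
            config.stable_hk_noise_sd if g in stable else config.unstable_hk_noise_sd
            for g in hk
        ],
        index=hk,
        name="hk_noise_sd",
    )

    scale = pd.Series(
        np.exp(
            rng.uniform(
                np.log(config.scale_low),
                np.log(config.scale_high),
                len(annotation.sample_ids),
            )
        ),
        index=annotation.sample_ids,
        name="scale_factor",
    )

    # regulator ground truth (edges are drawn later, in generate_network)
    regulators: dict[str, dict] = {}
    n_targets = min(config.targets_per_regulator, len(planted))
    for i in range(1, config.n_regulators + 1):
        targets = sorted(rng.choice(planted, size=n_targets, replace=False))
        regulators[f"REG{i:02d}"] = {
            "direction": 1,
            "targets": targets,
            "active": True,
        }
    for i in range(1, config.n_decoy_regulators + 1):
        targets = sorted(rng.choice(endo, size=n_targets, replace=False))
        regulators[f"DECOY{i:02d}"] = {
            "direction": 1,
            "targets": targets,
            "active": False,
        }

    truth = PlantedTruth(
        effects=effects,
        baseline_log2=baseline,
        hk_baseline_log2=hk_baseline,
        hk_noise_sd=hk_sd,
        stable_hk=stable,
        unstable_hk=unstable,
        regulators=regulators,
        scale_factors=scale,
    )
    return annotation, clinical, truth


def generate_count_matrix(
    annotation: SampleAnnotation,
    truth: PlantedTruth,
    config: SimulationConfig,
) -> "CountMatrix":
    """Draw the cohort count matrix implied by (annotation, truth, config).

    Negatives ~ Poisson(lambda); positives follow the titration times the
    sample's true scale factor; housekeeping counts are lognormal around
    their baselines with per-gene noise; endogenous counts are
    negative-binomial with mean baseline x scale x 2^effect, the effect
    applying in the metastatic arm of the zones where the gene is planted.
    Identical (config, seed) gives an identical matrix, and
    :func:`generate_counts` wraps the same draws into RCC samples.
    """
    config.checked()
    missing = [s for s in annotation.sample_ids if s not in truth.scale_factors.index]
    if missing:
        raise ValueError(f"truth lacks scale factors for samples: {missing}")
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])
    names = _gene_names(config)
    samples = annotation.sample_ids
    n_s = len(samples)
    scale = truth.scale_factors[samples].to_numpy()

    neg = rng.poisson(config.lambda_negative, size=(config.n_negative, n_s))
    pos = np.rint(
        np.asarray(config.positive_levels)[:, None] * config.positive_base * scale[None, :]
    ).astype(int)

    hk_sd = truth.hk_noise_sd[names["housekeeping"]].to_numpy()
    hk_noise = rng.normal(0.0, 1.0, size=(config.n_housekeeping, n_s)) * hk_sd[:, None]
    hk_base = truth.hk_baseline_log2[names["housekeeping"]].to_numpy()
    hk = np.rint(2.0 ** (hk_base[:, None] + hk_noise) * scale[None, :]).astype(int)

    endo_names = names["endogenous"]
    base = 2.0 ** truth.baseline_log2[endo_names].to_numpy()
    effect = np.zeros((len(endo_names), n_s))
    idx = {g: i for i, g in enumerate(endo_names)}
    ann = annotation.table
    for j, sid in enumerate(samples):
        row = ann[ann["sample_id"] == sid].iloc[0]
        if row["stage"] == "cSII_III":
            col = f"log2fc_{row['region']}"
            for g, e in truth.effects[col].items():
                effect[idx[g], j] = e
    mean = base[:, None] * scale[None, :] * 2.0**effect
    phi = rng.gamma(config.dispersion_shape, config.dispersion_scale, len(endo_names))
    r = 1.0 / np.maximum(phi, 1e-8)
    p = r[:, None] / (r[:, None] + mean)
    endo = rng.negative_binomial(r[:, None], p)

    counts = pd.DataFrame(
        np.vstack([endo, hk, pos, neg]),
        index=endo_names + names["housekeeping"] + names["positive"] + names["negative"],
        columns=samples,
    )
    classes = pd.Series(
        ["Endogenous"] * len(endo_names)
        + ["Housekeeping"] * config.n_housekeeping
        + ["Positive"] * config.n_positive
        + ["Negative"] * config.n_negative,
        index=counts.index,
    )
    return CountMatrix(counts, classes)


def generate_counts(
    annotation: SampleAnnotation,
    truth: PlantedTruth,
    config: SimulationConfig,
) -> list[RCCSample]:
    """Draw the RCC sample set (see :func:`generate_count_matrix`)."""
    matrix = generate_count_matrix(annotation, truth, config)
    names = _gene_names(config)
    endo_names = names["endogenous"]
    endo = matrix.counts.loc[endo_names].to_numpy()
    hk = matrix.counts.loc[names["housekeeping"]].to_numpy()
    pos = matrix.counts.loc[names["positive"]].to_numpy()
    neg = matrix.counts.loc[names["negative"]].to_numpy()
    samples = annotation.sample_ids

    out: list[RCCSample] = []
    for j, sid in enumerate(samples):
        probes = (
            [
                ProbeRecord("Endogenous", g, f"NM_{i + 1:06d}.1", int(endo[i, j]))
                for i, g in enumerate(endo_names)
            ]
            + [
                ProbeRecord("Housekeeping", g, f"NM_H{i + 1:04d}.1", int(hk[i, j]))
                for i, g in enumerate(names["housekeeping"])
            ]
            + [
                ProbeRecord("Positive", g, f"ERCC_{i + 1:05d}.1", int(pos[i, j]))
                for i, g in enumerate(names["positive"])
            ]
            + [
                ProbeRecord("Negative", g, f"ERCC_N{i + 1:04d}.1", int(neg[i, j]))
                for i, g in enumerate(names["negative"])
            ]
        )
        out.append(
            RCCSample(
                sample_id=sid,
                probes=probes,
                sample_attributes={"ID": sid},
                lane_attributes={"BindingDensity": "0.75"},
            )
        )
    return out


def generate_network(
    truth: PlantedTruth, config: SimulationConfig
) -> tuple[GeneSetCollection, RegulatorNetwork]:
    """Draw gene sets and the signed regulator network from planted truth.

    Active regulators get edges onto their recorded planted targets with
    signs agreeing with the planted direction at the configured
    consistency fraction; decoys get random signs on their random targets.
    Gene sets mix planted-enriched signal sets with null sets of random
    panel genes; each set also contributes signed membership edges to the
    network (regulator = set name) so that set-level activation z-scores
    are defined, with signal-set signs following the planted directions at
    the consistency fraction and null-set signs random.
    """
    config.checked()
    rng = np.random.default_rng([config.seed, _STREAM_NETWORK])
    names = _gene_names(config)
    endo = names["endogenous"]
    direction = truth.effects["direction"]

    rows = []
    for reg in sorted(truth.regulators):
        info = truth.regulators[reg]
        for t in info["targets"]:
            if info["active"]:
                agree = direction.get(t, 1) * info["direction"]
                sign = agree if rng.random() < config.sign_consistency else -agree
            else:
                sign = 1 if rng.random() < 0.5 else -1
            rows.append({"regulator": reg, "target": t, "sign": int(sign)})

    planted = truth.planted_genes
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    n_from_planted = min(
        int(round(config.signal_set_planted_fraction * config.set_size)), len(planted)
    )
    for i in range(1, config.n_signal_sets + 1):
        core = rng.choice(planted, size=n_from_planted, replace=False)
        rest = rng.choice(
            sorted(set(endo) - set(core)),
            size=config.set_size - n_from_planted,
            replace=False,
        )
        sets[f"SIGNAL_SET_{i:02d}"] = frozenset(core) | frozenset(rest)
        descriptions[f"SIGNAL_SET_{i:02d}"] = "planted-enriched"
    for i in range(1, config.n_null_sets + 1):
        sets[f"NULL_SET_{i:02d}"] = frozenset(
            rng.choice(endo, size=config.set_size, replace=False)
        )
        descriptions[f"NULL_SET_{i:02d}"] = "random panel genes"

    # signed membership edges so set-level activation z-scores are defined
    for name in sorted(sets):
        is_signal = name.startswith("SIGNAL")
        for t in sorted(sets[name]):
            if is_signal and t in direction.index:
                agree = int(direction[t])
                sign = agree if rng.random() < config.sign_consistency else -agree
            else:
                sign = 1 if rng.random() < 0.5 else -1
            rows.append({"regulator": name, "target": t, "sign": int(sign)})
    network = RegulatorNetwork(pd.DataFrame(rows))
    return GeneSetCollection(sets, descriptions), network


def write_cohort(
    outdir: str | Path,
    annotation: SampleAnnotation,
    clinical: pd.DataFrame,
    truth: PlantedTruth,
    samples: Sequence[RCCSample],
    collection: GeneSetCollection | None = None,
    network: RegulatorNetwork | None = None,
) -> None:
    """Write a full synthetic input set (RCC dir, TSVs, GMT, truth JSON)."""
    from zonalde.enrich import write_gmt

    outdir = Path(outdir)
    rcc_dir = outdir / "rcc"
    rcc_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        (rcc_dir / f"{s.sample_id}.rcc").write_text(write_rcc(s))
    annotation.to_tsv(outdir / "annotation.tsv")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    if collection is not None:
        (outdir / "gene_sets.gmt").write_text(write_gmt(collection))
    if network is not None:
        network.to_tsv(outdir / "network.tsv")
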