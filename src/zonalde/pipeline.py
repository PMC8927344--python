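"""End-to-end orchestration: ingest -> normalize -> filter -> DE -> enrichment.

A single declarative configuration (dict or YAML) drives a full run.  The
stage order is fixed: background subtraction, positive-control factor,
geNorm reference selection, housekeeping factor, presence filter, then
per-zone differential expression, gene-set enrichment, upstream-regulator
prediction, the cross-zone comparison and the clinical characteristics
table.  Every threshold of the analysis lives in the config with the
published defaults (FC 1.5/2, p 0.05, FDR 0.05, z 2, 40 counts in 25% of
samples), never hard-coded, and identical (config, seed) yields identical
output files.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from zonalde import clinical as clin
from zonalde import de as de_mod
from zonalde import enrich as enr
from zonalde import normalize as norm
from zonalde import simulate as sim
from zonalde.rcc import CountMatrix, SampleAnnotation, build_count_matrix, read_rcc

log = logging.getLogger("zonalde.pipeline")

REGIONS = ("TF", "TC")


def default_config() -> dict:
    """Template configuration with the analysis defaults (synthetic input)."""
    return {
        "seed": 0,
        "inputs": None,  # {"rcc_dir", "annotation", "gmt", "network", "clinical"}
        "synthetic": {},  # overrides for SimulationConfig fields
        "normalization": {
            "background_multiplier": 2.0,
            "band": [0.3, 3.0],
            "genorm": {"stop": "m_threshold", "m_max": 0.5, "min_genes": 3, "keep_n": None},
        },
        "presence": {"min_count": 40, "min_frac": 0.25},
        "de": {
            "pooled": False,
            "regime1_fc": 1.5,
            "regime1_p": 0.05,
            "regime2_fc": 2.0,
            "regime2_p": 0.05,
            "regime3_fc": 1.5,
            "regime3_q": 0.05,
        },
        "enrichment": {"z_min": 2.0, "fc_min": 2.0, "p_max": 0.05},
    }


def validate_config(config: dict) -> list[str]:
    """Return a list of issues; an empty list means the config is valid."""
    issues: list[str] = []
    has_inputs = bool(config.get("inputs"))
    has_synth = config.get("synthetic") is not None
    if has_inputs and has_synth:
        issues.append("inputs/synthetic: exactly one input source must be set")
    if not has_inputs and not has_synth:
        issues.append("inputs/synthetic: one input source is required")
    if has_inputs:
        for key in ("rcc_dir", "annotation"):
            if not config["inputs"].get(key):
                issues.append(f"inputs.{key}: required path missing")
    pres = config.get("presence", {})
    if not 0 < pres.get("min_frac", 0.25) <= 1:
        issues.append("presence.min_frac: must be in (0, 1]")
    if pres.get("min_count", 40) < 0:
        issues.append("presence.min_count: must be >= 0")
    de_cfg = config.get("de", {})
    for key in ("regime1_fc", "regime2_fc", "regime3_fc"):
        if de_cfg.get(key, 1.5) < 1:
            issues.append(f"de.{key}: fold-change threshold must be >= 1")
    for key in ("regime1_p", "regime2_p", "regime3_q"):
        if not 0 < de_cfg.get(key, 0.05) <= 1:
            issues.append(f"de.{key}: must be in (0, 1]")
    band = config.get("normalization", {}).get("band", [0.3, 3.0])
    if not (len(band) == 2 and 0 < band[0] < band[1]):
        issues.append("normalization.band: need 0 < low < high")
    if config.get("enrichment", {}).get("z_min", 2.0) <= 0:
        issues.append("enrichment.z_min: must be > 0")
    return issues


def config_hash(config: dict) -> str:
    """Stable hash of the semantic config content (key order irrelevant)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    config = default_config()
    for key, value in loaded.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    started: str
    finished: str = ""
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, **counts: Any) -> None:
        log.info("stage %s: %s", name, counts)
        self.stages.append({"stage": name, **counts})

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        tmp.replace(path)  # atomic publish


@dataclass
class PipelineResult:
    manifest: RunManifest
    matrix: CountMatrix
    annotation: SampleAnnotation
    de_results: dict[str, de_mod.DEResult]
    expressed: dict[str, list[str]]
    enrichment: dict[str, pd.DataFrame]
    regulators: dict[str, pd.DataFrame]
    comparison: pd.DataFrame | None
    table_one: pd.DataFrame | None
    truth: "sim.PlantedTruth | None" = None


def _load_inputs(config: dict, seed: int):
    """Returns (matrix, annotation, clinical, gene sets, network, truth)."""
    if config.get("inputs"):
        paths = config["inputs"]
        rcc_dir = Path(paths["rcc_dir"])
        samples = [read_rcc(p) for p in sorted(rcc_dir.glob("*.rcc"))]
        annotation = SampleAnnotation.from_tsv(paths["annotation"])
        matrix = build_count_matrix(samples, annotation)
        clinical = (
            pd.read_csv(paths["clinical"], sep="\t") if paths.get("clinical") else None
        )
        collection = (
            enr.read_gmt(Path(paths["gmt"]).read_text()) if paths.get("gmt") else None
        )
        network = (
            enr.RegulatorNetwork.from_tsv(paths["network"])
            if paths.get("network")
            else None
        )
        return matrix, annotation, clinical, collection, network, None
    sim_cfg = sim.SimulationConfig(seed=seed, **(config.get("synthetic") or {}))
    annotation, clinical, truth = sim.generate_cohort(sim_cfg)
    samples = sim.generate_counts(annotation, truth, sim_cfg)
    collection, network = sim.generate_network(truth, sim_cfg)
    matrix = build_count_matrix(samples, annotation)
    return matrix, annotation, clinical, collection, network, truth


def run_pipeline(
    config: dict, outdir: str | Path, seed: int | None = None
) -> PipelineResult:
    """Execute the full analysis described by ``config`` into ``outdir``."""
    config = copy.deepcopy(config)
    if seed is not None:
        config["seed"] = seed
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config),
        version=_version(),
        seed=seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    matrix, annotation, clinical_df, collection, network, truth = _load_inputs(
        config, seed
    )
    manifest.add_stage(
        "ingest", n_probes=len(matrix.probes), n_samples=len(matrix.samples)
    )

    ncfg = config["normalization"]
    thresholds = norm.background_thresholds(
        matrix, multiplier=ncfg["background_multiplier"]
    )
    subtracted = norm.subtract_background(matrix, thresholds)
    manifest.add_stage("background", mean_threshold=round(float(thresholds.mean()), 3))

    f_pos, flags = norm.positive_factor(subtracted, band=tuple(ncfg["band"]))
    for sid in flags.index[flags]:
        manifest.warnings.append(
            f"positive factor out of band for {sid}: {f_pos[sid]:.3f}"
        )
    manifest.add_stage("positive_factor", n_out_of_band=int(flags.sum()))

    hk_expr = subtracted.class_counts("Housekeeping").clip(lower=1.0)
    gcfg = ncfg["genorm"]
    genorm = norm.genorm_select(
        hk_expr,
        stop=gcfg["stop"],
        m_max=gcfg["m_max"],
        min_genes=gcfg["min_genes"],
        keep_n=gcfg["keep_n"],
    )
    manifest.add_stage(
        "genorm", n_candidates=len(hk_expr), n_selected=len(genorm.selected)
    )
    f_hk = norm.housekeeping_factor(subtracted, genorm.selected, positive=f_pos)
    factors = norm.NormalizationFactors(
        positive=f_pos, housekeeping=f_hk, out_of_band=flags, band=tuple(ncfg["band"])
    )
    normalized = norm.apply_normalization(subtracted, factors)
    manifest.add_stage("housekeeping_factor", n_references=len(genorm.selected))

    factors.report(thresholds).to_csv(
        outdir / "normalization_report.tsv", sep="\t", float_format="%.6g"
    )
    genorm.report().to_csv(
        outdir / "genorm_report.tsv", sep="\t", index=False, float_format="%.6g"
    )

    pres = config["presence"]
    de_cfg = config["de"]
    th = de_mod.DEThresholds(
        regime1_fc=de_cfg["regime1_fc"],
        regime1_p=de_cfg["regime1_p"],
        regime2_fc=de_cfg["regime2_fc"],
        regime2_p=de_cfg["regime2_p"],
        regime3_fc=de_cfg["regime3_fc"],
        regime3_q=de_cfg["regime3_q"],
    )
    ecfg = config["enrichment"]
    de_results: dict[str, de_mod.DEResult] = {}
    expressed: dict[str, list[str]] = {}
    enrichment: dict[str, pd.DataFrame] = {}
    regulators: dict[str, pd.DataFrame] = {}
    for region in REGIONS:
        groups = {
            "cSI": annotation.samples_for(region=region, stage="cSI"),
            "cSII_III": annotation.samples_for(region=region, stage="cSII_III"),
        }
        pf = norm.presence_filter(
            normalized, groups, min_count=pres["min_count"], min_frac=pres["min_frac"]
        )
        expressed[region] = pf.expressed
        pd.Series(pf.expressed, name="gene").to_csv(
            outdir / f"expressed_genes_{region}.tsv", sep="\t", index=False
        )
        spec = de_mod.ContrastSpec(region=region)
        result = de_mod.run_contrast(
            normalized,
            annotation,
            spec,
            expressed=pf.expressed,
            thresholds=th,
            pooled=de_cfg["pooled"],
        )
        de_results[region] = result
        result.table.to_csv(
            outdir / f"de_{region}.tsv", sep="\t", float_format="%.6g"
        )
        n_up1 = int((result.table["pass_regime1"] & (result.table["fc"] > 0)).sum())
        n_dn1 = int((result.table["pass_regime1"] & (result.table["fc"] < 0)).sum())
        manifest.add_stage(
            f"de_{region}",
            n_expressed=len(pf.expressed),
            n_up_regime1=n_up1,
            n_down_regime1=n_dn1,
            n_regime2=int(result.table["pass_regime2"].sum()),
            n_regime3=int(result.table["pass_regime3"].sum()),
        )

        if collection is not None:
            de_genes = result.genes(3)
            directions = result.directions(3).to_dict()
            etab = enr.enrichment_table(
                de_genes, collection, pf.expressed, directions, network
            )
            enrichment[region] = etab
            etab.to_csv(
                outdir / f"enrichment_{region}.tsv", sep="\t", float_format="%.6g"
            )
            if network is not None:
                # set-membership edges feed set z-scores, not regulator rows
                reg_net = enr.RegulatorNetwork(
                    network.edges[
                        ~network.edges["regulator"].isin(collection.sets)
                    ].copy()
                )
                rtab = enr.upstream_regulator_table(
                    result.table,
                    reg_net,
                    pf.expressed,
                    z_min=ecfg["z_min"],
                    fc_min=ecfg["fc_min"],
                    p_max=ecfg["p_max"],
                )
                regulators[region] = rtab
                rtab.to_csv(
                    outdir / f"regulators_{region}.tsv", sep="\t", float_format="%.6g"
                )
            manifest.add_stage(
                f"enrichment_{region}",
                n_sets=len(etab),
                n_de_genes=len(de_genes),
                n_regulators=len(regulators.get(region, [])),
            )

    comparison = None
    if len(enrichment) >= 2:
        comparison = enr.comparison_matrix(
            enrichment, z_min=ecfg["z_min"], p_max=ecfg["p_max"]
        )
        comparison.to_csv(outdir / "comparison.tsv", sep="\t", float_format="%.6g")
        manifest.add_stage(
            "comparison",
            **{
                f"n_{label.replace('+', '_')}": int(
                    (comparison["classification"] == label).sum()
                )
                for label in sorted(comparison["classification"].unique())
            },
        )

    table_one = None
    if clinical_df is not None:
        specs = [
            clin.VariableSpec("age", "continuous"),
            clin.VariableSpec("tumour_size", "continuous"),
            clin.VariableSpec("size_gt_4cm", "categorical"),
            clin.VariableSpec("lymphovascular_invasion", "categorical"),
            clin.VariableSpec("vein_invasion", "categorical"),
        ]
        specs = [s for s in specs if s.name in clinical_df.columns]
        table_one = clin.build_table_one(clinical_df, specs, arm_column="stage")
        table_one.to_csv(
            outdir / "table_one.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest.add_stage("table_one", n_variables=len(specs))

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        matrix=normalized,
        annotation=annotation,
        de_results=de_results,
        expressed=expressed,
        enrichment=enrichment,
        regulators=regulators,
        comparison=comparison,
        table_one=table_one,
        truth=truth,
    )


def _version() -> str:
    from zonalde import __version__

    return __version__
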