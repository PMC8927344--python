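"""Two-group differential expression in the invasive tumour front.

Draws the default 35-patient cohort (21 cSI vs 14 cSII/III, zones TF and
TC), normalizes it, applies the presence filter (>= 40 counts in >= 25%
of one arm) and tests cSI vs cSII/III in the TF zone.
"""

from zonalde import ContrastSpec, SimulationConfig, generate_cohort, generate_count_matrix, presence_filter, run_contrast
from zonalde.benchmarks import normalize_cohort

config = SimulationConfig(seed=1)
annotation, clinical, truth = generate_cohort(config)
normalized = normalize_cohort(generate_count_matrix(annotation, truth, config))

groups = {
    "cSI": annotation.samples_for(region="TF", stage="cSI"),
    "cSII_III": annotation.samples_for(region="TF", stage="cSII_III"),
}
pf = presence_filter(normalized, groups)
print(f"expressed genes in TF: {len(pf.expressed)}/{config.n_endogenous}")

result = run_contrast(normalized, annotation, ContrastSpec("TF"), expressed=pf.expressed)
t = result.table
up = int((t["pass_regime1"] & (t["fc"] > 0)).sum())
down = int((t["pass_regime1"] & (t["fc"] < 0)).sum())
print(f"|FC| >= 1.5 & p <= 0.05: {up} up, {down} down")
print(f"|FC| > 2 & p < 0.05:     {int(t['pass_regime2'].sum())} genes")
print(f"FDR < 0.05 & |FC| > 1.5: {int(t['pass_regime3'].sum())} genes")

top = t.sort_values("q").head(5)[["fc", "p", "q"]]
print("top genes by q:")
print(top.round(4).to_string())
planted = set(truth.planted_in("TF"))
print(f"{len(set(top.index) & planted)}/5 of the top genes carry a planted effect")
# Signed FC: +2 means doubled in the metastatic arm, -2 means halved.
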