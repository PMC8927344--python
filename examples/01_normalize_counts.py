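"""Three-step nCounter normalization on a small synthetic cohort.

Builds a 12-patient cohort, then runs background subtraction (negative
controls), positive-control factors with the 0.3-3.0 acceptance band,
geNorm reference selection and the housekeeping factor.
"""

from zonalde import (
    NormalizationFactors,
    SimulationConfig,
    apply_normalization,
    background_thresholds,
    generate_cohort,
    generate_count_matrix,
    genorm_select,
    housekeeping_factor,
    positive_factor,
    subtract_background,
)

config = SimulationConfig(seed=7, n_cs1=6, n_cs2=6, n_endogenous=200)
annotation, clinical, truth = generate_cohort(config)
matrix = generate_count_matrix(annotation, truth, config)

thresholds = background_thresholds(matrix)
print(f"background thresholds: mean {thresholds.mean():.1f} counts "
      f"(range {thresholds.min():.1f}-{thresholds.max():.1f})")
subtracted = subtract_background(matrix, thresholds)

f_pos, out_of_band = positive_factor(subtracted)
print(f"positive factors: {f_pos.min():.2f}-{f_pos.max():.2f}, "
      f"{int(out_of_band.sum())} sample(s) outside the 0.3-3.0 band")

hk = subtracted.class_counts("Housekeeping").clip(lower=1.0)
genorm = genorm_select(hk)
print(f"geNorm kept {len(genorm.selected)}/30 candidates "
      f"(excluded first: {genorm.exclusion_order[:3]})")
print(f"planted-unstable candidates excluded: "
      f"{sorted(set(genorm.exclusion_order) & set(truth.unstable_hk))}")

f_hk = housekeeping_factor(subtracted, genorm.selected, positive=f_pos)
normalized = apply_normalization(
    subtracted, NormalizationFactors(f_pos, f_hk, out_of_band)
)
print(f"normalized matrix: {normalized.counts.shape[0]} probes x "
      f"{normalized.counts.shape[1]} samples (flag normalized={normalized.normalized})")
# The geNorm exclusions should coincide with the genes simulated with high
# lognormal noise; low stability M means a reliable reference.
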