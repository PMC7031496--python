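"""Generate a pan-tumor expression cohort with planted ground truth.

Every sample carries a latent CD8+ T-cell infiltration factor; signature
genes track it, planted culprit genes oppose it in a subset of tumor
groups, and two 20-gene programs activate mutually exclusively in cold
samples.
"""

from culprit import GeneratorConfig, generate_pan_tumor

cfg = GeneratorConfig(seed=1)
cohort, truth = generate_pan_tumor(cfg)

print(f"cohort: {cohort.values.shape[0]} genes x {cohort.values.shape[1]} samples "
      f"in {len(cohort.groups)} tumor groups")
print("planted gene roles:")
print(truth.role_of.value_counts().to_string())
print(f"culprit effect active in groups: {', '.join(truth.culprit_groups)}")
cold = (truth.program_of != "none").sum()
print(f"{cold} cold samples carry program A or B "
      f"(A: {(truth.program_of == 'A').sum()}, B: {(truth.program_of == 'B').sum()})")
# The role table is the recovery target for every downstream stage: ranking
# should push 'culprit' genes to the top, and the mutual-exclusivity stage
# should separate programA from programB.
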