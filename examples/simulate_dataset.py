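"""Simulate a case-control dataset from a built-in two-locus disease model.

Each built-in model is a 3x3 penetrance table P(disease | genotype pair);
genotypes at the two functional SNPs follow Hardy-Weinberg proportions
and individuals are assigned case/control status by their penetrance.
"""

from sfmoabc import SimulationSpec, builtin_models, prevalence, simulate_dataset, write_genotype_table

models = builtin_models()
model = models["Model 1"]
print(f"{model.label}: penetrance table {model.table}")
print(f"population prevalence at MAF 0.25/0.25: {prevalence(model, (0.25, 0.25)):.4f}")

spec = SimulationSpec(model=model, mafs=(0.25, 0.25), n_cases=500, n_controls=500, n_snps=50, seed=1)
ds = simulate_dataset(spec)
print(f"simulated {ds.n_samples} samples x {ds.n_snps} SNPs; "
      f"functional pair hidden at columns {ds.truth[0]} (0-based)")

write_genotype_table(ds, "scratch_model1.csv")
print("wrote scratch_model1.csv (SNP columns + a 'Class' phenotype column)")
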