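"""Simulate a case-control dataset from a two-locus penetrance model.

Builds an XOR-like pure-interaction disease model, prints its population
descriptors, and draws a 400+400 dataset of 50 SNPs with the causal pair
hidden at random columns.
"""

from epiharmony import interaction_model, simulate_dataset, write_dataset

model = interaction_model(maf=0.4, low=0.02, high=0.6)
print(f"prevalence K = {model.prevalence:.4f}")
print(f"heritability H2 = {model.heritability:.3f}")
# K is the population disease risk implied by the penetrance table under
# Hardy-Weinberg genotype frequencies; H2 grades how much phenotype variance
# the two causal loci explain (0.4 is a strong, easily detectable signal).

ds, truth = simulate_dataset(model, n_cases=400, n_controls=400, n_snps=50, seed=1)
print(f"dataset: {ds.n_individuals} individuals x {ds.n_snps} SNPs")
print(f"causal pair hidden at columns {truth} (ids {ds.snp_ids[truth[0]]}, "
      f"{ds.snp_ids[truth[1]]})")

write_dataset(ds, "scratch_example_dataset.txt")
print("written to scratch_example_dataset.txt (tab-separated, Class column)")
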