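"""Generate a synthetic case/control study and write its input files.

The generator produces the three inputs the pipeline consumes — an
expression matrix with labels, a pathway collection (GMT), and a scored
protein-interaction network — plus a ground-truth file naming the planted
dysregulated pathways and the genes they shifted.
"""

from pathpin import SyntheticConfig, generate_inputs, write_synthetic_inputs

config = SyntheticConfig(seed=42)
inputs = generate_inputs(config)

print(f"genes:              {config.n_genes}")
print(f"samples:            {config.n_disease} disease vs {config.n_control} control")
print(f"pathways:           {len(inputs.pathways)} "
      f"(sizes {config.pathway_size_range[0]}-{config.pathway_size_range[1]})")
print(f"interactions:       {inputs.ppi.n_edges}")
print(f"planted pathways:   {sorted(inputs.truth.planted_pathway_ids)}")
print(f"affected genes:     {len(inputs.truth.affected_genes)} "
      f"(each shifted ~{config.effect_size} SD in disease samples)")

paths = write_synthetic_inputs(inputs, "scratch/example_inputs")
print("\nwrote:")
for path in paths:
    print(f"  {path}")
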