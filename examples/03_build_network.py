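"""Build and reduce the pathway interaction network (PIN).

Two pathways crosstalk when they share a differentially expressed gene or
when a protein interaction crossing them is highly co-expressed
(|Pearson r| > 0.8 in a condition).  Each edge is weighted by the summed
|PCC| of all crossing interactions; the network is then pruned to its
heaviest edges.
"""

from pathpin import (
    SyntheticConfig,
    build_pin,
    differential_expression,
    generate_inputs,
    pairwise_pcc,
    prepare_inputs,
    reduce_top_fraction,
)

inputs = generate_inputs(SyntheticConfig(seed=42))
targeted = prepare_inputs(inputs.study, inputs.pathways, inputs.ppi)

degs = differential_expression(targeted.study)
print(f"differentially expressed genes (p<0.05): {int(degs['is_deg'].sum())}"
      f" of {len(degs)}")

corr = pairwise_pcc(targeted.study, targeted.targeted_ppi)
print(f"interaction correlations computed: {len(corr)}")

pin = build_pin(targeted, degs, corr)
reduced = reduce_top_fraction(pin, fraction=0.5)
print(f"qualified pathway-pathway edges: {pin.number_of_edges()}")
print(f"kept after top-50% reduction:    {reduced.number_of_edges()}")

planted = inputs.truth.planted_pathway_ids
heaviest = sorted(reduced.edges(data=True),
                  key=lambda e: -e[2]["weight"])[:5]
print("\nheaviest crosstalk edges (weight = sum of |PCC| over crossing PPIs):")
for a, b, data in heaviest:
    tag = " (planted pair)" if a in planted and b in planted else ""
    print(f"  {a:3d} -- {b:3d}  weight={data['weight']:.2f}  "
          f"criteria={sorted(data['criteria'])}{tag}")
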