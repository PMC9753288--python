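"""Four-method target prediction with vote consensus and enrichment.

Builds reference ligand sets around distinct motifs, predicts targets for
a query carrying target T2's motif, applies the >=3-of-4 vote rule, and
runs a hypergeometric pathway enrichment on the consensus set.
"""

from herbscreen.synthetic import GeneratorConfig, generate_refsets, make_query
from herbscreen.targets import consensus_targets, enrich, predict_all

config = GeneratorConfig(n_targets=4, n_ligands_per_target=12, seed=21)
refsets, truth = generate_refsets(config)
query = make_query(config, motif_idx=1, seed=99)  # carries T2's motif
print("query:", query)

predictions = predict_all(query, refsets, seed=0, n_null=200)
for pred in predictions:
    best = pred.argmax()
    print(f"  {pred.method_id:<8} best={best}  predicted={sorted(pred.predicted)}")

cons = consensus_targets(predictions, min_methods=3)
print("votes:", dict(sorted(cons.votes.items())))
print("consensus (>=3 of 4 methods):", sorted(cons.consensus))
print("ranked by mean normalized score:", cons.ranked())

universe = {rs.target_id for rs in refsets}
annotation = {"pathway_A": {"T1", "T2"}, "pathway_B": {"T3", "T4"}}
for row in enrich(cons.consensus or {"T2"}, annotation, universe):
    print(f"  {row.pathway_id}: overlap {row.k}/{row.K}, "
          f"p={row.p_value:.3g}, BH-adjusted={row.p_adjusted:.3g}")
print("Small p-values flag pathways over-represented among consensus targets.")
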