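"""Signed pathway activity with a random-set permutation null.

Pathway activity = sum over members of sign x log2FC, where repressor
members carry sign -1 so that suppressing a repressor raises activity.
Significance compares the observed activity with 1000 random same-size
protein sets carrying the same sign multiset.
"""

from egopath import (
    PlantedPathway,
    SimulationScenario,
    compute_contrast,
    generate_abundances,
    generate_network,
    generate_pathways,
    score_all_pathways,
)

scenario = SimulationScenario(
    n_proteins=200, n_pathways=12, seed=4,
    planted_pathways=(PlantedPathway("PW0005", "UCCAO_MF", shift=0.8),),
)
network = generate_network(scenario)
pathways = generate_pathways(network, scenario)
matrix = generate_abundances(network, scenario, pathways)
contrasts = [compute_contrast(matrix, g) for g in ("UCCAO", "UCCAO_MF")]

table = score_all_pathways(pathways, contrasts, n_perm=1000, seed=4)
hits = table[table["p"] < 0.05]
print(table.sort_values("p").head(5)[
    ["pathway_id", "contrast", "activity", "null_mean", "null_sd", "p"]]
    .to_string(index=False))
print(f"\n{len(hits)} of {len(table)} pathway x contrast cells below p=0.05")
# The planted pathway PW0005 shows a large positive activity in the
# treatment contrast (activators up, repressors down both add positively);
# unplanted pathways hover near their null mean.
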