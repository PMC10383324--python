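"""Ego-module permutation statistics.

For every measured protein, its module (the protein + direct interactors
with a valid contrast) is summarized by the mean and SD of member log2 fold
changes and compared with 1000 random same-size protein sets.  A small
module-mean p flags a protein whose network neighborhood moved coherently.
"""

from egopath import (
    PlantedModule,
    SimulationScenario,
    compute_contrast,
    generate_abundances,
    generate_network,
    select_de_proteins,
)

scenario = SimulationScenario(
    n_proteins=150, seed=3,
    planted_modules=(PlantedModule("P000010", "UCCAO", delta=1.0),),
)
network = generate_network(scenario)
matrix = generate_abundances(network, scenario)
contrasts = [compute_contrast(matrix, g) for g in ("UCCAO", "UCCAO_MF")]

selection = select_de_proteins(network, contrasts, alpha=0.05,
                               n_perm=1000, seed=3)
per_seed = selection.per_seed
top = per_seed.sort_values("p_mean").head(5)
print(top[["seed_protein", "contrast", "module_size", "mean", "p_mean"]]
      .to_string(index=False))
# The planted seed P000010 tops the UCCAO contrast: its module-mean logFC is
# far outside what random same-size protein sets achieve (p ~ 1/1001).

for label, de in selection.de_sets.items():
    print(f"{label}: {len(de)} proteins at {de.criterion}")
# The pair set (UCCAO-UCCAO_MF) uses the module Pearson correlation between
# the two contrasts instead of the module mean.
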