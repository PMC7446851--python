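"""Hyperparameter grid search with five-fold chain-grouped cross-validation.

Scores a small cutoff x bin-size grid by pooled out-of-fold PCC and prints
the full score table plus the winning configuration.
"""

from rnaflex import FeatureConfig, GeneratorConfig, SearchGrid, build_dataset, generate_dataset
from rnaflex.learning import grid_search

structures = generate_dataset(
    GeneratorConfig(n_chains=6, nucleotides_range=(12, 18), seed=19)
)

grid = SearchGrid(
    cutoffs=(6.0, 10.0),
    fe_ratios=(0.5,),
    bin_sizes=(0.5, 1.0),
    model_params=({"alpha": 100.0}, {"alpha": 500.0}),
)

best_fc, best_spec, best_pcc, table = grid_search(
    lambda fc: build_dataset(structures, fc),
    grid,
    family="ridge",
    base_config=FeatureConfig(),
    k=5,
    seed=19,
)

print(table.to_string(index=False))
print(
    f"\nbest: E = {best_fc.cutoff} Å, f = {best_fc.bin_size} Å, "
    f"alpha = {best_spec.params['alpha']}, CV PCC = {best_pcc:.4f}"
)

# Each row is one feature-config x model-hyperparameter combination; the CV
# PCC pools every training chain's out-of-fold predictions into one score.
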