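"""Associate puncta with a dendritic tree and summarize densities by domain.

Generates a spiny pyramidal-like cell with domain-dependent puncta densities
(apical tuft 1.2/um vs proximal apical 0.4/um, 65% of dendritic puncta on
spines), associates every punctum with the dendrite surface at the 0.5 um
threshold, and prints per-domain densities (normalized within the cell) plus
the shaft/spine split.
"""

from perisynapse import synthetic
from perisynapse.association import (
    associate_puncta,
    density_table,
    normalize_densities,
    shaft_spine_fractions,
)

tree, labels, _ = synthetic.generate_tree(synthetic.TreeConfig(), seed=1)
puncta, truth = synthetic.place_puncta(tree, labels, synthetic.PunctaConfig(), seed=1)

records = associate_puncta(puncta, tree, labels)
table = normalize_densities(density_table(records, labels, tree))

print(table[["domain", "subdivision", "cable_length", "punctum_count", "density", "normalized_density"]]
      .round(3).to_string(index=False))
split = shaft_spine_fractions(records)
print(f"\nspine-associated: {split.loc[0, 'pct_spine']:.1f}%   "
      f"shaft-associated: {split.loc[0, 'pct_shaft']:.1f}%  (n={split.loc[0, 'n']})")
# Normalized densities average to exactly 1 within the cell; the tuft rows sit
# near 3x the proximal apical rows, matching the generator's density ratio, and
# the spine fraction recovers the 65% placement probability.
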