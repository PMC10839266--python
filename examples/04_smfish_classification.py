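"""smFISH field quantification: four-way cell classes and transcript levels.

Generates a field of nuclei across three regions x two layers with
class-dependent transcript counts (neurons 13.2/cell, non-neuronal 2.8/cell,
probe-positive neuron fractions 63% in the deep proximal stratum down to 33%
superficially), assigns probe puncta to nuclei (merged clusters counted by
area), classifies each cell by NeuN and probe positivity, and prints the
recovered per-class percentages and expression levels.
"""

from perisynapse import synthetic
from perisynapse.smfish import (
    assign_puncta_to_cells,
    classify_cells,
    count_transcripts,
    transcript_levels,
)

cells, puncta, truth, _ = synthetic.generate_fish_field(synthetic.FishConfig(), seed=11)
counted = count_transcripts(assign_puncta_to_cells(puncta, cells), cells)
cell_table, summary = classify_cells(counted)

pos = summary[summary.classification == "NeuN+/L2+"]
print(pos[["region", "layer", "pct", "transcripts_per_positive_cell"]].round(2).to_string(index=False))
print()
print(transcript_levels(cell_table).round(2).to_string(index=False))
# Probe-positive neuron percentages track the per-stratum generator fractions;
# expression levels recover ~13.2 transcripts/cell in neurons vs ~2.8 in
# non-neuronal cells.
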