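"""Three-channel perisynaptic minimum-distance analysis.

Generates 500 pre/post/perisynaptic marker triplets (pre-post separation
0.666 um, perisynaptic marker equidistant at 0.69 um), computes per-marker
minimum distances, applies the <1 um synaptic filter, and prints the violin
summaries (mean and quartiles of a seeded n=300 subsample per pair) in nm.
"""

from perisynapse import synthetic
from perisynapse.perisynaptic import triplet_analysis

pre, post, peri, truth = synthetic.generate_triplets(synthetic.TripletConfig(n=500), seed=17)
result = triplet_analysis(pre, post, peri, synaptic_radius=1.0, seed=17)

print(f"synaptic rows (<1 um to both partners): {int(result.table.synaptic.sum())} / {len(result.table)}")
for pair, v in result.violins.items():
    print(f"{pair:>10}: mean {v.mean*1000:6.1f} nm   q25 {v.q25*1000:6.1f}   q75 {v.q75*1000:6.1f}   n={v.n}")
# The peri marker sits ~690 nm from both synaptic markers while the pre-post
# coupling distance is ~666 nm: an equidistant, perisynaptic arrangement.
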