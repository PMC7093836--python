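"""Find tandem arrays and their monomer period in a contig.

Builds a contig with a satellite array buried in random sequence, then
locates the array, its period and its consensus, and cross-checks the
monomer size with a self-dotplot.
"""

import numpy as np

from satlib.tandem import dominant_offset, find_tandem_repeats, self_dotplot

rng = np.random.default_rng(4)
monomer = "".join(rng.choice(list("ACGT"), 23))
array = monomer * 12
contig = ("".join(rng.choice(list("ACGT"), 300)) + array
          + "".join(rng.choice(list("ACGT"), 300)))

for arr in find_tandem_repeats(contig, contig_id="ctg1"):
    print(f"array at {arr.start}-{arr.end}: period {arr.period} bp, "
          f"{arr.copy_number_in_array:.1f} copies, score {arr.score}")
    print(f"consensus: {arr.array_consensus}")
# A perfect array scores 2 per base (match weight 2); substitutions cost
# 5 each (one lost match plus one mismatch under the 2/3/5 weights).

hits = self_dotplot(array, window=10, min_identity=0.9)
print(f"dominant self-dotplot offset: {dominant_offset(hits)} bp "
      "(the monomer size, read off the first off-diagonal)")
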