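"""Peak-set colocalization with a planted overlap fraction.

Generates two peak sets where exactly 60% of set A's peaks sit on set B's
peaks, then measures asymmetric overlap fractions and Venn membership
counts with the >= 10 bp rule.
"""

from promoterscope.colocalization import (pairwise_fraction_table,
                                          venn_counts)
from promoterscope.genome_model import ChromSizes
from promoterscope.synthetic_data import plant_overlap_pair

chrom_sizes = ChromSizes({"chr2L": 1_000_000, "chr2R": 800_000})
set_a, set_b = plant_overlap_pair(chrom_sizes, n=500, fraction=0.60, seed=4)

print(pairwise_fraction_table({"A": set_a, "B": set_b}).to_string(index=False))
result = venn_counts({"A": set_a, "B": set_b}, reference="A")
print()
print(result.to_frame().to_string(index=False))
print()
print("0.60 of A's peaks share >= 10 bp with a B peak (the planted rate);")
print("the Venn rows partition A's 500 peaks by which sets they touch.")
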