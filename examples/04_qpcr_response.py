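"""Delta-delta-Ct expression response of a knockdown experiment.

Generates a qPCR Ct table with planted fold changes (7 genes down at 0.5,
3 up at 1.5, 11 unchanged, plus an 8-fold knockdown of the factor itself),
quantifies against the reference gene and classifies at the 20% threshold.
"""

from promoterscope.expression_response import (expression_table,
                                               knockdown_efficiency)
from promoterscope.synthetic_data import SimulationConfig, generate_qpcr

config = SimulationConfig(seed=5)
ct_table, truth = generate_qpcr(config)

table = expression_table(ct_table, efficiency=config.efficiency)
merged = table.merge(truth, on="gene")
print(merged.round(3).to_string(index=False))

kd = knockdown_efficiency(ct_table, config.target_gene)
print()
print(f"knockdown of {config.target_gene}: {kd.fold_decrease:.1f}-fold "
      f"decrease (effective: {kd.effective})")
print("fold_change is knockdown/control expression normalized to the")
print(f"reference gene ({config.reference_gene}); 'down' means <= 0.8, "
      f"'up' >= 1.2.")
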