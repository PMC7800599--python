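"""Averaged signal profile at bound sites with matched random controls.

Plants Gaussian enrichment bumps at 300 well-separated sites, then computes
the three-curve bundle: signal at the sites themselves, at an equal number
of random promoters, and at random genomic positions.
"""

import numpy as np

from promoterscope.metaprofile import (average_profile,
                                       extract_profile_matrix,
                                       fit_gaussian_peak, matrix_column_se,
                                       three_curve_bundle)
from promoterscope.synthetic_data import (SimulationConfig,
                                          generate_signal_track,
                                          lattice_sites,
                                          simulate_partitioned_genome)

config = SimulationConfig(seed=8)
chrom_sizes, genes, _ = simulate_partitioned_genome(config)
sites = lattice_sites(chrom_sizes, 300, spacing=6400, seed=9, jitter=100)
track = generate_signal_track(chrom_sizes, sites, config, mode="enrich")

bundle = three_curve_bundle(track, sites, genes, chrom_sizes, seed=10)
frame = bundle.to_frame()
center = len(frame) // 2
print(frame.iloc[[0, center - 1, center, center + 1, -1]].to_string(index=False))

matrix = extract_profile_matrix(track, sites)
fit = fit_gaussian_peak(average_profile(matrix), matrix_column_se(matrix))
print()
print(f"fitted peak amplitude {fit.amplitude:.3f} +/- {fit.amplitude_se:.3f} "
      f"(planted {config.bump_amplitude}), center {fit.center:+.1f} bp")
print("The factor curve rises ~4 units above the ~10-unit background at the")
print("anchor; both control curves stay at background level.")
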