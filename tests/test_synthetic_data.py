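"""Generator self-checks: determinism, feasibility and planting contracts."""

import numpy as np
import pandas as pd
import pytest

from promoterscope.colocalization import overlap_fraction
from promoterscope.expression_response import relative_expression
from promoterscope.genome_model import ChromSizes
from promoterscope.synthetic_data import (SimulationConfig,
                                          generate_genome, generate_qpcr,
                                          generate_signal_track,
                                          largest_remainder_counts,
                                          plant_overlap_pair, plant_peaks,
                                          simulate_partitioned_genome)


def test_largest_remainder_is_exact():
    assert largest_remainder_counts((0.732, 0.05, 0.15, 0.068), 1000) == \
        [732, 50, 150, 68]
    assert sum(largest_remainder_counts((1 / 3, 1 / 3, 1 / 3), 100)) == 100


def test_bad_fractions_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(category_fractions=(0.5, 0.2, 0.2, 0.2))


class TestGenerateGenome:
    def test_zero_genes_still_gives_chrom_sizes(self):
        cfg = SimulationConfig.small(0)
        cfg.n_genes = 0
        sizes, genes = generate_genome(cfg)
        assert genes == [] and sizes.genome_size > 0

    def test_same_seed_identical_annotation(self):
        a = generate_genome(SimulationConfig.small(5))[1]
        b = generate_genome(SimulationConfig.small(5))[1]
        assert a == b
        c = generate_genome(SimulationConfig.small(6))[1]
        assert a != c

    def test_genes_in_bounds_and_non_overlapping(self):
        sizes, genes = generate_genome(SimulationConfig.small(1))
        by_chrom = {}
        for g in genes:
            assert 0 <= g.start < g.end <= sizes[g.chrom]
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig.small(0)
        cfg.chrom_lengths = {"mini": 20_000}
        cfg.n_genes = 50
        with pytest.raises(ValueError, match="cannot fit"):
            generate_genome(cfg)


class TestPlantPeaks:
    def test_all_tss_fractions(self, small_config):
        _, _, partition = simulate_partitioned_genome(small_config)
        small_config.category_fractions = (1.0, 0.0, 0.0, 0.0)
        peaks = plant_peaks(partition, small_config)
        assert set(peaks.metadata) == {"TSS"}

    def test_planted_counts_exact(self, small_config):
        _, _, partition = simulate_partitioned_genome(small_config)
        peaks = plant_peaks(partition, small_config)
        counts = pd.Series(peaks.metadata).value_counts()
        expected = largest_remainder_counts(small_config.category_fractions,
                                            small_config.n_peaks)
        assert [counts.get(c, 0) for c in ("TSS", "TES", "GENE_BODY",
                                           "INTERGENIC")] == expected

    def test_same_seed_identical(self, small_config):
        _, _, partition = simulate_partitioned_genome(small_config)
        a = plant_peaks(partition, small_config, seed=8)
        b = plant_peaks(partition, small_config, seed=8)
        assert np.array_equal(a.positions, b.positions) and a.chroms == b.chroms

    def test_zero_capacity_rejected(self):
        cfg = SimulationConfig.small(0)
        cfg.n_genes = 0
        _, _, partition = simulate_partitioned_genome(cfg)
        with pytest.raises(ValueError, match="TSS"):
            plant_peaks(partition, cfg)


class TestPlantOverlapPair:
    def test_exact_fraction_at_zero_jitter(self):
        sizes = ChromSizes({"c1": 500_000, "c2": 400_000})
        set_a, set_b = plant_overlap_pair(sizes, n=200, fraction=0.60, seed=4)
        assert overlap_fraction(set_a, set_b) == 0.60
        assert len(set_a) == len(set_b) == 200

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 1.0])
    def test_other_fractions(self, fraction):
        sizes = ChromSizes({"c1": 500_000})
        set_a, set_b = plant_overlap_pair(sizes, n=100, fraction=fraction,
                                          seed=1)
        assert overlap_fraction(set_a, set_b) == fraction

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="lattice"):
            plant_overlap_pair(ChromSizes({"c": 5000}), n=100, fraction=0.5,
                               seed=0)


class TestSignalTrack:
    def test_noiseless_closed_form(self):
        sizes = ChromSizes({"c": 10_000})
        cfg = SimulationConfig.small(0)
        cfg.noise_sd = 0.0
        from promoterscope.genome_model import SiteSet
        site = SiteSet("s", ["c"], [5000])
        track = generate_signal_track(sizes, site, cfg, "enrich")
        arr = track.values("c")
        assert arr[5000] == pytest.approx(cfg.background_mean +
                                          cfg.bump_amplitude)
        assert arr[0] == pytest.approx(cfg.background_mean)
        dip = generate_signal_track(sizes, site, cfg, "deplete")
        assert dip.values("c")[5000] == pytest.approx(
            cfg.background_mean - cfg.bump_amplitude)

    def test_zero_noise_zero_amplitude_constant(self):
        sizes = ChromSizes({"c": 5000})
        cfg = SimulationConfig.small(0)
        cfg.noise_sd = 0.0
        cfg.bump_amplitude = 0.0
        from promoterscope.genome_model import SiteSet
        track = generate_signal_track(sizes, SiteSet("s", ["c"], [2500]),
                                      cfg, "enrich")
        assert np.all(track.values("c") == cfg.background_mean)

    def test_track_nonnegative_and_deterministic(self):
        sizes = ChromSizes({"c": 20_000})
        cfg = SimulationConfig.small(0)
        from promoterscope.genome_model import SiteSet
        sites = SiteSet("s", ["c", "c"], [4000, 12_000])
        a = generate_signal_track(sizes, sites, cfg, "deplete", seed=2)
        b = generate_signal_track(sizes, sites, cfg, "deplete", seed=2)
        np.testing.assert_array_equal(a.values("c"), b.values("c"))
        assert (a.values("c") >= 0).all()


class TestGenerateQpcr:
    def test_noiseless_inversion_is_exact(self):
        cfg = SimulationConfig(seed=2, ct_noise_sd=0.0)
        ct, truth = generate_qpcr(cfg)
        for _, row in truth.iterrows():
            if row.gene == cfg.reference_gene:
                continue
            change = relative_expression(ct, row.gene, cfg.efficiency)
            assert change.fold_change == pytest.approx(row.planted_fold,
                                                       rel=1e-9)

    def test_same_seed_identical_table(self):
        a, _ = generate_qpcr(SimulationConfig(seed=9))
        b, _ = generate_qpcr(SimulationConfig(seed=9))
        assert a.data.equals(b.data)

    def test_panel_structure(self):
        cfg = SimulationConfig(seed=1)
        ct, truth = generate_qpcr(cfg)
        assert len(truth) == 22  # 21-gene panel + knockdown target
        assert truth.planted_class.value_counts().to_dict() == {
            "down": cfg.qpcr_n_down + 1, "unchanged": cfg.qpcr_n_unchanged,
            "up": cfg.qpcr_n_up}
        reps = ct.data.groupby(["condition", "gene"]).size()
        assert (reps == cfg.qpcr_replicates).all()
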