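"""Profile extraction, averaging, log2 ratios and the three-curve bundle."""

import numpy as np
import pytest

from promoterscope.genome_model import ChromSizes, SiteSet
from promoterscope.io_formats import SignalTrack
from promoterscope.metaprofile import (average_profile, bin_centers,
                                       central_flank_contrast,
                                       extract_profile_matrix,
                                       log2_enrichment, three_curve_bundle)


def constant_track(sizes: ChromSizes, value: float) -> SignalTrack:
    track = SignalTrack(sizes)
    for chrom, length in sizes.items():
        track.set_span(chrom, 0, length, value)
    return track


@pytest.fixture
def sizes():
    return ChromSizes({"c": 100_000})


def test_bin_centers_symmetric_and_validated():
    centers = bin_centers(5000, 50)
    assert len(centers) == 201
    assert centers[0] == -5000 and centers[-1] == 5000
    np.testing.assert_array_equal(centers, -centers[::-1])
    with pytest.raises(ValueError):
        bin_centers(5000, 43)


def test_constant_track_fills_matrix(sizes):
    track = constant_track(sizes, 3.25)
    sites = SiteSet("s", ["c", "c"], [30_000, 60_000])
    matrix = extract_profile_matrix(track, sites, flank=1000, bin_width=50)
    assert matrix.values.shape == (2, 41)
    assert np.all(matrix.values == 3.25)


def test_half_defined_track_yields_half_nan(sizes):
    track = SignalTrack(sizes)
    track.set_span("c", 50_000, 100_000, 1.0)  # defined right of the anchor
    sites = SiteSet("s", ["c"], [50_000 + 25])  # anchor just inside data
    matrix = extract_profile_matrix(track, sites, flank=1000, bin_width=50)
    row = matrix.values[0]
    assert np.isnan(row[:19]).all()   # bins fully left of the data edge
    assert np.all(row[21:] == 1.0)


def test_step_function_bin_value_is_length_weighted_mean(sizes):
    # bin [975, 1025) over a 3-segment step: 10 bases of 2.0, 20 of 4.0,
    # 20 of 8.0 -> mean (10*2 + 20*4 + 20*8)/50 = 5.2
    track = SignalTrack(sizes)
    track.set_span("c", 0, 985, 2.0)
    track.set_span("c", 985, 1005, 4.0)
    track.set_span("c", 1005, 100_000, 8.0)
    sites = SiteSet("s", ["c"], [1000])
    matrix = extract_profile_matrix(track, sites, flank=50, bin_width=50)
    center_bin = len(matrix.bin_centers) // 2
    assert matrix.values[0, center_bin] == pytest.approx(5.2)


def test_site_on_missing_chromosome_gives_nan_row():
    sizes = ChromSizes({"c": 10_000, "empty": 10_000})
    track = SignalTrack(sizes)
    track.set_span("c", 0, 10_000, 1.0)
    sites = SiteSet("s", ["c", "empty"], [5000, 5000])
    matrix = extract_profile_matrix(track, sites, flank=500, bin_width=50)
    assert np.all(matrix.values[0] == 1.0)
    assert np.isnan(matrix.values[1]).all()


def test_average_profile_means_and_counts(sizes):
    track = SignalTrack(sizes)
    track.set_span("c", 0, 100_000, 1.0)
    track.set_span("c", 30_000 - 1100, 30_000 + 1100, 1.0)
    sites = SiteSet("s", ["c", "c"], [30_000, 60_000])
    matrix = extract_profile_matrix(track, sites, flank=1000, bin_width=100)
    matrix.values[0, :] = 1.0
    matrix.values[1, :] = 3.0
    matrix.values[1, 0] = np.nan
    avg = average_profile(matrix)
    assert avg.mean[1] == 2.0 and avg.n[1] == 2
    assert avg.mean[0] == 1.0 and avg.n[0] == 1
    # balanced design: grand mean equals mean of row means where complete
    complete = ~np.isnan(matrix.values).any(axis=0)
    np.testing.assert_allclose(avg.mean[complete],
                               matrix.values[:, complete].mean(axis=0))


def test_linearity_of_extraction(sizes, rng):
    track = SignalTrack(sizes)
    track.values("c")[:] = rng.normal(5, 1, 100_000)
    sites = SiteSet("s", ["c"] * 5, rng.integers(5000, 95_000, 5))
    base = extract_profile_matrix(track, sites, 2000, 50).values
    scaled = SignalTrack(sizes)
    scaled.values("c")[:] = 2.5 * track.values("c") + 7.0
    got = extract_profile_matrix(scaled, sites, 2000, 50).values
    np.testing.assert_allclose(got, 2.5 * base + 7.0, rtol=1e-12)


def test_translation_equivariance(rng):
    sizes = ChromSizes({"c": 50_000})
    vals = rng.normal(0, 1, 50_000)
    offset = 1234
    track_a = SignalTrack(sizes)
    track_a.values("c")[:] = vals
    track_b = SignalTrack(sizes)
    track_b.values("c")[offset:] = vals[:-offset]
    sites_a = SiteSet("s", ["c"] * 3, [10_000, 20_000, 30_000])
    sites_b = SiteSet("s", ["c"] * 3, [p + offset for p in (10_000, 20_000,
                                                            30_000)])
    a = extract_profile_matrix(track_a, sites_a, 2000, 50).values
    b = extract_profile_matrix(track_b, sites_b, 2000, 50).values
    np.testing.assert_array_equal(a, b)


class TestLog2Enrichment:
    def test_identity_when_equal(self, sizes):
        t = constant_track(sizes, 7.0)
        out = log2_enrichment(t, constant_track(sizes, 7.0), pseudocount=1.0)
        assert np.all(out.values("c") == 0.0)

    def test_doubling_approaches_one(self, sizes):
        out = log2_enrichment(constant_track(sizes, 2000.0),
                              constant_track(sizes, 1000.0),
                              pseudocount=1e-6)
        assert out.values("c")[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_per_base_formula_and_nan_propagation(self, sizes, rng):
        t, c = SignalTrack(sizes), SignalTrack(sizes)
        t.values("c")[:1000] = rng.uniform(0, 50, 1000)
        c.values("c")[:900] = rng.uniform(0, 50, 900)
        out = log2_enrichment(t, c, 1.0)
        expected = np.log2((t.values("c")[:900] + 1) / (c.values("c")[:900] + 1))
        np.testing.assert_allclose(out.values("c")[:900], expected)
        assert np.isnan(out.values("c")[900:]).all()

    def test_nonpositive_pseudocount_rejected(self, sizes):
        with pytest.raises(ValueError):
            log2_enrichment(constant_track(sizes, 1), constant_track(sizes, 1),
                            pseudocount=0.0)


class TestThreeCurveBundle:
    def test_constant_track_gives_three_flat_identical_curves(self):
        from promoterscope.synthetic_data import simulate_partitioned_genome
        from promoterscope.synthetic_data import SimulationConfig
        cfg = SimulationConfig.small(2)
        sizes, genes, _ = simulate_partitioned_genome(cfg)
        track = constant_track(sizes, 4.5)
        factor = SiteSet("f", ["chrA"] * 10,
                         np.linspace(20_000, 280_000, 10).astype(int))
        bundle = three_curve_bundle(track, factor, genes, sizes, seed=5,
                                    flank=2000, bin_width=50)
        for curve in (bundle.factor, bundle.promoters, bundle.random):
            assert np.all(curve.mean == 4.5)

    def test_fixed_seed_reproduces_controls(self):
        from promoterscope.synthetic_data import (SimulationConfig,
                                                  simulate_partitioned_genome)
        cfg = SimulationConfig.small(2)
        sizes, genes, _ = simulate_partitioned_genome(cfg)
        track = constant_track(sizes, 1.0)
        factor = SiteSet("f", ["chrA"] * 5, [50_000, 90_000, 130_000,
                                             170_000, 210_000])
        a = three_curve_bundle(track, factor, genes, sizes, seed=9, flank=2000)
        b = three_curve_bundle(track, factor, genes, sizes, seed=9, flank=2000)
        assert a.to_frame().equals(b.to_frame())


def test_planted_bump_recovered_and_depletion_direction():
    """Enrichment bumps raise the center; depletion dips lower it."""
    from promoterscope.synthetic_data import (SimulationConfig,
                                              generate_signal_track,
                                              plant_peaks,
                                              simulate_partitioned_genome)
    cfg = SimulationConfig.small(7)
    sizes, genes, partition = simulate_partitioned_genome(cfg)
    peaks = plant_peaks(partition, cfg)
    for mode, direction in (("enrich", 1), ("deplete", -1)):
        track = generate_signal_track(sizes, peaks, cfg, mode)
        matrix = extract_profile_matrix(track, peaks, flank=2000, bin_width=50)
        contrast, sem = central_flank_contrast(matrix)
        assert direction * contrast > 3 * sem
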