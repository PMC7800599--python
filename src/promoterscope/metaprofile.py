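"""Averaged signal profiles around anchor sites (meta-profiles).

Signal in a window of +/-flank bp (default 5 kb) around each anchor is
averaged into fixed-width bins (default 50 bp, giving 201 bin centers from
-flank to +flank), then averaged across sites per bin, skipping bins without
data.  The standard three-curve bundle pairs the factor-site curve with two
seeded controls of identical size: randomly sampled gene promoters and random
genomic positions.  Tracks may be raw coverage or log2 enrichment ratios; a
helper computes log2((treatment + p) / (control + p)) per base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import (ChromSizes, GeneModel, GenomePartition, SiteSet,
                           sample_random_promoters, sample_random_sites)
from .io_formats import SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Sites x bins matrix of binned signal around anchors (NaN = no data)."""

    site_ids: list[str]
    bin_centers: np.ndarray  # bp relative to anchor, symmetric about 0
    values: np.ndarray       # (n_sites, n_bins) float with NaN
    flank: int
    bin_width: int
    site_set_name: str


@dataclass
class AverageProfile:
    """Per-bin mean over sites with data, with per-bin site counts."""

    bin_centers: np.ndarray
    mean: np.ndarray     # NaN where no site has data
    n: np.ndarray        # sites contributing per bin
    site_set_name: str


def bin_centers(flank: int, bin_width: int) -> np.ndarray:
    if flank <= 0 or bin_width <= 0 or flank % bin_width:
        raise ValueError("flank must be a positive multiple of bin_width")
    return np.arange(-flank, flank + 1, bin_width, dtype=np.int64)


def extract_profile_matrix(track: SignalTrack, sites: SiteSet,
                           flank: int = 5000, bin_width: int = 50
                           ) -> ProfileMatrix:
    """Bin the track around each site anchor.

    Each bin spans ``bin_width`` bases centered on its bin center (for even
    widths, [center - w/2, center + w/2)); the bin value is the mean of
    defined per-base values in the span, NaN when the span is entirely
    off-chromosome or without data.
    """
    centers = bin_centers(flank, bin_width)
    half = bin_width // 2
    # per-base offsets of every bin, shape (n_bins, bin_width)
    offsets = centers[:, None] - half + np.arange(bin_width)[None, :]
    n_bins = len(centers)
    values = np.full((len(sites), n_bins), np.nan)
    missing_chroms: set[str] = set()
    for row, (chrom, pos) in enumerate(sites):
        if chrom not in track.chrom_sizes or not track.has_chrom(chrom):
            missing_chroms.add(chrom)
            continue
        arr = track.values(chrom)
        idx = pos + offsets
        valid = (idx >= 0) & (idx < len(arr))
        vals = np.full(idx.shape, np.nan)
        vals[valid] = arr[idx[valid]]
        counts = np.sum(~np.isnan(vals), axis=1)
        sums = np.nansum(vals, axis=1)
        with np.errstate(invalid="ignore"):
            values[row] = np.where(counts > 0, sums / counts, np.nan)
    if missing_chroms:
        logger.warning("sites on chromosomes absent from track: %s",
                       sorted(missing_chroms))
    ids = [f"{c}:{p}" for c, p in sites]
    return ProfileMatrix(ids, centers, values, flank, bin_width, sites.name)


def average_profile(matrix: ProfileMatrix) -> AverageProfile:
    """Arithmetic mean per bin over sites with data."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty profile matrix")
    n = np.sum(~np.isnan(matrix.values), axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(matrix.values, axis=0)
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return AverageProfile(matrix.bin_centers, mean, n, matrix.site_set_name)


def log2_enrichment(treatment: SignalTrack, control: SignalTrack,
                    pseudocount: float = 1.0) -> SignalTrack:
    """Per-base log2((treatment + p)/(control + p)); NaN where either lacks data."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if treatment.chrom_sizes.entries != control.chrom_sizes.entries:
        raise ValueError("treatment and control tracks disagree on chromosomes")
    out = SignalTrack(treatment.chrom_sizes)
    for chrom in treatment.chroms:
        if not control.has_chrom(chrom):
            continue
        t = treatment.values(chrom)
        c = control.values(chrom)
        with np.errstate(invalid="ignore", divide="ignore"):
            out.values(chrom)[:] = np.log2((t + pseudocount) / (c + pseudocount))
    return out


@dataclass
class ProfileBundle:
    """Factor curve plus size-matched promoter and random-site controls."""

    factor: AverageProfile
    promoters: AverageProfile
    random: AverageProfile
    n_sites: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.factor.bin_centers,
            "mean_factor": self.factor.mean,
            "n_factor": self.factor.n,
            "mean_promoters": self.promoters.mean,
            "n_promoters": self.promoters.n,
            "mean_random": self.random.mean,
            "n_random": self.random.n,
        })


def three_curve_bundle(track: SignalTrack, factor_sites: SiteSet,
                       genes: list[GeneModel], chrom_sizes: ChromSizes,
                       seed: int, flank: int = 5000, bin_width: int = 50
                       ) -> ProfileBundle:
    """Factor, random-promoter and random-site curves of identical size.

    Controls are sampled with the documented samplers from seeds derived
    deterministically from ``seed``; the random-site margin equals the flank
    so no control window runs off a chromosome.
    """
    n = len(factor_sites)
    promoters = sample_random_promoters(genes, n, seed=2 * seed + 1)
    randoms = sample_random_sites(chrom_sizes, n, seed=2 * seed + 2,
                                  margin=flank)
    curves = []
    for sites in (factor_sites, promoters, randoms):
        curves.append(average_profile(
            extract_profile_matrix(track, sites, flank, bin_width)))
    return ProfileBundle(*curves, n_sites=n, seed=seed)


@dataclass
class GaussianPeakFit:
    """Gaussian-plus-constant fit of an averaged curve."""

    amplitude: float
    amplitude_se: float
    center: float       # bp relative to the anchor
    width: float        # Gaussian sd, bp
    baseline: float


def fit_gaussian_peak(profile: AverageProfile,
                      se: np.ndarray | None = None) -> GaussianPeakFit:
    """Fit baseline + a*exp(-(x-mu)^2 / (2 s^2)) to the averaged curve.

    The fitted model is the Gaussian averaged over each bin's span (the
    curve is binned data, and bin-averaging attenuates a point-evaluated
    Gaussian), so the reported amplitude is unbiased with respect to the bin
    width.  ``se`` optionally supplies per-bin standard errors (e.g. column
    SEs of the profile matrix) so the reported amplitude SE is calibrated.
    """
    from scipy.optimize import curve_fit
    from scipy.special import erf

    mask = ~np.isnan(profile.mean)
    x = profile.bin_centers[mask].astype(float)
    y = profile.mean[mask]
    h = float(np.diff(profile.bin_centers).min()) / 2.0  # half bin width

    def model(x, a, mu, s, b):
        s = abs(s) + 1e-9
        z1 = (x + h - mu) / (s * np.sqrt(2))
        z0 = (x - h - mu) / (s * np.sqrt(2))
        return b + a * s * np.sqrt(np.pi / 2) * (erf(z1) - erf(z0)) / (2 * h)

    baseline0 = float(np.median(y))
    extremum = y[np.argmax(np.abs(y - baseline0))]
    a0 = float(extremum - baseline0)
    p0 = [a0, 0.0, (x[-1] - x[0]) / 10, baseline0]
    sigma = se[mask] if se is not None else None
    popt, pcov = curve_fit(model, x, y, p0=p0, sigma=sigma,
                           absolute_sigma=se is not None, maxfev=20_000)
    return GaussianPeakFit(float(popt[0]), float(np.sqrt(pcov[0, 0])),
                           float(popt[1]), float(abs(popt[2])),
                           float(popt[3]))


def matrix_column_se(matrix: ProfileMatrix) -> np.ndarray:
    """Standard error of each bin's across-site mean."""
    n = np.sum(~np.isnan(matrix.values), axis=0)
    sd = np.nanstd(matrix.values, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, sd / np.sqrt(n), np.nan)


def central_flank_contrast(matrix: ProfileMatrix, central_bins: int = 5,
                           flank_bins: int = 20) -> tuple[float, float]:
    """Mean per-site center-minus-flank contrast and its SEM across sites.

    Pairing center and flank within each site keeps the error estimate valid
    when per-site profiles are correlated across bins (smooth signal); used
    to test enrichment/depletion direction and control-curve flatness.
    """
    vals = matrix.values
    nb = vals.shape[1]
    center = nb // 2
    ci = slice(center - central_bins // 2, center + central_bins // 2 + 1)
    fi = np.r_[0:flank_bins, nb - flank_bins:nb]
    with np.errstate(invalid="ignore"):
        contrast = np.nanmean(vals[:, ci], axis=1) - \
            np.nanmean(vals[:, fi], axis=1)
    contrast = contrast[~np.isnan(contrast)]
    if len(contrast) < 2:
        raise ValueError("need >= 2 sites with data for a contrast")
    sem = float(contrast.std(ddof=1) / np.sqrt(len(contrast)))
    return float(contrast.mean()), sem
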