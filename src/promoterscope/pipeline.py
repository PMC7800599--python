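"""End-to-end orchestration: simulate -> annotate -> colocalize -> profile -> qPCR.

The pipeline is a thin, logged sequencer over the library modules: each
stage reads the previous stage's declared outputs (or in-memory objects in
synthetic mode), writes parameter-stamped TSV/BED/WIG files, and the run
manifest records versions, parameters, seeds and output digests so a run can
be reproduced bit-identically (tables; the manifest itself carries a
wall-clock timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .colocalization import pairwise_fraction_table, venn_counts
from .expression_response import expression_table, knockdown_efficiency
from .genome_model import genome_category_fractions, write_genes_gff3
from .io_formats import write_bed, write_tsv, write_wig
from .metaprofile import three_curve_bundle
from .peak_annotation import (annotate_peaks, annotated_to_bed,
                              category_distribution, distribution_table)
from .synthetic_data import (SimulationConfig, generate_qpcr,
                             generate_signal_track, plant_overlap_pair,
                             plant_peaks, simulate_partitioned_genome,
                             sites_to_peak_records)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    version: str
    timestamp: str
    seed: int
    parameters: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: SimulationConfig, out_dir,
                      profile_flank: int = 2000, profile_bin: int = 50,
                      write_tracks: bool = True) -> RunManifest:
    """Run the full synthetic workflow and write all result tables.

    With ``config.qpcr_replicates == 0`` the expression stage is skipped
    with a logged notice.  Identical configs (hence seeds) produce
    byte-identical result tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(__version__,
                           datetime.now(timezone.utc).isoformat(),
                           config.seed, config.to_dict())

    def deliver(name: str, writer) -> Path:
        path = out / name
        with open(path, "w") as fh:
            writer(fh)
        manifest.outputs[name] = _sha256(path)
        return path

    stage = "simulate"
    try:
        chrom_sizes, genes, partition = simulate_partitioned_genome(config)
        peaks = plant_peaks(partition, config, seed=config.seed + 1)
        records = sites_to_peak_records(peaks, chrom_sizes)
        set_a, set_b = plant_overlap_pair(
            chrom_sizes, n=min(config.n_peaks, 500), fraction=0.60,
            seed=config.seed + 2, flank=config.peak_flank)
        factor_track = generate_signal_track(chrom_sizes, peaks, config,
                                             "enrich", seed=config.seed + 3)
        histone_track = generate_signal_track(chrom_sizes, peaks, config,
                                              "deplete", seed=config.seed + 4)
        deliver("chrom.sizes", chrom_sizes.write)
        deliver("genes.gff3", lambda fh: write_genes_gff3(genes, fh))
        deliver("partition.bed", partition.write_bed)
        deliver("peaks.bed", lambda fh: write_bed(records, fh))
        import pandas as pd
        truth = pd.DataFrame({"name": [r.name for r in records],
                              "chrom": peaks.chroms,
                              "anchor": peaks.positions,
                              "planted_category": peaks.metadata})
        deliver("peaks_truth.tsv",
                lambda fh: write_tsv(truth, fh, {"seed": config.seed}))
        if write_tracks:
            deliver("track_factor.wig",
                    lambda fh: write_wig(factor_track, fh))
            deliver("track_histone.wig",
                    lambda fh: write_wig(histone_track, fh))
        logger.info("simulate: %d genes, %d peaks on %d chromosomes",
                    len(genes), len(peaks), len(chrom_sizes))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    stage = "annotate"
    try:
        params = {"flank": config.peak_flank, "min_overlap": config.min_overlap,
                  "tss_window": config.tss_window,
                  "tes_window": config.tes_window, "seed": config.seed}
        annotated = annotate_peaks(records, partition, chrom_sizes,
                                   config.peak_flank, config.min_overlap)
        dist = category_distribution(annotated, params)
        table = distribution_table(dist, genome_category_fractions(partition))
        deliver("annotated_peaks.bed",
                lambda fh: annotated_to_bed(annotated, fh, params))
        deliver("category_distribution.tsv",
                lambda fh: write_tsv(table, fh, params))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "colocalize"
    try:
        sets = {"setA": set_a, "setB": set_b}
        result = venn_counts(sets, reference="setA",
                             min_overlap=config.min_overlap)
        frac = pairwise_fraction_table(sets, config.min_overlap)
        deliver("colocalization_venn.tsv",
                lambda fh: write_tsv(result.to_frame(), fh,
                                     {"min_overlap": config.min_overlap,
                                      "reference": "setA"}))
        deliver("colocalization_fractions.tsv",
                lambda fh: write_tsv(frac, fh,
                                     {"min_overlap": config.min_overlap}))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "metaprofile"
    try:
        for label, track in (("factor", factor_track),
                             ("histone", histone_track)):
            bundle = three_curve_bundle(track, peaks, genes, chrom_sizes,
                                        seed=config.seed + 5,
                                        flank=profile_flank,
                                        bin_width=profile_bin)
            deliver(f"metaprofile_{label}.tsv",
                    lambda fh, b=bundle: write_tsv(
                        b.to_frame(), fh,
                        {"flank": profile_flank, "bin": profile_bin,
                         "seed": config.seed + 5, "track": label}))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "qpcr"
    if config.qpcr_replicates == 0:
        logger.info("qpcr: no replicates configured, stage skipped")
    else:
        try:
            ct, truth = generate_qpcr(config, seed=config.seed + 6)
            deliver("qpcr_ct.tsv", ct.write_tsv)
            deliver("qpcr_truth.tsv",
                    lambda fh: write_tsv(truth, fh, {"seed": config.seed + 6}))
            expr = expression_table(ct, config.efficiency)
            kd = knockdown_efficiency(ct, config.target_gene, config.efficiency)
            deliver("expression_response.tsv",
                    lambda fh: write_tsv(
                        expr, fh,
                        {"reference": config.reference_gene,
                         "efficiency": config.efficiency,
                         "knockdown_fold_decrease": round(kd.fold_decrease, 4),
                         "knockdown_effective": kd.effective}))
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    manifest.write(out / "run_manifest.json")
    logger.info("wrote %d outputs to %s", len(manifest.outputs), out)
    return manifest
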