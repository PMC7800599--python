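# Methods

## Genome partition and priority annotation

Gene models (one record per gene; no isoform handling) induce three
candidate region types per gene: a TSS window (upstream, downstream) around
the strand-aware start, a TES window around the strand-aware end, and the
gene span itself. For a minus-strand gene the windows mirror around the end
coordinate, so "upstream" points toward larger coordinates; the promoter
anchor used by samplers is the last base of the gene span, keeping anchors
within chromosome bounds. Windows are clipped at chromosome boundaries.

Every base takes the highest-priority category among the candidate regions
covering it, in the fixed order TSS > TES > gene body, intergenic
elsewhere. The priority is applied per base across *all* genes, not per
gene — the only reading that yields a well-defined exhaustive partition
when regions of different genes overlap. The implementation is a sweep
line over region endpoints with per-category active counts; the test suite
compares it, at every base, against an independent dense labeler that
paints categories in ascending priority.

Defaults: TSS and TES windows (200, 200) bp. The window widths are
genuinely free parameters of this analysis; 200 bp on each side is a
conventional promoter-proximal scale for a compact genome, and both are
recorded in every output header so results are self-describing.

Peak anchors are the summit when a summit column is present, else the
floored interval midpoint (deterministic and dialect-independent). The
peak region is anchor ± flank as the half-open window
[anchor − flank, anchor + flank + 1), i.e. 201 bp at the default
flank = 100, clipped at chromosome ends. A region is assigned the first
category among TSS, TES, gene body whose *total* overlapping bases reach
`min_overlap` (default 10); a region reaching the threshold in no
gene-linked category is intergenic even if it touches a TSS by fewer
bases. Overlap is summed per category across that category's intervals
rather than taken from the largest single block — the partition is
per-base, so category overlap is naturally a base count; the choice only
matters for regions straddling a category split and is documented here as
this toolkit's definition.

## Colocalization

Two peaks colocalize when min(end_a, end_b) − max(start_a, start_b) ≥ k
(default k = 10) on the same chromosome. Counting is membership-based per
reference peak: each reference peak is classified by the subset of other
sets it touches, so for three sets the four reference-containing Venn
regions are reported and sum to the reference set size. Physical-region
Venn semantics would require a peak-merging rule across factors that this
analysis deliberately does not introduce; both directions of every
pairwise fraction are emitted instead, since the statistic is asymmetric.
The engine is an interval tree; an all-pairs quadratic comparison serves
as the oracle in tests up to 5,000 × 5,000 peaks.

## Meta-profiles

For each site, signal is averaged in `bin_width` windows centered on the
201 bin centers −flank, …, +flank (defaults 5,000/50). A bin's value is
the mean of defined per-base values in its span; spans off the chromosome
or without track data yield "no data", and the across-site average uses
available-data means per bin (zero-filling would bias edges). Profiles are
not strand-flipped: factor binding sites carry no strand. Tracks may be
raw coverage or ratios; `log2_enrichment` computes
log₂((T + p)/(C + p)) per base with pseudocount p (default 1.0) and
propagates missing data.

The three-curve bundle computes the factor curve plus promoter and
random-site controls of identical size n, sampled without replacement
(promoters) and proportionally to usable chromosome length (random sites,
kept ≥ flank from ends) from seeds derived deterministically from the
bundle seed.

Two summary statistics support inference on planted signal. The
center-vs-flank contrast is computed **per site** (mean of 5 central bins
minus mean of 40 flank bins) and summarized by its mean and SEM across
sites; pairing within sites keeps the SEM valid although neighboring bins
of one site are strongly correlated. Peak recovery fits
baseline + a·Gaussian(μ, σ) to the averaged curve by least squares, using
the *bin-integrated* Gaussian as the forward model — fitting a
point-evaluated Gaussian to binned data attenuates the amplitude by
roughly bin²/(24σ²) and that bias is avoided rather than tolerated. Per-bin
standard errors from the profile matrix calibrate the amplitude SE.

## Expression response

ΔΔCt with configurable amplification efficiency E (default 2.0, perfect
doubling): ΔCt = Ct(gene) − Ct(reference) within each (condition,
replicate); ΔΔCt differences the condition means; fold = E^(−ΔΔCt).
Replicates are paired by replicate id when both conditions share ids,
otherwise per-knockdown-replicate estimates are taken against the mean
control ΔCt; the mode used is reported. The SEM is computed over
per-replicate fold-change estimates, i.e. on the axis the error bars live
on. Classification at threshold t (default 0.20) is inclusive on both
boundaries: down iff fold ≤ 1 − t, up iff fold ≥ 1 + t. Knockdown
efficiency is the reciprocal fold change of the target's own mRNA with an
adequacy flag at ≥ 5-fold (inclusive, tolerant to float round-off).
Adding a constant to every Ct of one replicate — a pipetting offset —
cancels exactly in ΔCt; the generator plants such offsets to keep this
invariant honest.

## Synthetic data

The generator emulates the shape of a promoter-bound factor study in a
desk-sized setting. Defaults: a 9.6 Mb genome on three chromosomes, 1,000
non-overlapping genes (1.5–6 kb, gaps 1.2–6 kb, the first gap per
chromosome widened to guarantee wide intergenic planting room), 1,000
peaks planted at category fractions (0.732, 0.05, 0.15, 0.068) — a
promoter-heavy composition — with largest-remainder rounding so planted
counts are exact and distribution tests are exact rather than stochastic.
Anchors are placed so the whole ±100 bp region sits inside a single
partition interval of the target category, making annotation unambiguous
under the priority rule; ambiguous straddling regions are exercised by
hand-built fixtures instead. Signal tracks are per-base
Normal(10, 2) background truncated at zero with Gaussian bumps of
amplitude 4 and σ = 300 bp added (enrichment) or subtracted
(histone-style depletion) at sites. The qPCR panel plants 7 genes at fold
0.5, 3 at 1.5, 11 at 1.0 with 3 replicates and Ct noise σ = 0.05 cycles,
plus an 8-fold knockdown of the factor itself and a reference gene fixed
at fold 1.

Two auxiliary generators exist because exactness by construction needs
geometric control: `plant_overlap_pair` places anchors on a lattice whose
spacing exceeds two region widths so a chosen subset — and nothing else —
overlaps, making planted colocalization fractions exact; `lattice_sites`
provides well-separated profile sites so no ±5 kb window sees a
neighbor's bump.

What the generator does **not** emulate: read-level sampling noise and
mappability structure, sequence content and motifs, peak-caller artifacts,
transcript isoforms, correlated biological replicate structure in qPCR.
Passing tests therefore demonstrate correctness of the computations on
data satisfying the planting contracts, not robustness to every artifact
of real ChIP-Seq.

## Numerical and I/O choices

Intervals are 0-based half-open internally; GFF and WIG convert at the
boundary (WIG declared start 1 ↔ internal base 0). Signal tracks are dense
per-base float arrays with NaN as the "no data" state; the WIG writer
emits per-base fixedStep runs with `repr` floats so read∘write is
bit-exact, and the reader accepts fixedStep and variableStep with
UCSC-standard step/span defaults. All randomness flows through
`numpy.random.default_rng` with explicit integer seeds and no global
state; derived seeds (controls, pipeline stages) are fixed affine
functions of the run seed. Result tables are TSV with a commented header
recording version and parameters. Figures are not produced — every result
is a table, which keeps outputs diffable and the dependency surface small.

Problem sizes in tests and the acceptance script (10⁴ oracle instances,
1,000-peak and 1,000-site studies, 5,000-peak overlap oracle) were chosen
as the smallest scales at which every planted effect is resolved with wide
statistical margin.

## Known limitations

- One TSS/TES per gene record; multi-transcript collapsing is the
  annotation provider's job upstream.
- Venn counts are reference-membership counts, not merged-region areas.
- Dense track storage assumes desk-scale genomes (≲ tens of Mb); no
  bigWig streaming.
- No statistical significance testing of overlaps (no permutation
  p-values) and no primer-efficiency calibration — out of scope by
  design.
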