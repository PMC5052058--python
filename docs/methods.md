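# Methods

This note records the models, estimators and numerical choices behind
`repairmap`, and what the synthetic-data tests do and do not demonstrate.

## Signal model and conventions

All probe values are log2-scale arbitrary units; replicate noise is additive
Gaussian on that scale.  Coordinates are 0-based half-open internally;
GFF3's 1-based inclusive convention is converted only at file boundaries.
Strand affects only TSS/TES anchoring and profile orientation, never the
signal itself (damage assays read both strands).

A `ProbeTrack` is a sorted, non-overlapping set of intervals with one value
each; a `SignalSet` is a replicate group on one shared probe grid, tagged
with strain, factor/mark and UV timepoint.  Dispersion bands follow the
convention SEM for n ≥ 3 replicates and SD for n = 2.

## The synthetic generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated by parameter recovery.

**Genome layout.**  Genes tile each chromosome in gene-plus-gap slots: a
leading intergenic gap is drawn (so the first gene has a promoter region),
then gene length and following gap are drawn from uniform ranges (defaults
300–3000 bp and 200–1500 bp, a compact yeast-like density); a gene is placed
only if its full slot fits, so the last partial slot is dropped.  Strands
are random; expression is lognormal.

**Abf1 sites** are placed 50–500 bp upstream of the TSS with probability
0.6 and 50–500 bp downstream of the TES with probability 0.15.  Sites
closer than 1500 bp to an already-kept site are thinned: with 250 bp probes,
a ~200 bp peak width and gap-tolerant run merging, sites closer than about
six probe spacings produce one contiguous enriched region and are not
independently resolvable by *any* probe-level method, so planting them as
distinct recoverable truth would make "recovery" ill-posed.  The thinning
threshold is config-exposed.

**Damage and repair.**  The t0 CPD field is i.i.d. lognormal per probe
(heterogeneous induction).  The per-probe repair amount between t0 and the
repair timepoint is

    repair(p) = base + tc · rank(expr_gene) · [p in ORF] + gg_eff · exp(−d/λ)

with `d` the distance to the nearest Abf1 site, λ = 1000 bp, and defaults
base 0.2, tc 0.4, gg 0.6 log2 units.  Expression enters as its quantile
rank in [0, 1]: the spec of a "boost scaled by expression" leaves the
functional form open, and the rank keeps the increment bounded while giving
the lowest-expression stratum a near-zero gene-body boost, matching the
observation that silent genes show little body enhancement.  The repair
amount is clamped so the t120 signal never drops below a floor (default 0).
Mutant scenarios scale the GG component: `rad16_null` 0 (pathway
abolished), `gcn5_null` 0.4, `rad16_ring`/`rad16_atpase` 0.5,
`rad16_double` 0.1 — qualitative residual-function factors, config-exposed.
Noise streams are deliberately independent of scenario, so same-seed tracks
for two scenarios differ exactly by the planted model terms.

**Binding.**  Gaussian peaks (σ = 200 bp) of height 3.0 log2 units over a
flat zero background.  The default height is set by the detector's design
point, not tuned to it: with z-threshold 2, three required probes and
250 bp spacing, a σ = 200 peak needs roughly 12 background spreads of
amplitude on the replicate-mean track to guarantee three supra-threshold
probes at the worst probe phase; 3.0 log2 units at noise 0.3/√3 gives
~17 spreads, comfortably above that bound and within the range of strong
sequence-specific factor peaks.  Post-UV, a chosen fraction of each peak's
probe-summed mass moves into a uniform increment over the nearest ORF's
probes; total mass is conserved exactly.

**Acetylation.**  Two symmetric Gaussian lobes (σ = 150 bp) at ±offset
(300 bp pre-UV, 500 bp post-UV by default), multiplied by a central dip
`1 − exp(−d²/2h²)` with h = 100 bp representing the nucleosome-free region;
UV adds an induction amplitude to the lobes.

What the generator does **not** emulate: sequence-level dipyrimidine
placement, strand-specific repair, nucleosome positioning beyond the NFR
dip, spatially correlated array artifacts, dye bias, or non-Gaussian noise.
Passing tests therefore demonstrate algorithmic correctness under the
planted model, not robustness to every artifact of real arrays.

## Normalization

**Quantile normalization** replaces the rank-r value of each replicate with
the mean of the r-th order statistics across replicates; tied values within
a track receive the mean of their targets.  After it, sorted value vectors
are identical across replicates (exactly, when values are distinct — the
tie rule takes precedence otherwise) and within-track rank order is
preserved.

**Background standardization** models an enrichment track as a dominant
background plus a contaminated right tail.  The center is the argmax of a
Gaussian KDE; the bandwidth uses a Silverman-style plug-in factor at the
n^(−1/7) rate, which is the optimal rate for *mode* (rather than density)
estimation — at the usual n^(−1/5) bandwidth the peak location of the KDE
is noisy enough (±0.05–0.1 background SDs at n = 10⁵) to violate a 5%
recovery tolerance a third of the time.  The scale is 1.4826 × the median
absolute deviation over probes at or below the mode, which the enriched
tail cannot inflate; `fraction_enriched` is the fraction of probes more
than two spreads above the mode in excess of the 2.275% a pure Gaussian
places there, so an uncontaminated track reports ≈ 0.  Standardization is
invariant to positive affine transforms and idempotent up to estimator
noise.

**Order of the full mode**: standardize each replicate first, then quantile
across replicates — a high-background replicate would otherwise dominate
the rank targets.  CPD sets are never background-standardized: a damage
distribution has no clean unenriched background component.

## Peak detection

Probes whose standardized value exceeds `z_threshold` (default 2) are
flagged; runs of flagged probes tolerating up to `max_gap_probes` (default
1) unflagged probes are merged; runs with fewer than `min_probes` (default
3) flagged probes are discarded.  Defaults are documented as conventional,
not optimal.  Each region yields one site at the z-weighted centroid of its
flagged probes (sub-probe localization for symmetric peaks), scored by the
mean z over the region span (gap probes included).  On pure N(0,1) noise
the false-site rate is bounded by a union-bound estimate of
(probes/Mb) · 4 · P(z>2)³ ≈ 0.19 sites/Mb and measured below that in
seeded simulation.

## Composite profiles

Gene profiles use fixed-bp flank bins (default 2 kb flanks, 50 bp bins) and
a length-normalized gene body (default 40 fractional bins); point profiles
bin signed distance to the site midpoint (default ±2 kb).  Bin widths are
chosen to roughly match probe density and are config-exposed.

**Deduplication.**  Each probe contributes to at most one feature window.
Where windows overlap, the probe goes to the feature whose nearest anchor
(ORF start/end, or site midpoint) is closest to the probe midpoint; exact
ties go to the lower feature index.  The same rule attaches sites to genes
for localization, so a site in a shared intergenic gap is classified
relative to its *nearer* gene — with dense gene spacing an appreciable
fraction of promoter-planted sites legitimately classify as "downstream" of
the preceding gene.

**Minus-strand genes** take the exact complement bin (N−1 minus the
plus-strand bin), so flipping every strand reverses a profile exactly,
including probes that fall on bin boundaries.  Probes straddling TSS/TES
are assigned by midpoint.

**Dispersion.**  For a replicate set, the profile is computed per replicate
and combined with SEM (SD for n = 2) across replicate profiles; for a
single track, the per-bin SEM over contributing probes is used.
Empty bins carry NaN and propagate as empty through differences.

**Flat-null calibration.**  The control for profile artifacts is the
profile of a stationary noise track over random non-overlapping intervals,
which must be flat.  A naive "no bin beyond 3 SE" rule is mis-calibrated:
with ~120 bins the maximum |z| of a perfectly flat profile exceeds 3
in roughly a quarter of runs, and bins with few contributions have
Student-t rather than normal statistics.  `flatness_check` therefore scores
each bin against a per-bin t quantile (df = contributions − 1) at a
Šidák-corrected level, so a truly flat profile passes at the stated
family-wise rate regardless of bin count.  Low-count bins (n ≤ 1) are
untestable and excluded.

**Expression stratification** splits genes at the 0.15 expression quantile
(ties at the cut go to the low stratum; genes without expression are
excluded).  Note that far-flank composite bins absorb signal from
neighboring transcribed genes under the dedup rule, so stratum contrasts
are assessed on gene-body bins, where the planted expression-rank contrast
is recovered to within a few hundredths of a log2 unit.

## Domain analysis

Profile differences subtract bin means and combine dispersions in
quadrature; the operation is linear, so the nested difference
(WT post−pre) − (mutant post−pre) equals (WT−mutant)post − (WT−mutant)pre
bin-wise, exactly.  A domain is the maximal contiguous bin run containing
the difference peak with values at or above half the peak (fraction
config-exposed); the call is invariant to positive rescaling.  Profile
correlation is unweighted Pearson over shared non-empty bins (a
contribution-weighted variant would privilege body bins; the unweighted
choice is documented and deliberate).

A structural note: the repair deficit around sites follows the planted
monotone exponential (scale ~1 kb) while the acetylation deficit follows
the lobes-with-central-dip kernel, so their bin-wise Pearson correlation is
positive but bounded near ~0.6–0.7 — the two deficits co-locate in the same
promoter-proximal domain without being shape-identical.

## Pipeline and reproducibility

Manifest-driven runs execute named steps over a shared object registry;
every output is stamped with parameters, seed and package version, and a
failed step aborts with its name and cause, leaving a FAILED marker beside
partial outputs.  The global seed fans out to per-stage seeds by CRC-32
hashing of stage names, so inserting a stage does not perturb the
randomness of others.  All generator randomness flows through
`numpy.random.default_rng` with explicit integer stream keys; identical
(spec, seed) pairs produce byte-identical serialized outputs.

## Problem sizes

Tests and the acceptance script run on compact genomes — 0.25–0.5 Mb for
unit tests, ~2.3 Mb with ~500 planted sites for study-scale recovery checks
— sizes at which every qualitative structure (replicate noise averaging,
site density, window overlap, dedup contention) is fully exercised while
whole-suite runs stay in seconds.

## Known limitations

* Detection assumes approximately symmetric peaks; strongly skewed peaks
  would bias the weighted centroid.
* Sites closer than the array's resolving distance are thinned at
  generation rather than modeled as merged truth.
* Background standardization assumes the background is the majority
  component; tracks that are mostly enriched violate the left-half MAD
  premise.
* Repair rates are relative, two-timepoint quantities; no kinetic curve
  fitting or absolute lesion-frequency calibration is attempted.
* Quantile normalization is per-timepoint by default; a joint mode across
  timepoints is available but changes the interpretation of rate zero.
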