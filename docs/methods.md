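# Methods

## Signal model and coordinate conventions

All coordinates are 0-based half-open (BED convention) internally and on
disk; positions are converted to 1-based only in human-readable text. A
*fragment* (one concordantly aligned read pair) is the unit of signal. In
NET-seq mode the informative position is the RNA 3′ end — the base the
polymerase most recently transcribed: for a '+'-strand RNA this is `end − 1`
of the half-open span, for a '−'-strand RNA it is `start`. Tracks store dense
per-base integer counts per (chromosome, strand) with the retained library
size; in 3′-end mode the track total always equals the retained fragment
count. Because the RNA-strand encoding of paired-end protocols is
kit-dependent, ingestion takes a `strand_is_rna` flag (default: the stored
strand is the RNA strand). The MAPQ cutoff defaults to 30 — enough to exclude
multi-mappers under common aligners — and is configurable.

## Gene filters

Metagene and readthrough statistics are only meaningful on genes whose
neighbourhood is not confounded by another transcription unit. Two filters
implement this:

- **Expression**: TPM computed per gene from strand-matched counts
  (TPM_g = (c_g/L_g)/Σ_h(c_h/L_h) × 10⁶; ties at the threshold are kept).
  The default cutoff is TPM ≥ 1 — conventional, and configurable since no
  canonical value exists.
- **Isolation** (NET-seq mode): gene g is kept iff no other expressed gene's
  span intersects [TES_g − 1250, TES_g + 15,250], oriented so that positive
  offsets point downstream of transcription. Orienting the window by strand
  is our choice (readthrough is downstream of the TES); the window bounds are
  the standard exclusion range for TES-anchored termination metagenes.
- **Isolation** (RNA-seq mode): transcriptional windows
  [TSS − 3 kb, TES + 7 kb] of expressed genes must not overlap; an optional
  strict mode additionally demands zero reads in the window outside the
  gene's own span (requires a track; off by default because it is
  noise-sensitive).

## Metagene profiles

The TES-anchored profile evaluates, for every nucleotide offset in
[−1250, +15,250], the sum of 3′-end counts in a centred 5-bp window (step 1,
truncated at chromosome edges) and averages over genes. Antisense values come
from the opposite-strand track over the same windows and are stored
separately (negated only for display). Normalizations: `per_1e8` (counts ×
10⁸/library size — the track-level convention for displaying single-gene and
averaged occupancy), `tpm_window` (window counts normalized by the same
library factor as gene TPM, window length as the length term), or `raw`.
Whether window TPM should be normalized library-wide or within the profiled
region is genuinely ambiguous; we normalize library-wide and keep `per_1e8`
as the default.

The scaled-body profile (RNA-seq coverage) keeps fixed 10-base flank bins
(3 kb upstream of the TSS, 7 kb past the TES) and linearly rebins each gene
body into 1000 bins by exact mass-preserving interpolation; per-bin
RPKM = count × 10⁹/(bin length × library size). Genes shorter than the bin
count are skipped and counted. Bin sizes are our choice; published analyses
delegate this step to generic profiling tools without printing them.

## Readthrough statistics

Per gene, with offsets oriented downstream of transcription:

- **US density**: mean per-base density over [TES − 2000, TES − 500). The
  500 bases nearest the TES are excluded to avoid PAS-proximal pausing
  signal.
- **Ratios**: mean density in a 500-base probe centred at each offset
  (defaults +5000 and +15,000; per-gene overrides accepted) divided by the
  US density. A zero denominator yields a missing value with a recorded
  reason, never an infinity; missingness propagates into summaries.
- **Background B̂**: two estimators.
  - `distal_quartile`: median 50-base-smoothed sense density over the most
    distal quarter of the flank window. Accurate when termination completes
    within the window; degenerates to the plateau level exactly when it does
    not.
  - `antisense` (default for termination calling): mean opposite-strand
    per-base density over the *gene body*. The body's antisense strand
    carries no termination-zone signal from this gene or its neighbours, so
    it reads the noise floor even when the sense flank never decays. The
    mean is used because per-base antisense counts are sparse (a median is
    typically 0). Opposite-strand signal sitting at background is itself an
    empirical property of this data type.
- **Termination point x_term**: the first offset where (a) the 50-base
  running-mean density is ≤ 1.5·B̂ *and* (b) the mean density over the
  following 20 smoothing windows (1000 bases) also stays ≤ 1.5·B̂. The
  pointwise test locates the crossing; the block mean verifies the signal
  *stays* at background — demanding every sparse-count window individually
  sit below threshold cannot distinguish termination from a counting-noise
  gap at realistic depth. Offsets whose evidence block would truncate at the
  flank-window end are not callable (a truncated tail block of a few dozen
  bases is routinely read-free by chance). No qualifying offset means "none
  called", which is a value, not an error: it is the expected outcome when
  PAS cleavage is lost. On a noiseless profile B + A·e^(−x/λ) the call lands
  at the analytic crossing λ·ln(A/((ε−1)B)) to within one smoothing width.
- **Decay length λ̂**: background-subtracted flank densities are aggregated
  into 100-base bins and log(density − B̂) is regressed on offset by least
  squares weighted by bin read counts (statsmodels WLS); λ̂ = −1/slope, SE by
  the delta method, R² reported. The fit covers the *termination zone only*:
  the leading contiguous run of bins above B̂. Bins past the first return to
  background are noise-floor fluctuations whose log-values would flatten the
  slope severely. Fewer than 5 usable bins or a non-negative slope is "no
  fit" with a diagnostic. The pooled (gene-summed) fit uses the
  distal-quartile background of the pooled profile.
- **Condition comparison**: per-offset mean ratio difference over the shared
  gene set with a percentile bootstrap CI resampling *genes* with
  replacement (gene-to-gene variability dominates metagene contrasts;
  `n_boot=0` gives point estimates only), plus the none-called fraction per
  condition.

## The simulator

The generator stands in for real nascent-RNA libraries. Per gene, the 3′-end
density in strand-oriented offset space is: uniform over the body at the
gene's relative rate d (rates log-normal, σ = 0.75); multiplied by Gaussian
pause peaks (kernel σ = 25 bases, 5-fold peak enrichment, 3 per body and 2
in the flank — stalling peaks are visible in real traces but not
parameterized there, so these are tuning knobs, not claims); and
d·e^(−x/λ) over flank offsets x ∈ (0, W], W = 15 kb. Conditions: `control`
λ = 200 bases (sharp termination within ~1 kb); `torpedo_impaired`
λ × 10 = 2000 with flank pause amplitude doubled (extended readthrough with
elevated stalling over the same positions); `cleavage_impaired` replaces the
decay with a non-decaying plateau at d. A 5% antisense fraction lands
uniformly on the opposite strand of each gene's region, and 5% of fragments
receive MAPQ < 30. Fragment lengths are uniform in 30–100 bases (only the 3′
end matters downstream). Annotation geometry places genes with > 16.5 kb
clearance so each is isolated by construction, except a configurable crowded
fraction built as (gene, partner) pairs with the partner inside the gene's
exclusion range but not vice versa — giving exact ground truth for the
isolation filter. Sampling is inverse-transform/categorical in oriented
offset space from a single seeded generator, which makes libraries
byte-reproducible and exactly equivariant under coordinate reflection with
strand flip.

What the simulator does *not* emulate: sequences and alignment error,
splicing, PAS motifs, promoter-proximal pausing structure, 5′→3′ positional
biases, or biological gene-class heterogeneity (histone, snRNA, pri-miRNA
3′-end pathways). Passing tests therefore demonstrate that the estimators
recover the parameters of this occupancy family and order the three regimes
correctly — not that real libraries satisfy the model.

## Problem sizes and numerical choices

Simulation-based checks use 50 genes × 2×10⁵ fragments per condition, a λ
grid of {200, 1000, 5000} bases with 3 seeds, and 10⁵-fragment single-gene
libraries for the flank-mass law (agreement required within 3 binomial
standard errors; the closed form is itself validated against quadrature to
1e−9 relative). These sizes give stable statistics at desk scale; all sizes
are parameters. Window sums use cumulative-sum arithmetic and match
brute-force re-summation exactly on random fixtures. bedGraph output merges
equal-value runs, omits zeros by default, and round-trips counts exactly
(float values are written with full repr precision). Degenerate inputs have
defined behaviour throughout: empty gene sets raise (an empty metagene would
silently average nothing), empty libraries and all-zero tracks are valid,
and a gene set yielding no eligible genes aborts the pipeline with a
dedicated exit code.

## Known limitations

- λ̂ is biased low by ~25–30% when λ approaches a third of the flank window
  (decay incomplete within 15 kb, so the distal-quartile background absorbs
  real signal). Recovery at λ ≤ 1000 is within a few percent; the median
  error across the tested grid is ~5%.
- The ratio/x_term/λ̂ trio is an operationalization: published termination
  analyses probe fixed offsets and show the decline but define no
  genome-wide readthrough statistic. Defaults (ε = 1.5, 50-base smoothing,
  20-window evidence span, 100-base fit bins) are declared constants, all
  configurable.
- Gene models are single-span (longest isoform at load); no isoform-resolved
  TES calling, PAS-motif detection, or alternative-polyadenylation analysis.
- The minimal SAM dialect covers ungapped (M-only) alignments; CIGAR
  arithmetic, duplicate marking and BAM indexing are out of scope.
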