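# Methods

## Model and assumptions

`promotercalc` treats transcription initiation by RNAP/σ<sup>70</sup> as a
two-state equilibrium: the holoenzyme is either free or bound at a promoter
with a stable transcription bubble. Under rapid equilibration (σ-factor in
excess over free polymerase, binding sites in excess over free holoenzyme,
fast turnover after termination) the initiation rate at a site is
proportional to its equilibrium occupancy,

    C_i = R_total · P_i · exp(−β ΔG_total,i) / Z,
    Z = 1 + Σ_j P_j · exp(−β ΔG_total,j),

where P_i is the DNA copy number and R_total the available holoenzyme.
Because Z and R_total are properties of the whole system, all predictions
are made relative to a reference promoter measured under the same
conditions:

    TX_i / TX_ref = exp(−β (ΔG_total,i − ΔG_total,ref)).

The model is deliberately coarse: no transcriptional pausing intermediates,
no alternative σ-factors, no transcription-factor regulation, no RNAP
collisions or supercoiling. Those are the known limitations of the two-state
treatment; they are out of scope here.

ΔG_total decomposes additively over seven sequence regions (UP, −35,
spacer, extended −10, −10, discriminator, ITR). Each region's energy is a
linear function of the 346-entry feature vector described below, so the
fitted coefficients are directly interpretable as interaction energies.

### Units and calibration

All energies are in RT units and β is fixed at 1.0: the coefficients are
fitted to natural-log rates, so any other β would be absorbed into them.
ΔG_total,ref is fixed at 0 and TX_ref is calibrated during training so that
predictions line up with the min-normalized measurement scale; the reference
promoter is the record whose log rate is closest to the dataset's
log-mean-center (a well-measured, mid-range promoter).

### Feature space (346 coefficients)

| block | features | count |
|---|---|---|
| −35 hexamer | 3-mers at positions 1–3 and 4–6 | 128 |
| −10 hexamer | 3-mers at positions 1–3 and 4–6 | 128 |
| discriminator | 3-mer of the first three nucleotides | 64 |
| extended −10 | 2-mer abutting the −10 hexamer | 16 |
| spacer length | categories 15–20 bp | 6 |
| spacer rigidity | mean dinucleotide stiffness | 1 |
| UP minor groove width | distal and proximal 10-bp half-sites | 2 |
| R-loop stability | first 15 transcribed nt | 1 |

The extended −10 window is defined as the 3'-terminal 4 nt of the spacer;
only its downstream 2-mer is encoded (the upstream 2-mer carries no signal
and is pruned). Discriminator nucleotides beyond the first three likewise
contribute no features. Ambiguity codes (N, etc.) are rejected rather than
marginalized.

Numeric features are divided by stored normalizers (maximum possible values
derived from the shape tables by default). The normalizers live inside
`EnergyModelParams` rather than being recomputed per dataset, so predictions
are reproducible. Note that the R-loop feature is a free-energy *difference*
and can be negative; after normalization it lies in [−1, 1] while the other
numeric features lie in (0, 1].

### Shape and thermodynamic tables

Four lookup tables feed the numeric features; all load from TSV and are
swappable, and trained coefficients are only meaningful with the tables in
force at training time, so a table checksum is pinned inside the parameter
set and verified at prediction time.

* DNA:DNA nearest-neighbor ΔG°37: SantaLucia (1998) unified parameters.
* RNA:DNA hybrid ΔG°37: Sugimoto (1995) parameters, keyed by the coding-
  strand DNA 2-mer.
* Pentamer minor-groove width and dinucleotide stiffness: **synthetic**
  additive stand-ins (marked `_synthetic` in filename and header) that
  follow the qualitative trends of published high-throughput shape tables
  (AT-tracts narrow the groove and stiffen the helix; pyrimidine–purine
  steps are flexible). Swap in measured tables for production use on real
  data.

Within a 10-bp UP half-site the six pentamer widths are averaged
(unweighted), as are dinucleotide stiffness steps over the spacer; the
R-loop term sums the 14 nearest-neighbor steps of the first 15 ITR
nucleotides. Mean aggregation is a documented choice; nothing in the model
structure depends on it.

## Scanner

At a candidate TSS the scanner enumerates spacer length 15–20 ×
discriminator length 5–10 (36 tilings), scores each and keeps the most
negative ΔG_total. Ties break deterministically: |spacer − 17| ascending,
then smaller discriminator, then smaller spacer — profiles are therefore
bit-stable. Linear sequences are evaluated only at positions with full
context for *all* 36 tilings (62 nt upstream, 20 nt downstream), so the
argmin is always over the complete enumeration; circular sequences evaluate
every position by wrapping. The reverse strand is scored by running the
identical forward computation on the reverse complement and re-mapping
coordinates, which makes strand symmetry exact by construction. No silent
padding is ever applied; callers can supply explicit flanking context
instead.

## Training

Measured rates are log-transformed and normalized by the dataset minimum
(y = ln TX/TX_min ≥ 0). Each promoter is reduced to one binding
configuration: from recorded design annotations when available, otherwise
by scanning placements around the measured predominant TSS with
consensus-derived PWMs (match probability 0.7, pseudocount spread over the
other bases; score ties resolve toward the 17-bp spacer). Ridge regression
with an explicit intercept is fitted on the 346 features; the
regularization strength is chosen by 10-fold cross-validation over a
logarithmic grid 1e−4…1e2. Fitted weights are negated into energies
(favorable motifs negative), and each one-hot block is centered to mean
zero — the blocks are collinear with the intercept, so block-centered
energies are the only identifiable parameterization; the offsets are
absorbed into the TX_ref calibration. Unobserved categorical levels keep
energy 0 with a warning. A single integer seed controls the train/test
split and fold assignment, making reports bit-reproducible.

Supporting analyses:

* **Feature-drop analysis** retrains without a named feature group and
  reports the test-MAE delta, with a pruning recommendation below a
  tolerance (default 0.02 RT).
* **Variance decomposition** attributes measured log-rate variance to the
  seven predicted energy terms by sequential (type-I) sums of squares in
  fixed order (UP, −35, spacer, −10ext, −10, disc, ITR); fractions plus the
  residual sum to exactly 1, and constant terms contribute 0.
* **Quadratic extension** augments the six region energies (the extended
  −10 folds into the spacer region) with all 30 ordered pairwise products,
  fitted by least squares. Ordered duplicates make the design rank
  deficient by construction; the minimum-norm pseudo-inverse solution is
  used and flagged. This model exists to *test* for inter-motif
  cooperativity; the linear model remains the production path.
* **Positive controls** check that TTGACA, TATAAT, TG and the 17-bp spacer
  carry strictly minimal energies in their blocks; ties are reported as
  failures.

LASSO/Elastic-Net variants and the mono-nucleotide (PWM-style) hexamer
encoding are deliberately not production paths.

## Measurement pipeline

Barcodes (20 nt, minimum pairwise Hamming distance 2, optional k-mer
blocklist) are designed greedily with rejection, seed-deterministically.
Read assignment is asymmetric on purpose: RNA barcode fields may be 1
Levenshtein edit from a unique barcode (edlib), while DNA reads require an
exact barcode *and* an exact promoter match — mis-mapped DNA would corrupt
the normalization denominator. Every read is classified exactly once
(counted or discarded with a reason code).

Rates follow r_ij = (RNA_ij/DNA_ij)·(ΣDNA_j/ΣRNA_j) with sums over the
variants included in replicate j (DNA_ij > 0); the DNA-weighted mean of
r_ij is exactly 1 per replicate, an identity the tests verify to 1e−12.

TSS-mapping reads are anchored on a constant flanking sequence; the
adjacent transcript fragment is accepted only when it matches the variant's
reference perfectly at exactly one start location (a unique-exact-occurrence
search; fragments with any mismatch or multiple hits are discarded).

Training-set filtering intersects three criteria: ≥ 50 RNA and ≥ 50 DNA
counts — read as *per replicate*, the stricter of the two possible readings,
switchable to summed; a predominant TSS with at least twice the runner-up's
reads; and the predominant TSS within a 10-bp-wide window of the anticipated
location (±5 by default; a ±10 reading is available by flag). The
high-precision filter keeps CV < 0.40 (strict).

## Designers

* **Background generator**: rejection sampling to a GC target (±0.05,
  default 0.508), with forbidden restriction sites excluded and any 6-mer
  window scoring above a PWM ceiling (default: five or more consensus
  matches) rejected — no cryptic hexamers.
* **Library generator**: seven subsets totalling 14,206 unique variants.
  The −10 (4096), −35 (4096) and extended −10 (256 × 8 backgrounds = 2048)
  subsets are exhaustive enumerations; the UP (605 × 4 = 2420), spacer
  (229, lengths 1–32 bp), discriminator (735) and ITR (582) subsets are
  generated by their design rules with the subset sizes taken as inputs —
  the sampled sets are rule-faithful, not byte-identical to any particular
  historical library. Each subset is built in its own optimized background,
  which both mirrors per-subset design contexts and guarantees global
  uniqueness (a shared background would make the all-consensus member of
  the −10 and −35 enumerations collide).
* **Promoter annealer**: geometric cooling T = 2.0 → 0.01 over 5000
  single-nucleotide substitution proposals by default; cost is the summed
  squared log-rate error at the targets plus (optionally) a worst-offender
  off-target penalty (max rather than sum — switchable). Flanks are fixed,
  forbidden motifs rejected per move, and the best-so-far sequence is
  returned, so the reported cost trace is non-increasing. When the
  off-target penalty is zero only the target sites are rescored per move,
  which is an exact shortcut. Tests and examples use shorter schedules
  (hundreds of proposals) sized to their small windows.
* **Silent-DNA designer**: minimizes the maximum predicted rate over both
  strands, either over free sequence ("no-promoter" regions) or over
  synonymous codon substitutions with the protein sequence preserved
  exactly (standard genetic code via Biopython).

All designers are seed-deterministic.

## Circuit debugging

TSS calls require a predicted rate at least threefold (inclusive) above the
per-strand mean; adjacent qualifying positions within 5 nt merge to their
local maximum (real profiles plateau; merging is disableable). Predicted
calls are compared to measured TSS lists by precision-style accuracy
(matched within a 10-bp window, divided by predictions; undefined when
nothing was predicted). Context sensitivity is quantified by embedding a
core promoter between random 30-bp flank pairs (uniform base composition,
10,000 draws by default) and summarizing the per-context maximum rate
(mean, CV, quartiles, 1.5-IQR outliers); a fixed-TSS aggregation mode is
available instead of the maximum.

## Synthetic data

The generator emulates the *statistical structure* of barcoded in vitro
measurements: ground-truth energies are block-wise Gaussian (hexamer blocks
σ = 0.6 RT, other categorical blocks σ = 0.3 RT, numeric terms σ = 1.0 RT,
block-centered) with canonical features optionally forced 0.5 RT below
their block minimum; promoters are assembled from the configuration grammar
with at least one consensus hexamer anchor (mirroring how measurement
libraries anchor motif localization); replicate log-rates carry additive
Gaussian noise (default σ = 0.3 RT); reads are sampled multinomially with
fixed per-replicate totals (matching the estimator's normalization
structure), lognormal copy-number dispersion σ = 0.2, optional uniform
substitution errors and ±1 TSS jitter.

What passing synthetic tests does **not** show: performance on real data
with unmodeled biology (pausing, σ-factor competition, mRNA decay in vivo),
realistic error profiles, or shape tables other than the shipped stand-ins.
The round-trip and recovery properties demonstrate that the estimator and
trainer are *correct and well-conditioned*, not that the shipped demo
energies are biologically accurate.

## Numerical choices

* Recovery comparisons use block-centered energies and are run at n = 5000,
  σ = 0.3 RT (three seeds, R² ≥ 0.9) and noiselessly at α → 0
  (R² ≥ 0.999); these sizes keep the default suite in minutes.
* Energy additivity is maintained to 1e−9 RT; occupancy conserves the total
  holoenzyme to 1e−12 relative.
* Degenerate inputs fail loudly: non-ACGT bases, spacer/disc lengths
  outside range, linear positions without full context, zero-variance
  targets, k-fold CV with too few records, zero-DNA variants (excluded per
  replicate and flagged).
* Coordinates are 0-based half-open throughout; the TSS index is the first
  transcribed base.
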