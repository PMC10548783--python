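# Methods

## The model

A metal-loaded metallothionein that matches its metal adopts one
conformation; a mismatched metal leaves the protein exchanging between
states. Three NMR observables, all derived from [¹⁵N,¹H]-HSQC-type data,
summarise this:

1. **Peak count.** One backbone-amide peak per non-proline residue is
   expected for a unique structure (~60–66 for the two-domain MTs this
   package targets). Millisecond ("intermediate") exchange broadens peaks
   beyond detection; much slower exchange duplicates them.
2. **Mean T₂.** Exchange adds to transverse relaxation, so short average T₂
   times over the visible peaks indicate exchange even when the peak count
   looks normal.
3. **Inhomogeneity S.** With the k = 60 most intense peaks, zero-padded
   when fewer are observed, intensities are normalised by their mean Ī and
   `S = mean(|I/Ī − 1|)`. Padding makes S sensitive to broadened-away
   peaks, which mean T₂ (computed over survivors only) cannot see.

A complex is **conform** when mean T₂ ≥ `t2_delim_ms` (default 140 ms) and
S ≤ `inhom_delim` (default 0.55). Both delimiters are approximate
boundaries, kept configurable and recorded in every report; the boundary is
inclusive so that values sitting exactly on a delimiter count as conform.

### Exchange-regime call

With expected peak count `E` and tolerance `tol` (default 0.15):
count < E(1−tol) → intermediate exchange; count > E(1+tol) → slow exchange;
otherwise stable. A *mixed* call (intermediate + slow together) is made
when weak peaks (below half the median intensity) exceed a quarter of the
spectrum **and** the strong-peak count falls below E(1−tol). The strong-peak
criterion, rather than the raw total, is used because duplicate weak peaks
can push the raw count back into the expected band while the strong set is
still depleted.

## T₂ fitting and its error

Each peak's series at the nine CPMG delays (20, 50, 75, 100, 125, 150,
200, 250, 300 ms) is fitted to `I(t) = I₀·exp(−t/T₂)` by nonlinear least
squares (scipy `curve_fit`), started from a log-linear regression of ln I
on t; no baseline offset is fitted. At least three usable points are
required; missing delays are dropped pairwise and never imputed.

The error model propagates the uncertainty of I₀ into T₂:

1. draw `n_resamples` (default 500) values of I₀ from Normal(I₀, SE(I₀));
2. refit the one-parameter model with each I₀ fixed, giving T₂ᵢ and SEᵢ;
3. perturb each T₂ᵢ once by Normal(T₂ᵢ, SEᵢ);
4. report the standard deviation (ddof = 1) of the perturbed values.

Step 3's standard error is ambiguous in principle (the refit's own SE or
the original two-parameter fit's); the default uses the refit SE and
`RunConfig.mc_se_source` switches to the alternative. Refit failures are
skipped and counted; more than 50 % failures aborts with an error. Fits
with Monte-Carlo errors **strictly larger** than 25 ms are excluded before
averaging; the filter reports each exclusion with its reason.

For noiseless input the procedure reports an error at machine precision
(~1e−14 ms, because a converged fit on exact data still leaves ~1e−13
residuals) rather than a clamped literal zero.

## Inhomogeneity details

Ties at the k-th intensity are broken by a stable sort on (intensity
descending, peak id ascending) so results are platform-independent.
Negative intensities (phase artifacts) are rejected rather than silently
absolute-valued. An empty spectrum pads to all zeros with a warning;
S itself is undefined (error) on an all-zero list. Analytic anchor: n equal
peaks padded to k give exactly S = 2(k−n)/k, which the tests sweep for all
n ≤ 60. Peak heights, not volumes, are assumed throughout.

## Lineage descriptors

Substitution counting is bookkeeping, not distance estimation: a column
counts on every branch where it changes, with no multiple-hit correction;
gap-versus-residue columns travel through a separate indel channel and
never enter substitution totals. Cumulative counts are path sums by
construction and equal direct root-versus-node counts whenever no column
changes twice along the path (the generator can enforce this for testing).

Sequence identity supports three denominator policies —
`alignment_columns` (default: columns in the region where at least one
sequence has a residue), `shorter_sequence`, `mean_length` — because
published similarity tools differ and the choice changes gapped values;
the policy is recorded in the output.

Bulkiness sums Zamyatnin residue volumes (Å³, the IMGT tabulation). The
K/N ratio counts Lys and Asn from the first Cys (inclusive, position 11 in
the canonical numbering) to the C-terminus; with zero Asn it is reported
as undefined rather than as a number, since ratios on one or two Asn are
already unstable. For cross-descriptor consistency the descriptor table
applies the same first-Cys exclusion to bulkiness by default, with a
switch for whole-sequence sums.

## Bundle RMSD

For every conformer pair (i from bundle A, j from bundle B) the selected
atoms (Cα, or Sγ of Cys residues, within an optional residue range) are
superimposed by the standard least-squares SVD rotation with reflections
disallowed, and the mean ± SD over all |A|×|B| pairwise RMSDs is reported.
Superposition is computed on the selection itself, so domain comparisons
are domain-wise superpositions. Mapping between non-identical proteins
must be supplied explicitly (e.g. from an alignment); nothing is aligned
structurally. Fewer than three mapped atoms is an error (the rotation is
under-determined).

## Synthetic data: what it emulates, and what not

* **Relaxation tables / spectra.** Per-peak intensities are log-normal
  (CV 0.25) around a base intensity, reflecting homogeneous-but-not-equal
  stable spectra; noise is additive Gaussian with SD = 2 % of each peak's
  I₀, the standard detector-noise assumption. True T₂ values are Gaussian
  per regime (stable 170 ± 25 ms, intermediate 90 ± 20 ms with survivors
  shortened ×0.8, slow 120 ± 30 ms, mixed 100 ± 25 ms). The intermediate
  regime removes a deterministic `round(missing_fraction · n)` peaks
  (default half); the slow regime appends `round(extra_weak_fraction · n)`
  duplicates at 25 % intensity. Defaults use 66 residues, matching the
  ~60 observable amides of a two-domain MT.
* **Lineage fixture.** `stylommatophora_lineage()` is a deterministic,
  hand-placed synthetic alignment (61 sequences, 66 columns, two 9-Cys
  domains, first Cys at column 11, a two-residue linker) whose per-branch
  edits encode the published substitution ledger of the snail MT lineage:
  11 substitutions into the Cu-lineage ancestor with 7 persisting in the
  extant Cu-specific isoform, 8 more with 4 persisting, N-domain counts of
  1 (Un-lineage), 5 (Cu-lineage) and 8 (Cd-lineage), a 23-substitution
  cumulative Cd-lineage total, and one single-residue deletion travelling
  through the indel channel. Companion and filler sequences are seeded
  random variants. The fixture shares the *bookkeeping structure* of the
  real supplementary alignment, not its residues: recovering these counts
  validates the counting machinery, not the biology.
* **Not emulated:** peak overlap, chemical-shift structure, field-strength
  effects, volume-versus-height differences, correlated noise, indel
  evolution beyond single columns, realistic coordinates (toy bundles are
  jittered random chains). Passing tests therefore certify the statistics
  and bookkeeping, not spectral processing or structure determination.

## Numerical choices and problem sizes

Monte-Carlo error uses 500 resamples, the protocol default. The replicate
benchmarks run 200 noisy series for the mean-T₂ check, 500 independent
series for the error-model comparison (reported error within a factor of
two of the empirical SD) and 300 spectra (100 per regime) for regime
recovery — sizes at which the checks are stable across seeds while the
whole acceptance run finishes in seconds. A single seeded generator drives
each run; derived seeds stay below 2³¹.

## Known limitations

Whole-protein verdicts only: attributing exchange to individual domains
requires resonance assignments, which are out of scope. The conformity
delimiters are calibrated to two-domain snail MTs at 600 MHz; other
systems will need their own `RunConfig`. The exchange-regime call assumes
reasonably complete peak picking — systematic under-picking mimics
intermediate exchange.
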