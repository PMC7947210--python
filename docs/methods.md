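# Methods

## Quantification model

Each dye channel of the multiplex assay is calibrated independently.
The genomic standard dilution series (10, 2, 0.4, 0.08, 0.016 ng per 1-µl
reaction, in duplicate) yields ordinary-least-squares fits of
`Ct = slope · log10(amount) + intercept` for the short-C and long-Cfree
channels; PCR efficiency is reported as `10^(−1/slope) − 1` and a
non-negative slope is rejected outright. Amounts are read back as
`10^((Ct − intercept)/slope)`; an undetermined Ct quantifies to zero and
carries a `NO_SIGNAL` flag rather than an error, because "no amplification"
is a measurement, not missing data.

The converted-allele (short-T) channel has no genomic calibrator: genomic
DNA contains no converted template. It is calibrated indirectly through a
synthetic indicator oligo with a degenerate Y base at the probe's
discrimination site, assumed to split 50 % C / 50 % T. Across the four
indicator dilutions (10⁶…10³ copies/µl) the C-channel Ct is regressed on
the T-channel Ct, giving the transform `Ct_C_equiv = α·Ct_T + β`. The
regression direction matters under noise and is fixed by use: the transform
consumes T-channel Cts. A transform R² below 0.99 flags every result of
the run `TRANSFORM_UNRELIABLE` (and fails the run under `--strict`); the
run is still evaluated so the operator can see how bad it is.

The 50/50 split assumption is exposed as `indicator_c_fraction` in the
simulator precisely because it is an assumption: synthesising a biased Y
shifts β by `slope · log10(f/(1−f))` and propagates directly into the
converted-allele quantities, which is the correct behaviour to exercise in
robustness tests, not something the pipeline should silently correct.

## Replicate handling

Wells are collapsed per (sample, channel) by arithmetic mean of the numeric
Cts. All-undetermined groups stay undetermined. A mixed group (one numeric,
one undetermined) keeps the numeric Ct with a `REPLICATE_DROPOUT` flag —
dropping it would silently discard exactly the low-input samples the assay
is most useful for. Numeric duplicates spanning more than 0.5 cycles get a
`REPLICATE_DISCORDANT` warning; the threshold is a conventional duplicate-
agreement rule, configurable in one place (`REPLICATE_DELTA_CT_WARN`).

## Metrics

For a converted sample and its source gDNA (pairing supplied in run
metadata; the pairing normalises individual copy-number variation of the
multicopy targets, making degradation level and recovery invariant under
scaling all of one individual's quantities):

- efficiency `= 100·T/(C+T)`, clamped to [0, 100] against 1-ulp overflow;
  undefined (NaN + flag) when the short channel is completely dark;
- degradation level `= [(C+T)/L]_bs / [C/L]_g`; a dark long channel gives
  +inf with an `INFINITE_DEGRADATION` flag — severe degradation is a
  finding, not missing data; a dark gDNA side is an invalid pair (error);
- recovery `= 100 · 2 · (C+T)_bs/C_g · V/10`, with V the elution volume in
  µl. The ×2 compensates single-strand amplifiability of converted DNA;
  the V/10 term rescales samples eluted in more than the 10-µl baseline.

The gDNA denominator uses its short-C quantity only: untreated template
yields no T-channel signal, so `C_g` *is* the gDNA short amount.

IPC QC flags a sample when its IPC Ct exceeds the run median by more than
2.0 cycles (default; the inhibition literature typically uses 1–3 cycles)
or when the IPC failed entirely. Kit summaries are arithmetic means per kit
(medians available), ranked with high-is-good for efficiency and recovery
and low-is-good for degradation, plus Pearson's r between qPCR recovery and
fluorometric (Qubit-style) recovery when the latter is supplied.

## Assay design

In-silico conversion applies the per-base rule: C→T except, under the
CpG-methylated model, a C immediately followed by G (an ambiguous N
neighbour does not protect). Scans are exhaustive window enumerations —
candidate discovery is cheap at amplicon scale and exhaustiveness is what
the brute-force oracle tests pin down. Forward primers must be C-free on
the top strand; reverse primers G-free on the top strand, because their
annealing footprint's convertible cytosines appear as the primer's G
complements. Discrimination probes carry exactly one C, in non-CpG context,
and are emitted as C/T sequence pairs. In-silico PCR is exact-match only
(the panel's primers are exact by design; mismatch models are out of
scope), returns all products (multicopy targets are the point of the
marker choice), and measures amplicons 5'-end of the forward primer through
5'-end of the reverse primer inclusive, the convention under which the
panel's printed sizes (104, 238, 147 bp) are reproduced. Tm estimates use
the Wallace rule up to 14 nt and a GC-fraction formula above — ranking
aids only. Coordinates are 0-based half-open throughout.

## Simulator

The generative model tracks amplifiable molecules per sample:

| parameter | default | meaning |
|---|---|---|
| `gdna_input_ng` | 50 | mass fed into conversion (ng) |
| `gdna_conc_ng_per_ul` | 5 | loading of paired gDNA wells |
| `locus_copies_per_ng` | 1000 | amplifiable copies of each target per ng |
| `copy_cv` | 0.2 | lognormal CV of per-individual copy number |
| `true_conversion_prob` | 0.99 | P(C→T) at the probe site per molecule |
| `breakage_prob_per_nt` | 0.003 | per-nucleotide fragmentation probability |
| `retention_prob` | 0.6 | per-molecule purification survival |
| `elution_volume` | 10 µl | eluate volume; 1 µl enters each well |
| `ct_noise_sd` | 0.15 | Gaussian Ct noise per well |
| `indicator_c_fraction` | 0.5 | C share of the indicator's Y base |
| `n_samples` / `n_replicates` | 20 / 2 | cohort size / duplicate wells |

An amplicon of length L survives fragmentation with probability
`(1−b)^(L−1)` (independent per-nt breakage; any break in the span kills
it), the simplest model producing size-dependent loss. Template copies per
well are Poisson (low-input stochastic effects are representable);
conversion is a per-molecule Bernoulli at the probe site; converted
molecules are single-stranded, so n copies read like n/2 double-stranded
standard copies on the calibration curves. Channel responses share a slope
(−3.3219, perfect doubling) with small probe-specific intercept offsets —
exactly the channel difference the C-T transform exists to absorb. Cts
beyond 40 cycles, or zero copies, report as Undetermined. Defaults sit
inside the ranges the assay is designed for (efficiency ≈ 94–99.9 %,
degradation 1–1.8, recovery 18–50 %) and put the 10-ng standard near Ct 21
in the short-C channel; `locus_copies_per_ng` is a free parameter since
absolute copy numbers of multicopy loci are assay-specific.

Closed forms (`expected_metrics`): efficiency `100·p`; degradation
`(1−b)^(short_len − long_len)`; recovery `100·retention·(1−b)^(short_len−1)`
— the elution correction cancels the per-µl dilution by construction and
the strand ×2 cancels the single-strand signal halving, so neither appears.

`stochastic_copies=False` replaces every molecule-count draw by its
expectation, giving the exact zero-noise limit: with `ct_noise_sd=0` the
pipeline then reproduces the closed forms to float precision, which pins
the algebra of the whole chain (curve → transform → metrics, including the
×2 and elution corrections) independently of Monte-Carlo tolerances.

What the simulator does *not* emulate: sequence-context conversion bias,
deamination kinetics, probe cross-hybridisation, inter-operator effects,
and real instruments' baseline/threshold processing (Cts are consumed, not
computed from fluorescence). Passing parameter-recovery tests therefore
show the *computational* chain is faithful and well-calibrated under the
stated noise model — not that any wet-lab kit behaves like the defaults.

## Statistics cascade

Per metric: Shapiro-Wilk per group and Levene (mean-centred, the classic
form) across groups at α = 0.05 gate the choice — any non-normal group →
Kruskal-Wallis with Bonferroni-corrected pairwise Mann-Whitney U tests;
all normal but heteroscedastic → Welch's ANOVA with Games-Howell; normal
and homoscedastic → one-way ANOVA with Tukey's HSD. The "any group fails"
normality rule is the conservative reading. The pairwise base test under
Kruskal-Wallis is Mann-Whitney U; Dunn's rank test is the common SPSS
alternative and would differ slightly. A constant group is treated as
maximally non-normal; identical groups make Levene 0/0, treated as equal
variances. Significance tiers <0.05 / <0.01 / <0.001 are reported alongside
adjusted p-values. Welch ANOVA and Games-Howell are delegated to pingouin;
everything else is scipy.

## Parameter-recovery validation design

Estimates from one plate share that plate's fitted calibrations, so the
20-sample study mean carries a run-level error component comparable to its
per-sample standard error (for degradation level they are nearly equal).
The recovery check therefore simulates six independent studies per
parameter-grid cell and compares the grand mean against the closed forms
with a tolerance of three times the run-to-run SD of a single study mean —
the Monte-Carlo standard error of the estimator a study actually computes.
Known limitation surfaced by this design: at ~1 C-allele copy per well
(conversion 0.999 with low retention) the keep-numeric duplicate rule
conditions on detection and inflates the C quantity, biasing efficiency
down by ≈0.04 percentage points — far below any decision threshold, but a
real small-sample property of the estimator at the Poisson limit.

## Numerical and degenerate-input choices

Standard-curve fits require ≥3 distinct amounts; transforms ≥2 dilutions
with both channels amplified (an undetermined indicator Ct is an error
naming the dilution — the calibrator must always amplify). Ct parsing
accepts "Undetermined" case-insensitively and rejects Cts outside
(0, max_cycles]. Plate round-trips are lossless: Cts and amounts are
serialised with `repr`, metadata rides in a `#meta` JSON header line.
IUPAC expansion is capped (default 4096) to keep degenerate inputs from
exploding. All randomness flows through `numpy.random.default_rng(seed)`;
fixed seeds reproduce plates bit-for-bit.
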