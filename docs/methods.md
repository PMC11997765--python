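# Methods

This note documents the models, conventions and numerical choices
behind `hfomark`, and what the synthetic-data tests do and do not
demonstrate about real intracranial EEG.

## Detection

**HFO detector.** Per channel and band (ripple 80–250 Hz, fast ripple
250–500 Hz), the trace is band-passed with a zero-phase FIR filter
(window design; transition width max(4 Hz, 0.15 × band low edge); the
symmetric kernel is applied once by FFT convolution, so event times
are not shifted) and the analytic-signal envelope is computed by
Hilbert transform. Envelope statistics are taken over the whole
analyzed segment (no epoching); a median/MAD option exists. A
candidate exists wherever the envelope exceeds
`mean + threshold_sd × SD` (default 5); its extent is delimited where
the envelope falls back to `mean + boundary_sd × SD` (default 2) —
the peak must clear the high threshold, but brief band-limited bursts
are mostly above threshold only at their center, so the supra-boundary
region defines onset/offset. Candidates closer than 10 ms merge.

Two acceptance rules follow:

- *duration floor*: `min_oscillations` cycles at the band's upper
  edge (16 ms for ripples, 8 ms for fast ripples) unless overridden;
- *oscillation count*: rectified-signal peaks above a quarter of the
  event's envelope maximum count half-waves (two per cycle), and the
  tally is capped by the number of cycles the event's duration can
  span at its spectral peak frequency. The cap is what makes a
  3-cycle burst unable to masquerade as four oscillations: whatever
  the peak counter says, a 3-cycle-long event cannot span 4 cycles.
  Events with fewer than 4 oscillations are discarded.

The exact thresholds of the detector this emulates are not published,
so all values here are this package's own defaults, chosen so that at
signal-to-background ratio 5 an 8-cycle burst is recovered with
sensitivity and precision above 0.9 while 60-s noise-only segments
(white or 1/f) essentially never yield an event. They are fully
configurable (`HfoDetectorParams`).

**Automated QC.** Visual review of HFO candidates is emulated by two
rules applied to the raw (unfiltered) segment around each event:
accept iff the event shows an isolated spectral peak strictly inside
the band whose power exceeds twice the band-edge power (the "island"
test) *or* carries at least four oscillations, and reject as Gibbs
ringing any event whose raw context contains a sharp transient
(first-difference z-score > 6 against median/MAD) with fewer than
four in-band oscillations. Rejection reasons are recorded
(`rejected_blob`, `rejected_gibbs`). QC is deterministic.

**Spike stand-in.** Spikes are detected on preprocessed data (common
average reference, DC removal, zero-phase 1–70 Hz band-pass, 60 Hz
notch; the notch uses a wide Q = 5 so a pure mains tone is attenuated
below 5 % including filter transients). The statistic is the Hilbert
envelope of a 10–60 Hz band-passed version of that trace — spike
transients concentrate energy there while 1/f background is already
weak — z-scored per channel against median/MAD; samples above z = 6
seed events merged within a 200 ms refractory period, with durations
bounded to 20–200 ms. The envelope (rather than the signed trace)
makes detection insensitive to the phase at which the sharp peak is
sampled. This detector is intentionally simple and is **not** a
substitute for clinical-grade spike detection; external annotations
can be imported through the event-table reader.

**Matching.** Detections are scored against reference annotations by
greedy one-to-one nearest-peak matching per channel (default
tolerance 100 ms for spikes, 50 ms for HFOs); sensitivity =
matches/|reference|, precision = matches/|detected|.

## Temporal categorization

Events on the same channel whose peak times differ by at most 50 ms
(closed interval) are co-occurring; chains merge by single linkage
(connected components — the only order-independent choice, since
transitive chains are otherwise ambiguous). Peak times, not interval
overlap, define proximity: peaks are the detectors' most stable
landmark. Per channel, `All_S`/`All_R`/`All_FR` count raw events;
the combination categories count clusters by exact type set; `S+HFO`
counts clusters containing a spike and at least one HFO. Both
per-cluster and per-event tallies are available
(`categorize_events`, `per_event_labels`) because either convention
can be reported. Rates are counts divided by recording minutes. The
identities `S+HFO = S+R + S+FR + S+R+FR` and `#clusters containing S
= S_only + S+R + S+FR + S+R+FR` hold exactly and are asserted in
tests.

## Localization scoring

Each contact is a unit scored by its rate for one category; contacts
inside the SOZ (or resection) are condition-positive; contacts with
no events participate with rate 0. A contact is predicted positive
when its rate strictly exceeds the threshold; thresholds sweep all
unique rates plus +∞. Sensitivity at a specificity level is read at
the achievable operating point with the smallest specificity at or
above the level (no interpolation — rate thresholds are discrete).
The restricted pAUC integrates sensitivity over false-positive rate
on [0, 0.15] along the empirical ROC staircase, linearly
interpolating only on the segment that straddles FPR = 0.15, and is
normalized by 0.15.

Two "chance" conventions exist for the normalized pAUC and they
disagree: half of the maximum (0.5 normalized, 0.075 raw) is the
convention used when reporting patient cohorts, while a literally
diagonal no-skill ROC sweeps only ∫₀^0.15 x dx = 0.01125 raw
(0.075 normalized). The package computes and exposes both
(`CHANCE_LEVEL_HALF_MAX`, `CHANCE_LEVEL_DIAGONAL`) and takes no side;
the half-max figure describes the midpoint of the attainable range,
not the expected value of a random classifier.

The per-contact confusion-matrix convention is the standard one
(TP = inside with rate above threshold, FP = outside above, etc.);
this leaves sensitivity, specificity and the ROC identical to a
description that swaps the FP/FN labels verbally.

## Outcome prediction

The resection ratio of a biomarker is the resected share of its total
rate; it is undefined (and the patient excluded, with the exclusion
count reported) when the patient has no event of that biomarker. The
SOZ ratio is the resected share of SOZ contacts. Positive class =
good outcome (Engel I, parsed case-insensitively; any class beginning
1/I is good); a positive prediction is a ratio strictly above the
threshold, so a ratio of exactly 0.5 predicts poor.

The Youden-point analysis fits the threshold maximizing
sensitivity + specificity − 1 (ties resolve to the largest, most
specific threshold) and reports the full metric suite. Leave-one-out
cross-validation refits the optimal point on each n−1 subset and
summarizes per-fold metrics as median (IQR); this characterizes the
stability of the operating point rather than held-out prediction of
the dropped patient, and is documented as such. The
pseudo-prospective analysis instead fixes the cut-off at 0.5 with no
fitting anywhere. Subgroup rules: `frequent_spikes` keeps patients
whose median channel spike rate exceeds the cohort median (recomputed
by default, configurable); `no_fr_rare_spikes` keeps patients with no
fast ripples at all and a median spike rate below the cut.

## Statistical primitives

Wilcoxon signed-rank (paired, per-patient inside vs outside medians),
rank-sum, Kruskal–Wallis and Spearman delegate to scipy; identical
samples short-circuit to p = 1 (zero effect) rather than relying on
degenerate asymptotics. The Tukey–Kramer post hoc on Kruskal–Wallis
compares rank means with the studentized-range distribution at
infinite degrees of freedom, with tie-corrected rank variance
N(N+1)/12. Barnard's exact unconditional 2×2 test is implemented
directly in the pooled-z ordering: the p-value is the maximum over a
nuisance grid (step 0.001) of the probability of tables whose |z|
reaches the observed; it is symmetric under row and column swaps by
construction. The two-proportion z-test uses the pooled variance.

## Synthetic data: what it emulates and what it does not

**Background** is per-channel independent 1/f^α noise (α = 1 default,
target RMS 25 µV) generated by spectral shaping; it reproduces the
broadband spectral slope of interictal iEEG but none of its
nonstationarity, sleep architecture, mains harmonics or shared-reference
correlation structure.

**Events.** Ripples/fast ripples are Hann-windowed sinusoids
(n cycles/f0 long, default 8 cycles, f0 uniform in 100–200 Hz and
270–420 Hz); spikes are ~60 ms biphasic transients built from two
opposed Gaussian lobes with >99 % of energy below 70 Hz. Peak
amplitudes are `snr` times the channel's realized background
amplitude — the mean analytic envelope of the band-passed
background — in the event's own band (1–70 Hz for spikes); default
snr = 5. No published amplitude statistics were available for the
events this emulates, so the SNR scale is the package's own.

**Event processes.** Per channel, spikes, ripples and fast ripples
arrive as independent Poisson processes (defaults 1.3, 0.9 and
0.1 events/min — cohort-scale figures for this kind of recording).
Co-occurrence is *planned at generation time*: each spike gains a
ripple companion with probability 0.11 and a fast-ripple companion
with 0.02; each process-ripple gains a fast-ripple companion with
0.05 (fractions matching the reported proportions of spikes on
ripples etc.). Companions are jittered uniformly within ±50 ms of
their anchor, and anchors on a channel are at least 300 ms apart with
a 100 ms edge margin — which guarantees the ±50 ms single-linkage
clustering recovers the planned clusters exactly, giving exact
ground-truth category counts. Real co-occurrence is emergent, not
planned; the generator trades that realism for exact ground truth.

**Epileptogenic structure.** The first `n_resected` channels form the
epileptogenic set (SOZ = its first `n_soz` channels, so SOZ ⊆
resection in the good-outcome geometry). All event rates there are
multiplied by `inside_multiplier` (default 2 — the doubling observed
inside SOZ/RA in good-outcome cohorts), and the spike-ripple
co-occurrence probability is additionally multiplied by
`cooccur_boost` (default 4). The boost is needed because a rate
doubling alone cannot push the S+R resection ratio above 0.5 when
only ~1/5 of channels are resected; it concentrates spike-on-ripple
events in epileptogenic tissue, at the cost of slightly
over-doubling All R inside (≈2.8× rather than 2×). All S and All FR
remain doubled.

**Outcome model.** Designed-good patients resect the whole
epileptogenic set (realized ground-truth S+R resection ratio > 0.5,
verified and redrawn if Poisson noise violates it); designed-poor
patients resect only a third of it plus unremarkable channels
(ratio < 0.5). Labels then flip independently with `label_noise`
(default 0.1). Defaults: 40 patients, 26 good, 32 channels, 10 min
per recording — cohort-scale sizes; recordings are kept to minutes
and channels to 32 so whole-cohort analyses run in seconds. A null
mode (`outcome_rule_biomarker=None`, multiplier and boost 1) removes
all structure for type-I-error checks.

**What passing tests show.** Detector recovery, category algebra,
localization and outcome-model results on this generator demonstrate
internal correctness — each stage recovers what was planted, at the
planted effect sizes — not clinical performance: real spikes and HFOs
vary in morphology, overlap with artifacts, and co-occur with
structure no Poisson model captures, and the stand-in spike detector
has not been validated against expert markings.

## Numerical and degenerate-input conventions

Times are seconds from recording start; event intervals are
half-open [onset, offset). Single-class label vectors raise a
degenerate-labels error rather than returning NaN curves; LOO folds
that become single-class are skipped and counted. Undefined
predictors (no events) are excluded, never imputed. Ratios are exact
fractions of sums, so they are invariant under rescaling all rates.
EDF output quantizes to 16 bits over each channel's physical range;
the round-trip error is below two quantization steps. All generators
are deterministic given their seed (`numpy.random.default_rng`).

## Known limitations

- The spike stand-in is a convenience for synthetic data and
  pipeline plumbing, not a clinical detector.
- Cross-channel co-occurrence and propagation are out of scope;
  clustering is per channel only.
- The Barnard implementation enumerates achievable tables and is
  intended for cohort-scale 2×2 tables (n ≲ a few hundred), not
  large contingency problems.
- The generator's good/poor geometries are stylized (nested vs
  partial resection of one contiguous channel block); real resections
  are spatially structured in ways channel indices do not capture.
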