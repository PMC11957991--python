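# Methods

This note documents the models, conventions and numerical choices behind
`atriakit`, in the order data flows through the package.

## Synthetic electrogram generator

The generator exists so that every analysis stage can be validated against
known ground truth.  It is a phenomenological signal model, not a
biophysical one: waveforms are analytic bumps placed at event times, and
the SA/AV node is a rule-based response model.

**Waveforms.** P and T waves are Gaussians; the QRS, the atrial bipolar
deflection and the ventricular far-field are Gaussian first derivatives
(biphasic wavelets).  A "width" parameter spans ±2σ.  Defaults emulate an
adult male rat four weeks after electrode implantation: sinus cycle length
182.2 ms with 1-ms beat-to-beat jitter, PR interval 50 ms, 1-mV atrial
deflections of 4-ms width at 2 kHz.  The T wave peaks 30 ms after the R
peak — rats have no isoelectric ST segment — which also keeps the entire
ventricular far-field inside the −40/+60 ms cancellation template span.

**Ventricular far-field.** The atrial channel receives a broader (22-ms)
biphasic ventricular wavelet plus a scaled T bump at 35% of the atrial
deflection amplitude, with ±10% per-beat uniform gain jitter on by
default so that template subtraction is exercised beyond the trivial
exact case.

**Noise model.** Additive Gaussian noise (0.03 mV) low-passed at 200 Hz,
plus a 0.05-mV respiratory baseline wander at 1.5 Hz on the atrial
channel.  These two numbers matter for the complexity ratio: with a
median-split symbolization, baseline samples near the window median
binarize stochastically, so the stationary noise fixes the "complexity
floor" shared by pre- and post-burst windows.  A floor that is too low
makes the CR scale with activation count (penalizing fast but regular
rhythms); one that is too high saturates the symbol stream and erases all
contrast.  The defaults sit in the regime where a regular 70-ms SVT stays
near CR ≈ 1.1 while fractionated AF rises well above the 1.236 cutoff,
and where the single pre-burst reference window is stable (LZ76 ≈ 70 ± 4
across seeds).  These values were fixed while designing the generator and
were not revisited afterwards.

**AF episodes.** Activation times follow a Gamma renewal process
(default mean 45 ms, CV 0.25) with intervals below 15 ms rejected as
physiologically impossible, giving a dominant frequency of
≈ 1000/mean interval.  Crucially, the AF electrogram is *fractionated*,
as real fibrillation electrograms are: per-activation amplitude
(lognormal, CV 0.30) and width (uniform 0.7–1.6×) variability, double
potentials with probability 0.35 at 3–6 ms offset and half amplitude, and
continuous low-amplitude f-wave activity (0.12 mV, 40–250 Hz) between
activations.  Without fractionation the LZ76 of an AF window is barely
distinguishable from that of a fast regular rhythm, because a spike train
contributes symbol novelty roughly per activation regardless of timing
irregularity; the continuous irregular activity is what raises the
entropy rate of genuine AF.  Regular SVT episodes use fixed morphology
with interval CV 1% (default cycle length 70 ms).

**Ventricular response during arrhythmia.** Ventricular beats continue
through burst and episode at an irregular conducted rate (0.8–1.25× the
sinus cycle), so the far-field cancellation stage has work to do inside
the analysis windows.  This is a simplification — no explicit AV
filtering model links atrial to ventricular times during AF.

**Node model.** Atrial capture requires the coupling interval to *exceed*
the atrial ERP (the interval equal to the ERP fails, matching the
"longest failing coupling" reporting convention, so configured values are
recovered exactly on any sweep grid that contains them).  The atrial ERP
is flat across basic cycle lengths, as observed in rat atria.  Premature
(S2) AV conduction fails at couplings at or below `av_erp_base`.
Sustained constant-CL pacing engages a decremental recurrence on the
AV recovery interval R (time from atrial activation to the last
ventricular activation): conduction delay is `d0` for R ≥ θ, grows by
`g·(θ − R)` below θ, and blocks below an effective recovery floor.  θ and
the floor are derived internally from the configured Wenckebach and 2:1
cycle lengths (offset +1 ms, baseline delay d0 = 20 ms), which makes a
descending sweep produce first Wenckebach periodicity (at and below the
configured Wenckebach CL) and then strict 2:1 alternation (at and below
the configured 2:1 CL), exactly, for sweep steps of 2 ms or more.  After
at least 10 s of uninterrupted overdrive the first spontaneous cycle is
prolonged by `snrt_suppression` (0.5-ms jitter on spontaneous cycles).

**Cohort generator.** Study-level data are generated at the parameter
level: per-animal random effects (SD matched to the published group SEMs,
n = 13 males / 16 females) shared across the three within-animal
conditions, additive condition shifts per sex following the reported
directions (pentobarbital slows the sinus rate in both sexes, isoflurane
prolongs CSNRT and suppresses the AF substrate in males only, both
anesthetics prolong refractory periods), binomial AF induction over 20
bursts and lognormal (right-skewed) episode durations.  Where the source
tables print no number for a shift, the default is a plausible magnitude
chosen once; these defaults define the simulated study conditions.

**Determinism.** All randomness flows from the single `seed` through one
`numpy.random.Generator` per call; identical parameters give bit-identical
arrays.

## Conditioning and beat detection

The acquisition chain is reproduced with zero-phase (forward–backward)
second-order Butterworth filters — 1–1,000 Hz band-pass (the upper edge
clipped to Nyquist at 2 kHz, with a warning) and a Q = 30 notch at 50 Hz.
Zero-phase filtering keeps channels latency-free, which the template
alignment downstream relies on.

QRS detection is Pan–Tompkins-style: 10–100 Hz band-pass, derivative,
squaring, 30-ms moving integration, then a scale-free threshold at 25% of
a robust feature amplitude (median of the strongest candidate peaks) with
a 50-ms refractory period, followed by refinement to the largest absolute
band-passed excursion within ±20 ms.  Detection counts are invariant to
uniform amplitude scaling.  P-wave onsets are the first supra-threshold
deflection in a 10–60 ms pre-R window; the threshold derives from the
early 70% of that window so a QRS upstroke leaking past the window tail
(detector jitter) cannot mask the much smaller P wave.  RR and PR are
means over five consecutive cycles, reported in milliseconds.

## Far-field cancellation

The template is the pointwise mean of −40/+60 ms windows around pre-burst
R peaks (≥3 usable beats; windows overlapping stimulus pulses or other
excluded events are skipped), baseline-anchored and tapered with 5-ms
cosine ramps.  At subtraction each beat is re-aligned by integer-shift
cross-correlation within ±5 ms and (by default) scaled by its
least-squares gain; overlaps resolve by sequential subtraction in time
order, and samples outside all windows are untouched.  Per-beat scaling
can never increase the within-window residual energy relative to unit
gain (least-squares optimality).  Sub-sample timing blur bounds the
achievable residual at roughly 3% of the far-field RMS on generated
signals; sample-aligned mixtures cancel to well under 1%.

## Complexity ratio

Each 1-s window is binarized by a strict median split (`sample > median`,
ties to 0; amplitude- and offset-invariant; constant windows are flagged
low-variance) and its LZ76 production count computed with Kaspar–Schuster
pointer counting, verified exhaustively against a naive parsing oracle on
all binary strings up to length 12.  The reference is the single 1-s
cleaned window ending at burst onset (configurable to the mean of the
last k pre-burst windows); post-burst windows are consecutive and
non-overlapping from the burst offset, final partial window dropped.  The
arrhythmic cutoff defaults to 1.236 — a calibration constant of the
recording system the statistic was developed on, kept configurable —
and session summaries follow the study conventions (mean CR of the first
five windows per burst; percentage of all windows above the cutoff).

## Dominant frequency

A raw FFT of a train of sharp biphasic deflections peaks at waveform
harmonics, not at the activation rate (the wavelet's power grows with
frequency).  DF analysis therefore uses the standard activation-envelope
preprocessing: band-pass 40–350 Hz (the deflection energy band), rectify,
low-pass at 45 Hz — the top of the DF search band, scaled up from the
classic human settings to rat activation rates.  Spectra are
Hann-tapered, zero-padded fourfold (0.25-Hz peak localization on 1-s
windows) and normalized as one-sided PSDs whose integral matches the
time-domain variance.  The DF is the argmax over 3–45 Hz minus the
48–52 Hz notch-artifact band, ties toward the lower frequency.  Raw
(non-envelope) spectra remain available and are the right choice for
narrowband signals such as calibration sinusoids.

## Episode rules

Activation detection uses peaks of the absolute cleaned signal above 35%
of a robust amplitude reference, floored above five noise MADs, with a
15-ms refractory.  The episode runs from the burst offset until the first
activation opening three consecutive intervals within ±20% of the
pre-burst sinus cycle length (estimated from the detected pre-burst
beats).  Two refinements guard the interval statistics: the terminal
transition interval (last tachycardic beat to first sinus beat) belongs
to neither rhythm and is excluded, and the stability CV is computed on
intervals within 50% of the median so isolated detection dropouts or
double counts cannot masquerade as irregularity.  Classification then
follows the interval rules (AF: median < 55 ms, or CV > 5% with median
< 60 ms; regular SVT: CV ≤ 5% and median > 60 ms; stable 55–60 ms
rhythms: indeterminate, never silently merged).  Inter-burst scheduling
implements the protocol rules: minimum 60-s wait, wait equal to the
episode duration after events longer than 60 s, abort action past 240 s.

## Programmed-stimulation interpretation

ERPs are reported as the longest failing coupling interval (failure =
loss of atrial capture for the atrial ERP; capture without ventricular
conduction for the AV ERP); non-monotone sweeps raise an error rather
than guessing, sweeps without failure report "below range", and the
three-fold confirmation returns the common value or a flagged median.
CSNRT subtracts the spontaneous cycle length (mean of three consecutive
spontaneous cycles, excluding the suppressed recovery cycle itself) from
the SNRT, averaged over the three overdrive runs.  The Wenckebach CL is
the longest pacing CL with at least one dropped beat in an otherwise
conducting train; the 2:1 CL the longest with strict conduct/drop
alternation over at least six stimuli.  Capture detection blanks the full
4-ms biphasic stimulus artifact plus 1 ms of filter ringing before
searching the post-stimulus window — a 2-ms blanking cannot work when the
pulse itself lasts 4 ms.

## Statistical battery

Two-sided α = 0.05 throughout.  The Shapiro–Wilk gate applies per
parameter across all groups: failure in any group routes the comparison
to the nonparametric path, and constant samples fail with an explicit
degenerate flag.  The parametric three-condition path is one-way
repeated-measures ANOVA (statsmodels `AnovaRM`, no sphericity correction)
with a Tukey post-hoc computed from the RM error mean square via the
studentized-range distribution; the nonparametric path is Friedman's test
with Dunn's within-block rank-sum post-hoc under a Bonferroni-type family
correction (the correction flavor is recorded in the report, since
"Dunn's correction" is not a single convention).  Sex comparisons use
pooled-variance Student's t (Welch optional) or Mann–Whitney; AF
dominant-frequency groups use Kruskal–Wallis with the independent-sample
Dunn test (tie-corrected).  The summary-statistics t-test reconstructs
SDs as SEM·√n and agrees with a raw-data t-test to machine precision when
fed a sample's own summary statistics.  Degenerate inputs (identical
conditions, all-tied groups) report p = 1 with a note instead of NaN.
At the study's group sizes (13/16, three conditions) all four gated paths
have empirical type-I error within 5% ± 1.5% under null simulations.

## What the generator does and does not show

Passing tests demonstrate that the analysis chain is internally correct:
it recovers what the generator put in (beat times, episode classes,
activation rates, refractory periods, block cycle lengths, suppression
constants) and that the statistics are calibrated.  They do not
demonstrate performance on real electrograms — the generator's waveforms
are stylized, its noise is stationary and Gaussian, electrode motion,
ectopy, signal dropout and true AV coupling during AF are absent, and the
fractionation model is parametric rather than fitted to recorded AF (no
public recordings accompany the source study).  The 1.236 CR cutoff in
particular was calibrated on the original recording system; on other
hardware it should be recalibrated rather than assumed.

## Problem sizes

Default test and acceptance runs use 200 burst trials (3–8 s episodes)
for classification fidelity, 100 seeds for dominant-frequency and SNRT
recovery, 1000 null replicates and 500 effect replicates for the
statistical calibration — sizes at which the Monte-Carlo standard errors
are several times smaller than the margins being checked.
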