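# Methods

## Scope

`microecg` analyzes extracellular field potentials (FPs) recorded from
spontaneously beating 3-D cardiac microtissues and turns them into the
quantities a cardiotoxicity screen needs: per-beat beating period (BP),
field-potential duration (FPD), its Fridericia-corrected form (FPDcF) and
spike amplitude (AMP); residual-based arrhythmic-event and cessation flags;
baseline quality control; dose-response threshold calls; FDA-label
concordance metrics; and a torsades-de-pointes (TdP) risk map. A
phenomenological FP simulator with ground-truth annotations makes every
stage testable without laboratory data. Cell culture, microfabrication,
amplifier hardware and any biophysical (ionic-current) modelling are out of
scope; amplifier gain and analog band are carried only as recording
metadata.

## Signal model and analysis procedure

A recording is one or two voltage channels (µV) sampled at 2000 Hz. Each
beat is assumed to consist of a sharp biphasic depolarization spike
followed, FPD later, by a slower unimodal repolarization wave; everything
else is noise (white noise, baseline wander, powerline interference) or
irregular activity. The analysis has three phases.

**Phase 1 — beat detection.** A Pan-Tompkins-style chain: first difference,
squaring, moving-window integration (80 ms), then an amplitude threshold at
a configurable fraction (default 0.70) of the *highest* integrated-energy
value, with a refractory period (default 250 ms) enforced height-first.
Accepted peaks are snapped to the extremum of the raw trace in a ±80 ms
neighbourhood, so beat times refer to the unsquared spike extremum. The
"fraction of the highest value" reading (rather than a causal running
maximum) keeps the detector equivalent to a plain absolute-threshold scan,
which the test suite exploits as a brute-force oracle.

**Phase 2 — template averaging.** Per-beat depolarization windows (default
0.5 s starting 75 ms before the peak) and repolarization windows (default
0.7 s starting 100 ms after the peak) are averaged into templates and
iteratively re-aligned to the trace by cross-correlation, independently for
the two windows, until the largest offset change is ≤ 1 sample or 10
iterations. The correlation search range (default ±50 ms) shrinks with the
free gap between beats (see `AnalysisConfig.for_geometry`) so the search
cannot lock onto a neighbouring depolarization. Beats whose windows leave
the signal bounds are dropped from the average and flagged, not raised.
An optional zero-phase notch (50 Hz and all harmonics below Nyquist,
cascaded biquads, Q = 30) and an optional zero-phase Butterworth band-pass
(0.67–100 Hz, order 3) run before this phase.

**Phase 3 — fiducials and parameters.** On the baseline-removed (median)
depolarization template: peak = global extremum; onset = last crossing of
10 % of the peak amplitude before it. On the repolarization template: the
fiducial is the extremum of the largest-|amplitude| lobe after median
removal, because repolarization polarity varies between tissues. FPD is
measured onset→repolarization-extremum by default; a peak-to-peak mode
(spike extremum→repolarization extremum) is available because the endpoint
convention is not standardized, and the mode used is recorded in every
summary. Per-beat values map the template fiducials through each beat's
alignment offsets; BP is the interval to the next depolarization; AMP is
the raw peak-to-peak excursion in the depolarization window. Summaries are
mean ± sample SD (n−1 throughout).

**Reconstruction, SNR, irregular events.** The signal is reconstructed by
placing the two templates at every beat's aligned positions. Within one
beat the depolarization template is cropped where the repolarization
placement begins — the two windows overlap by design, and summing them
there would double-count the signal; placements of *different* beats that
overlap are summed and flagged. SNR = 10·log₁₀(reconstruction power /
residual power); this reconstruction-based definition is an implementation
choice. Irregular (arrhythmia-candidate) events are residual excursions
beyond k = 5 robust SDs (1.4826 × MAD), at least one refractory period away
from each other *and* from the annotated beat windows; the extra guard
matters because reconstruction edges sit exactly at window borders. k = 5
was calibrated so clean simulated recordings produce < 1 false event per
minute (measured ≈ 0.05/min over 20 × 60 s). Cessation is flagged below 6
detected beats/min. Arrhythmia subtypes are not classified.

**Channel selection.** With two electrodes, the "cleaner" channel is the
one whose template reconstruction attains the highest SNR, with ties broken
by channel order; this operationalizes an otherwise qualitative criterion.
Signals the automatic analysis cannot handle can be re-analyzed from a
manual annotation sidecar (peak times), which replaces phase 1 only.

## Quality control and statistics

Tissues whose baseline per-beat BP has a coefficient of variation above
25 % are excluded (boundary inclusive: exactly 25 % passes, since only
"greater than 25 %" is discarded). Dose groups are compared with the
Kruskal–Wallis omnibus test (scipy) followed by Dunn's pairwise z-tests on
mean ranks with tie correction; the adjustment is the classical
Bonferroni-style one and is recorded in the output. Dunn's test is
implemented here directly (no post-hoc package is used) and is checked in
the tests against a frozen hand computation.

## Dose-response and classification

FPD is rate-corrected as FPDcF = FPD / BP^(1/3) (BP in seconds). Percent
changes are taken against each tissue's own baseline and aggregated across
replicate tissues as mean ± SEM. A compound crosses threshold T at the
lowest dose whose aggregated mean |%ΔFPDcF| ≥ T; prolongation and
shortening share the same absolute cut-offs (LOW 10 %, MID 15 %, HIGH 20 %,
with INF 5 % and SUP 50 % closing the ROC sweep). Calls use the aggregated
mean, matching how replicate data are reported; per-tissue calls can be
derived from the per-tissue analyses if needed. Sequential dosing and
washout are protocol metadata only — no pharmacokinetics is modelled, and
concentrations are stored in µM with explicit unit tags at the manifest
boundary.

Concordance against FDA-label ground truth uses two endpoints: QT
prolongation (positive = upward MID crossing) and TdP/arrhythmia (positive
= any irregular-event detection along the ladder). The vehicle (DMSO)
counts in the negative class, giving the 12-entry accounting that yields
accuracy 11/12. Sensitivity, specificity and accuracy are kept as raw
fractions in machine output and formatted to one decimal for display.

The packaged reference panel (`microecg/data/reference_panel.csv`) encodes
the published screen outcomes for the 11-compound CiPA-style panel plus
vehicle. Known discrepancies in the published record are resolved in favour
of the results table: alfuzosin is encoded as arrhythmia-negative (the
accompanying prose treats it as a false positive, which would give a
different TdP triple, and a second prose variant quotes 80/75/78); the
table's calls are reported mechanically even where prose differs
(cisapride's shortening, aspirin's LOW-threshold bump, nifedipine's
cessation). Several printed concentration/C_max ratios are mutually
inconsistent (quinidine LOW, ranolazine); the panel stores the C_max that
reproduces the self-consistent majority of ratios, and f_ETPC values come
from the CiPA MEA literature since the original concentration table is not
machine-readable.

## TdP risk scoring

Score: 3 = arrhythmic events; 2 = prolongation beyond HIGH; 1 =
prolongation between MID and HIGH; 0 = no effect above MID; −1 =
*shortening* beyond MID (reading "−1" as shortening keeps −1 and 0
disjoint and matches the placement of the calcium blockers in the low-risk
region). Margin = concentration eliciting the scored response / f_ETPC; a
score-3 compound uses its lowest arrhythmic dose by default (configurable
to the FPD-effective dose); a score-0 compound uses the maximum tested
concentration. Categories: high = score ≥ 2 at margin ≤ 10; intermediate =
score 1 at margin in (1, 100] or score ≥ 2 at margin in (10, 100]; low =
score ≤ 0, or score ≥ 1 at margin > 100; uncategorizable = score 1 at
margin ≤ 1. "Score > 2" in the intermediate band is read as "score ≥ 2" so
that score 2 at margin 50 is not unmapped; region boundaries are inclusive
on the riskier side (margin exactly 10 → high, exactly 100 → intermediate).
The map plots score against log-scaled margin with the three shaded
regions.

## The simulator

`simulate_recording` renders: beat times with Gaussian BP jitter (truncated
at a 0.3 s floor); per-beat FPD jitter drawn independently of BP jitter so
the two estimators are separably testable; a depolarization spike built
from two Gaussian lobes (dominant lobe σ = 4 ms, a smaller leading lobe of
opposite sign) normalized to the requested peak-to-peak amplitude, with the
annotated beat time exactly on the dominant extremum; a Gaussian
repolarization bump (σ = 50 ms) centred FPD after the spike at a
configurable amplitude fraction and polarity; white noise scaled to a
requested SNR against the noise-free render; optional sinusoidal baseline
wander and 50 Hz interference; ectopic spikes (default 60 % of beat
amplitude — large enough to detect in the residual, small enough not to
capture the beat detector's threshold) placed uniformly at random but clear
of the normal beats' analysis windows; and optional cessation after a set
time. The ground truth records beat times, per-beat FPD in both endpoint
conventions (the onset offset is computed from the rendered spike with the
same 10 % rule the analysis uses), amplitudes and ectopic times. Seeding
uses spawned substreams so that re-rolling only the noise leaves beat
times, FPDs and ectopic times untouched.

Defaults mirror a typical included baseline tissue: BP 1.9 s (CV 5 %), FPD
0.69 s, AMP 250 µV, SNR 25 dB, 2000 Hz, 60 s.

`simulate_drug_experiment` layers a Hill effect on top: FPD (and optionally
BP) scale by 1 + (Emax/100)·dᵸ/(dᵸ+EC50ᵸ); arrhythmia (as ectopic
activity) and cessation switch on above configurable dose thresholds in a
configurable fraction of tissues. The analytic %ΔFPDcF curve and its
threshold-crossing dose are available in closed form for end-to-end
recovery tests.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: drifting beat morphology within a recording,
electrode motion artifacts, the amplitude attenuation and SNR loss real
tissues show at toxic doses, non-Gaussian noise bursts, and genuine
arrhythmia morphologies (ectopics are clean extra spikes). Recovery-error
bands met on simulated data therefore bound the algorithmic error, not the
biological measurement error.

## Numerical choices

* Zero-phase filtering runs `sosfiltfilt` with an odd (anti-symmetric)
  signal extension and a 2 s pad. Narrow-band sections ring for ~0.2 s, and
  a mirror (reflect) extension places a derivative cusp exactly at the
  signal boundary that the notch rings on; the odd extension continues
  oscillatory content smoothly and keeps powerline attenuation ≥ 30 dB
  including edges.
* Sample SD (ddof = 1) everywhere, including the CV.
* Threshold comparisons are ≥ (a dose exactly at 15 % crosses MID).
* Degenerate inputs: flat templates raise a "degenerate pattern" error;
  zero-beat traces return an empty beat table plus a cessation flag rather
  than raising; all-tied group comparisons report H = 0 with a warning.
* Tissues missing a baseline are excluded from aggregation with a log
  entry; a tissue that ceased at a dose contributes to the cessation
  fraction but not to that dose's FPDcF mean.

## Problem sizes used in the checks

The parameter-recovery grid runs BP ∈ {0.8, 1.9, 3.0} s × FPD ∈ {0.3,
0.56, 0.9} s (the 8 geometrically feasible combinations — FPD 0.9 s does
not fit into BP 0.8 s) × SNR ∈ {15, 25, 40} dB × 10 seeds on 30 s
recordings; measured median errors are ≈ 0.001 % (BP), ≈ 0.2 % (FPD) and
≈ 0.3 % (AMP) at SNR ≥ 25 dB, comfortably inside the 2 / 5 / 12 % bands
the package promises. Arrhythmia calibration uses 10 ectopic-injected and
20 clean 60 s recordings; the synthetic screen uses 3 tissues × 5 doses ×
30 s. `scripts/acceptance.py` re-runs all of these from scratch.

## Known limitations

* FPD endpoint conventions differ across instruments; compare FPDcF values
  only within one mode (the mode is stamped in every summary).
* The detector's single global threshold assumes roughly stationary spike
  amplitude; strongly decaying amplitude within one recording can shed
  beats (real screens re-record or fall back to manual annotation, which
  the sidecar mechanism supports).
* Dunn's test uses the normal approximation; with very small replicate
  counts (n = 2–3 per dose) its p-values are approximate.
* Risk-map placement depends on externally supplied C_max/f_ETPC values;
  the package does not derive them from pharmacokinetic data.
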