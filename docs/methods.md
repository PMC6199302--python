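# Methods

`nervechip` models an ex vivo "nerve-on-a-chip" measurement: a teased nerve
rootlet threaded through an insulating PDMS microchannel (100 × 100 µm²
cross-section, 4–10 mm long) carrying up to eight platinum electrodes at
0.67–1.33 mm pitch. Electrical stimulation in a second, upstream
microchannel elicits single-fibre (SFAP), multi-unit (MUAP) or compound
action potentials that propagate through the recording channel at 1–60 m/s.
The package provides (i) a synthetic-recording generator with the
statistical structure such recordings have, (ii) the acquisition-side
processing chain, (iii) velocity selective recording (VSR) by delay-and-sum
with its success-rate (SR) statistic and response-surface model, and (iv)
the normalized-signal-density (NSD) analysis of opto-thermal
neuroinhibition by a photothermal polymer film.

## Synthetic recordings

**Spike template.** The extracellular spike is a Ricker wave (negative
second derivative of a Gaussian): triphasic, zero-mean, with a closed-form
relation between the Gaussian scale σ and the full width at half amplitude,
`FWHM = 2 x½ σ` with `x½ ≈ 0.6267` solving `(1 − x²) e^(−x²/2) = ½`.
Templates are parameterised directly by (width at half amplitude [ms],
baseline-to-peak amplitude [µV]). A template request is rejected when
`fs < 10 / width` (fewer than ten samples per main lobe makes width
metrology meaningless).

**Along-channel amplification.** Sealing the extracellular space amplifies
the recorded potential; the gain grows from zero at the channel entrance,
peaks at two-thirds of the channel length and falls off asymmetrically
toward the exit. The default phenomenological profile is
`g(u) ∝ u (1 − u)^q` with `q = ½` (peak at `u = 1/(1+q) = 2/3`, normalised
to 1 there), replaceable by a measured lookup table. A separate length
scale — linear in channel length by default, also table-replaceable —
makes longer channels record larger signals. No cable-theoretic modelling
is attempted; the profile is an empirical stand-in.

**Session assembly.** Per stimulus pulse, each electrode at position `z_e`
receives: a stimulation artifact at the pulse time (identical and
simultaneous on all electrodes; decaying exponential, sign set by the pulse
polarity), one onset artifact per fibre when it crosses the channel
entrance (simultaneous; narrow template, default 30 µV / 0.1 ms), and each
fibre's template delayed by `(d_stim + z_e)/v` and scaled by
`g(z_e/L) · scale(L)`. The stimulation-cathode-to-channel-entrance distance
defaults to 10 mm (the stimulation channel and gap are several mm; the
exact value is not printed anywhere and is config-exposed). White Gaussian
noise is calibrated so the best-electrode SNR —
`20 log₁₀(peak biological amplitude / noise RMS)`, the package-wide SNR
definition, with noise RMS measured in a signal-free pre-stimulus window —
equals the requested level. All randomness derives from one seed via
spawned per-pulse substreams, so identical (arguments, seed) give identical
traces.

## Processing chain

Band-pass: order-1 Butterworth, 100 Hz – 3 kHz, applied forward–backward
(`filtfilt`). Zero-phase filtering is a deliberate deviation from the
causal bench amplifier: velocity estimates must not inherit the filter's
group delay. Up-sampling: cubic spline from the 50 kHz acquisition rate to
the 500 kHz analysis rate (integer ratios only; input samples are
reproduced exactly). Spike detection thresholds the rectified trace at
`k = 4` robust noise sigmas (1.4826 × MAD of the pre-stimulus window),
merging side-lobe peaks within 0.5 ms of a dominant peak. Amplitude is
measured from the pre-stimulus baseline median; width is the full width at
half amplitude of the dominant rectified lobe (a half-prominence variant is
available; the two differ for wave shapes whose lobes ride on an offset,
and half-amplitude is the default because it is the quantity the template
is parameterised by). Coherent averaging of `n` repetitions is predicted to
gain `10 log₁₀ n` dB of SNR, and the simulator reproduces this empirically.

**Artifact handling.** Both artifacts are identical and simultaneous on
all electrodes. They overlap the early-electrode spikes in time at fast
conduction velocities, so zeroing their windows truncates biological
signal and biases the delay-and-sum argmax by one to several grid bins;
subtracting the per-sample cross-electrode median also biases it, because
a graded fraction of the signal leaks into the median when the spike spans
all electrodes. The default pipeline therefore regenerates the
deterministic artifact waveforms from the recording's own metadata and
subtracts them — the simulation counterpart of the supervised artifact
rejection applied to bench data. Window blanking, common-mode median
subtraction and no-op modes remain available (`artifact_removal=`).

## Velocity selective recording

Candidate inter-electrode delays are the integer sample shifts `s` with
`v = pitch/(s·Δt)` inside [1, 60] m/s at the 500 kHz analysis rate; for a
1 mm pitch the grid starts at `s = 9` (55.6 m/s; `s = 8` would be
62.5 m/s). `delay_and_sum` advances electrode `i` by `i·s` samples and
sums, so a forward-propagating wave with true delay `s` adds
constructively at `+s`; the sign of `s` encodes direction. The metric is
the peak absolute value of the summed trace; ties break deterministically
toward smaller `|s|`, then forward. No sub-sample refinement is applied —
the estimator works on the integer grid by design.

δ, the velocity tolerance, is half the spacing between the two adjacent
grid velocities (`(v(s−1) − v(s+1))/2`, ≈ 5.05 m/s at 50 m/s for 1 mm /
500 kHz); at the fast grid edge the one-sided gap is used. The SR over
`N` time-locked repetitions is the fraction of per-repetition estimates
that land within one grid shift of the reference estimate from the
pointwise-mean epoch. The one-grid-shift bracket (equivalently, the
one-sided gaps on each side) rather than the symmetric mean-gap δ is used
for counting because the gaps around a grid point are asymmetric: with the
symmetric δ the upper adjacent bin fails by ~3%, which halves SR whenever
the true velocity falls mid-bin. Epochs whose mean yields no estimate give
an undefined, flagged SR. Recordings with velocity > 60 m/s or more than
one spike per electrode are discarded with a recorded reason.

## SR response-surface model

`SR ~ a₀ + a₁ N_E + a₂ pitch + a₃ width + a₄ e^(1/v) + a₅ SNR`, ordinary
least squares on the untransformed SR in [0, 1] (a logit variant is out of
scope; predictions are clipped). Term significance is a type-II F-test at
α = 0.05. "Standardized half effect" of term `j` is `a_j · range_j / 2` —
the SR change from the midpoint of the factor's observed range to its
extreme, i.e. the coefficient under [−1, 1] coding — with a 95% CI scaling
the coefficient's standard error by the same half range. The safe region
maps predicted SR ≥ 0.8 over SNR × velocity × channel length (channel
length enters through the length-gain calibration as an SNR offset,
`20 log₁₀ scale(L)`); below threshold the minimal coherent-averaging count
`n` with `SR(snr + 10 log₁₀ n) ≥ 0.8` is reported in closed form, `∞` when
the SNR coefficient cannot reach it.

## Opto-thermal neuroinhibition

**Thermal model.** Surface heating follows a first-order response to the
light square wave: rise `ΔT_max (1 − e^(−t/τ))` during a pulse, exponential
decay with the same τ after, piecewise-exact across pulse trains. Defaults:
τ_polymer = 3.22 s, ΔT_max = 10 °C, 15-s pulses every 45 s focused on
electrode E4, with a Gaussian spatial footprint of σ = 1.5 mm (heat spreads
over a few millimetres).

**Coupling (generator calibration).** Fibre amplitude at electrode `z` is
scaled by `1 − r(t) · c_class · ΔT_ss(z)`, where `r(t)` is a first-order
activation of the light square wave with a class time constant. The
defaults are calibrated once to the study conditions the analyses assume:
`τ_fast = τ_polymer = 3.22 s` (large fibres track the temperature),
`τ_slow = 2 τ_polymer` (thin fibres respond more slowly), `c_fast = 0.031`,
`c_slow = 0.075 /°C` (thin fibres couple more strongly), so that the
fitted inhibition time constant of fast fibres is about half that of slow
fibres and the pooled end-of-pulse NSD of fast fibres is about twice that
of slow fibres across the unmasked electrodes. When the steady-state spot
heating reaches the block threshold (8 °C), slow fibres are additionally
conduction-blocked downstream of the spot: the downstream scale relaxes to
zero with the same slow kinetics, giving zero contribution in sustained
light and full recovery after light-off. Fast-fibre conduction velocity
rises slightly with temperature (0.003 /°C). All modulation is reversible
by construction.

**NSD.** Per electrode, each stimulus epoch is split at the arrival time
of a threshold fibre (`d / 5 m s⁻¹`, `d` = distance from the stimulation
cathode): earlier arrivals are "fast", later ones "slow". The band-passed,
artifact-subtracted response is rectified and integrated over each window
(signal energy `x²` is a config alternative), with the per-electrode epoch
truncated at the arrival of a 1.5 m/s fibre to bound the rectified-noise
area. Densities are normalized per (electrode, class) by the mean over the
first 10 control responses — which must precede the first light pulse — so
the control mean is exactly 1 by construction. The ITO electrodes under
the light spot (E4–E6) are masked by default in session analyses. The
rectified noise floor adds a pulse-independent offset to both numerator
and denominator, compressing NSD excursions toward 1 at finite SNR; ratios
quoted against the noiseless generator values are therefore evaluated on
noiseless sessions.

**Kinetics.** Inhibition: `NSD(t) = P + (1 − P) e^(−t/τ)` with `t` the
time since light onset; recovery: `NSD(t) = 1 + (NSD_off − 1) e^(−t/τ)`
since light-off. NSD is averaged across electrodes per pulse and pooled
across cycles before nonlinear least squares; R² is reported and
non-convergence is flagged rather than raised.

**Statistics.** The factorial ANOVA of NSD uses illumination phase, fibre
class, electrode and session, plus the illumination × class interaction
(all two-way interactions optional). The NSD is studentized within each
(session, electrode, class) cell first: the rectified-area noise scale
varies several-fold across cells (window lengths and gains differ), and on
the raw scale the pooled F-test for illumination is conservative (~2%
type-I at α = 0.05 under a zero-coupling null); on the studentized scale
it is calibrated (~5%, uniform null p-values), with the cell-constant
factors acting as blocks. Post-hoc one-way ANOVAs test illumination within
each class. SNR-by-channel-length comparisons use a Kruskal–Wallis omnibus
test with Bonferroni-corrected pairwise two-group tests.

## Problem sizes and numerical choices

Monte-Carlo suites run at reduced problem sizes chosen to keep each run on
one CPU core in minutes: velocity-recovery uses 200 single-epoch trials at
30 dB with a 0.1 ms template (narrow templates make the constructive-sum
peak discriminative across shifts; at 0.22 ms the metric differs by < 0.1%
between adjacent shifts above ~45 m/s, which is precisely why SR falls
with velocity); the ANOVA null calibration uses 200 replicates of compact
4-electrode sessions (1 Hz stimulus, shortened light cycles — timing is
irrelevant under the null); significance checks use the study's 15-s-on /
30-s-off cycle because slow-fibre suppression does not recover across
shorter gaps. Session simulations run at the 25 kHz polymer-experiment
acquisition rate with MUAP-scale widths (0.4/0.6 ms) compatible with the
template sampling guard.

Degenerate inputs are defined rather than left to chance: flat epochs give
a no-estimate result; an all-blanked detection epoch gives an empty event
list, not an error; zero-range factors give zero, flagged half effects;
empty integration windows give zero density with a warning; negative
thermal scales clip at zero with a warning.

## What the generator does and does not emulate

It reproduces the features the analyses rely on: propagation delays linear
in electrode index, the 2/3-length amplification peak and its length
scaling, simultaneous common-mode artifacts, calibrated noise, repetition
structure, and class-specific reversible thermal modulation with a spatial
gradient. It does not model biophysics (no cable equations, no
Hodgkin–Huxley temperature dependence), electrode impedance or ITO noise,
waveform variability across repetitions (jitter is optional and off by
default), overlapping-unit superposition beyond linear addition, or heat
diffusion beyond a static Gaussian footprint with first-order kinetics.
Passing tests therefore validate the estimators and statistics under the
generator's assumptions — not the biology of real rootlets, where
repetition-to-repetition waveform irregularity is the dominant extra
variance source.
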