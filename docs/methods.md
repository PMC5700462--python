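# Methods

## The kinetic model

The probe on the nanowire is modelled as a three-state semi-Markov jump
process over the conformations duplex ("low"), hairpin ("intermediate") and
single strand ("high"), named for their conductance levels. Leaving state
*i*, the destination *j ≠ i* is drawn with exit probability *P(i→j)*
(rows of *P* sum to 1, zero diagonal) and the sojourn duration from an
exponential with mean *τ(i→j)* in milliseconds. Drawing the destination
*before* the duration is deliberate: measured dwell-time histograms of the
same state differ depending on the following conformation, which a
memoryless continuous-time Markov chain (one exit rate per state) cannot
produce. The semi-Markov construction reproduces destination-resolved
lifetime matrices exactly by design.

Closed-form long-run occupancy: with π the stationary distribution of the
embedded jump chain (πP = π) and d_i = Σ_j P(i→j) τ(i→j) the
destination-averaged mean sojourn, the time fraction of state *i* is
π_i d_i / Σ_k π_k d_k. For the bundled well-matched (WT-C) parameters this
gives 87.7 / 11.1 / 1.1 % (low/intermediate/high). The *measured* reference
occupancy profile for the same target is 78.5 / 20.2 / 1.3 % — the two
disagree, most plausibly because real idealization misses fast events. The
package reports both and never forces agreement; simulation-based tests
assert against the closed form, calling tests against the measured profiles.
One visible consequence: occupancies simulated from the reference kinetics
of the two middle mismatches (MT-A ≈ 6.2 %, MT-G ≈ 7.4 % low) sit between
the measured MT-A and MT-G profiles and can swap nearest-reference labels;
the well-matched vs mismatch separation is unaffected.

## Trace rendering

Rendered traces are the piecewise-constant level signal sampled at
`sample_rate` (default 28.8 kSa/s, i.e. 28.8 samples per ms) plus additive
Gaussian noise (`noise_sd`, default 0.5 nA) and an optional spectrally
synthesized 1/f component (`pink_amplitude`, default 0 for probe recordings,
0.3 nA for blank devices, where 1/f background dominates). The noise sum is
band-limited by a first-order Butterworth low-pass at `filter_cutoff`
(default 5 kHz) and rescaled to its nominal standard deviation, emulating
the acquisition chain's anti-alias filter. The filter is applied to the
noise process only: conformational transitions are fast compared with the
filter rise time, so step edges are rendered sharp. This keeps a noiseless
trace exactly equal to its level sequence and makes zero-noise rendering
exactly invertible by nearest-level assignment, which the tests exploit as
ground truth.

The default `noise_sd` of 0.5 nA is a package choice (no noise magnitude is
published): adjacent levels ~3 nA apart are then ≥ 3σ separable, matching
clearly resolvable amplitude-histogram peaks. Dwells shorter than one
sampling interval (0.0347 ms, vs a shortest bundled lifetime of 0.55 ms) are
clamped to one sample with a warning.

The two-level control (hairpin folding/unfolding, no target) uses package
defaults of 10 ms folded / 2 ms unfolded at levels 0 / +3 nA; only the
qualitative two-peak structure matters and no published values exist.

## Idealization

Amplitude histograms are fitted as 1–3 component Gaussian mixtures on the
raw samples (no binning; Freedman–Diaconis binning is used only for
diagnostic histograms), with quantile-initialized EM plus nine
randomly-initialized restarts per k, a fixed internal seed, and selection by
minimum BIC. BIC replaces visual peak counting for determinism. Baseline
("0") assignment is per k: the middle component for k = 3 (the hairpin sits
between duplex and single strand) and the lower component for k = 2 (the
folded hairpin of the control); reported means are re-centered so the
baseline is exactly 0, preserving the sign convention low < 0 < high.
Traces longer than 100,000 samples are evenly strided down for the mixture
fit only; decoding always uses every sample.

State assignment uses a Gaussian-emission HMM with emissions fixed at the
mixture estimates, the transition matrix re-estimated by EM from a sticky
(0.98 diagonal) start, and Viterbi decoding; components map to state labels
by sorted mean. Dwells shorter than the minimum-dwell threshold (default 2
samples ≈ 0.07 ms, the 5 kHz filter rise-time scale) are merged into the
longer neighbour, ties going to the preceding dwell, shortest offenders
first. No drift or baseline-wander correction is applied (the modelled
traces are stationary), and no dead-time correction is applied by default —
none is published — though `fit_exponential(dead_time=...)` provides the
first-order additive correction.

With the default noise the per-sample Bayes error for Gaussians 3 nA apart
at σ = 0.5 is ~0.13 % per adjacent-level boundary; HMM smoothing can only
improve on independent classification, which is why the tests demand > 99 %
per-sample recovery.

## Dwell statistics

The first and last sojourns of a path have unobserved predecessor/successor
and are censored from dwell statistics; occupancy is a whole-trace time
fraction and uses every sojourn. Lifetimes are exponential MLEs (the sample
mean) on raw durations — the primary estimate, since any binning choice
would be arbitrary — with 95 % nonparametric bootstrap percentile intervals
(1,000 resamples, seeded) and a binned least-squares single-exponential fit
retained as a diagnostic cross-check. Directions with fewer than the fit
floor (default 10) dwells report counts but no lifetime. Transition
probabilities are direction count fractions, so each estimated row sums to 1
exactly. Reported percentages are rounded to one decimal.

## Allele calling

Replicate occupancies aggregate as arithmetic mean ± sample standard
deviation (n−1). The published ± terms of the reference profiles match
neither SD nor SEM exactly; they are stored and used as dispersions but
never asserted. Calling is nearest-reference under Euclidean distance on the
three state percentages, each coordinate standardized by the reference
dispersion floored at 0.5 percentage points (the published discrimination
was visual; a concrete metric is required, and the floor prevents near-zero
dispersions from dominating). Exact ties break toward the larger low-state
percentage — the more conservative, well-matched-leaning call — and are
flagged. Stability rankings order alleles by destination-averaged low-state
lifetime (descending) and by P(low→high), the unwinding probability
(descending). Targets with multiple mismatches need no special casing: lower
duplex occupancy simply yields larger distances from the well-matched
profile.

Three cells of the published averaged-occupancy table are inconsistent with
their own five device columns at one decimal (MT-G low 8.3 vs 8.06, MT-G
intermediate 72.0 vs 72.26, MT-A high 6.4 vs 6.48; re-checking also finds
MT-A intermediate 90.0 vs 89.92 and MT-G high 19.7 vs 19.64). These are
treated as probable typos: exact-aggregation tests cover only the
arithmetically consistent cells (all of WT-C and MT-T, MT-A low).

## Melting curves

Normalized A260 melting curves are fitted by nonlinear least squares to the
two-state sigmoid f(T) = lo + (hi − lo)/(1 + exp((t_m − T)/slope)).
Normalization is by the *fitted* baselines, not raw extrema (robust to noise
at the temperature ends); decreasing-orientation curves are flipped
automatically and flagged; a fitted midpoint outside the measured span only
warns. The unfolded fraction at temperature T is the baseline-free sigmoid
value. Thermodynamic (van 't Hoff) parameter extraction is out of scope: the
reference data are normalized curves and midpoints only (hairpin 46.5 °C,
well-matched duplex 59.6 °C; mismatched-duplex midpoints are published only
as an ordering, which is used only descriptively). The transition width used
in simulations, 2.5 °C, is a package choice typical of short-oligonucleotide
duplexes on a 15–80 °C, 5 °C-step grid.

## Problem sizes and determinism

Every stochastic routine takes one explicit integer seed; no global RNG
state is used, and identical configuration plus seeds yields byte-identical
pipeline reports. Test and acceptance problem sizes are chosen so sampling
error sits well inside the asserted tolerances: 20,000 exits for parameter
recovery (the low state then completes ~7,700 sojourns for the well-matched
model, giving a lifetime standard error of ~0.2 ms), 50,000 exits for
occupancy-vs-closed-form checks (< 1 percentage point), 200,000 exits where
≥ 5,000 dwells are needed in the rarest direction, ~300-sojourn rendered
traces (~70,000 samples) for idealization round trips, and 100 replicates
for melting-curve bias/RMSE.

## What the simulations do and do not show

The generators reproduce the statistical structure the analysis assumes —
exponential destination-resolved dwells, Gaussian level noise, 1/f
background, band-limited sampling. They do not emulate baseline drift,
level-amplitude variation between devices within a run, flicker between
more than three levels, or any physical model of the conductance mechanism
(levels are free parameters). Passing round trips therefore validates the
estimation chain under its own model assumptions; they cannot certify
performance on instrument recordings, none of which are publicly available.
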