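# Methods

## Scope and data model

The package analyses simultaneous motor-cortex and dorsolateral-striatum
recordings: multi-channel continuous LFP (carried at 1 kHz), sorted single
units (spike times plus a 30 kHz waveform template), and behavioural-state
epochs (alert rest, walking). All downstream analyses consume exactly one
60-s `Segment` per behavioural state per subject, and require at least four
electrodes in each region; shorter epochs or thinner montages are rejected
with explicit reasons. Time is in seconds, 0-based, with half-open
`[start, end)` intervals. When several epochs of a state qualify, the
earliest one long enough to contain 60 s is used — a deterministic rule; no
principled criterion for choosing among qualifying epochs exists, so the
reproducible one was picked.

## Preprocessing

Wideband input is reduced to the LFP range by a zero-phase low-pass at
250 Hz followed by integer downsampling to 1 kHz. All band-limiting in the
package (the decimation low-pass, the 25–40 Hz filters for phase and STWA,
and the simulator's narrowband sources) is implemented as multiplication of
the real-signal spectrum by a raised-cosine magnitude mask — an exact
zero-phase linear filter applied circularly. This choice trades the edge
behaviour of a finite filter (a few wrapped samples at segment boundaries,
negligible at 60 s) for three properties that matter here: no group delay
(spike–LFP timing is preserved exactly), unit passband gain (a 30 Hz probe
tone passes with < 0.01 dB and < 1° error), and O(N log N) cost. The
band-pass transition width is 2 Hz; the decimation low-pass rolls off over
250–275 Hz, giving effectively complete stop-band rejection above 275 Hz.
The 0.1 Hz acquisition high-pass corner is represented by per-signal mean
removal: 0.1 Hz is far below the ≥ 8 Hz bands analysed and below the
spectral resolution of a 60-s segment for practical purposes.

## Spectral estimation

Welch PSDs use 1-s Hann windows with 50 % overlap (1 Hz resolution,
K = 119 averages on a 60-s segment), density-scaled so that the trapezoidal
integral over the one-sided grid recovers the signal variance. The window
length resolves the 12–18 vs 19–25 Hz low-beta split; the large K keeps the
coherence independence bias (1/K ≈ 0.008) small. Band powers are closed
trapezoidal integrals over [f_lo, f_hi] with interpolated edge ordinates,
making disjoint bands exactly additive. Peak frequency is the argmax of the
density inside the search band, ties broken to the lowest frequency. Band
normalisation is absolute (signal-units²); a relative-power column (band /
total) is emitted alongside, since either convention is found in practice.

## Coherence

Magnitude-squared coherence is computed from Welch-averaged auto- and
cross-spectra sharing the spectral estimator settings; the per-window FFTs
of each channel are computed once and reused across all cortex × striatum
pairs, which guarantees co-estimation and keeps the 16-pair grid cheap. The
estimator refuses K < 2 (single-window coherence is identically 1). No bias
correction is applied; instead the independence expectation 1/K is exposed
(`expected_null_coherence`) and verified by calibration. The summary
statistic is band-mean coherence per pair, then the arithmetic mean over
pairs, then over segments — band-averaging first keeps a meaningful
per-pair diagnostic table.

## Spike–field measures

Spike phases are read off the band-passed analytic signal at the nearest
1 kHz sample (≤ 0.5 ms error, ≈ 5° at 30 Hz). Phase 0 is the oscillation
peak. The phase-locking test draws exactly 40 spikes without replacement
(one seeded draw per unit), computes the resultant length R, Z = nR², and
the standard series approximation
p ≈ exp(−Z)·[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)];
a unit is locked when p < .05. Units with fewer than 40 spikes are excluded
and never enter denominators. The STWA averages band-filtered LFP snippets
over ±100 ms around spikes (the window spans ≥ 2.5 cycles at 25 Hz, enough
for a meaningful peak-to-trough); its magnitude is referenced to the mean
over 20 surrogate trains built by permuting inter-spike intervals (count
and ISI multiset preserved, phase alignment destroyed; circular rotation
would be an acceptable alternative and the construction is isolated in one
function). The LFP is filtered before averaging rather than filtering the
average; for a linear zero-phase filter the two orders differ only through
snippet edges. The analysis electrode per region is the one with the
highest 25–40 Hz power — a deterministic, power-maximising choice recorded
in the output.

## Unit metrics

Trough-to-peak duration is measured on the waveform template from the
global trough to the subsequent positive local maximum, both refined by
3-point parabolic interpolation (the 0.033 ms bin at 30 kHz is coarse
relative to class differences); templates without a genuine positive
after-wave (> 1 % of trough magnitude) are invalid. The putative
pyramidal/interneuron split uses configurable defaults — pyramidal iff
trough-to-peak > 0.30 ms (strict) and rate < 20 Hz — which are conventions,
not measured boundaries, and are echoed into outputs. Cluster separation
indices: J1 is the mean squared distance of points to their own centroid,
J2 the size-weighted mean squared distance of centroids to the grand mean,
J3 = J2/J1, pseudo-F = (J2/(k−1))/(J1/(N−k)), and Davies–Bouldin uses mean
Euclidean distance to the centroid as scatter. J3 is defined by the
within/between scatter-ratio convention of spike-sorting software, the only
widely used definition by that name. All three are verified against an
independent brute-force double-loop implementation to 1e−10.

## Group statistics

Normality is screened per group with a one-sample KS test against a normal
with the sample's mean and SD; this estimated-parameter variant is
conservative (true type-I rate below nominal), which only makes the
non-parametric routing (Kruskal–Wallis with Bonferroni-adjusted pairwise
comparisons; Wilcoxon for paired data) less frequent. One-way ANOVA carries
all-pairs Bonferroni t comparisons (adjusted p = raw × m, capped at 1);
two-way ANOVA uses type-II sums of squares, which coincide with other types
on the simulator's balanced complete designs. The locked-proportion
comparison is a Pearson chi-square on the 2×2 locked/unlocked table, df = 1,
no continuity correction by default.

## Synthetic cohort

Each channel is `background + g_shared·s(t[−delay]) + g_private·b(t)`:
`s` a unit-variance 25–40 Hz noise source common to both regions (the
striatal copy delayed 5 ms, standing for conduction/polysynaptic lag),
`b` a private per-region source, and the background an independent
1/f^α process per electrode (α = 1, SD = 1 by default, envelope held flat
below 1 Hz so 60-s segments are not drift-dominated). Narrowband sources
are band-passed noise, not sinusoids, so coherence and phase estimators
face realistic bandwidth. Default gains are 0.3 (shared and private, both
regions), giving a sham-like expected band coherence of 0.13 and a clear
but not dominant beta peak. Because all mixing gains are known, the
expected band coherence has the closed form

    C(f) = (g_c·g_s·S)² / ((g_c²S + g_cI²S + σ²B)(g_s²S + g_sI²S + σ²B))

with S and B the unit-variance spectral densities of source and background;
it is averaged over band bins and shipped as ground truth (the delay only
rotates the cross-spectrum phase). The closed form was verified against
Monte-Carlo coherence estimates before being relied on.

Units fire as inhomogeneous Poisson processes with intensity
λ(t) = r₀·exp(κ·cos(φ(t) − μ))/I₀(κ), realised by thinning at the envelope
rate r₀·e^κ/I₀(κ); the I₀ normalisation keeps the time-averaged rate at r₀
for any κ, decoupling rate from locking strength. The expected vector
strength is I₁(κ)/I₀(κ). A 1.5 ms absolute refractory period is imposed
after thinning — a sorted single unit must show one, and the refractory
screen would otherwise reject every simulated unit; at the simulated rates
this trims well under 1 % of spikes. Spikes lock to the phase of the summed cortical
beta component — what a cortical unit would feel — so phase estimates from
a noisy electrode are attenuated relative to the von Mises prediction,
as in real data. Default unit set: eight cortical units, four locked
(κ = 2, spread preferred phases, broad 0.45 ms templates) and four
unlocked (κ = 0, narrow 0.2 ms templates), rates 2–10 Hz.

The cohort layout mirrors a groups × weeks × states design (sham / lesion /
lesion-treated). An effect table maps each (group, week, state) to shared
and private gain multipliers; the default gives the lesion group a 2×
shared gain (which more than doubles expected coherence) and relaxes the
treated group geometrically toward sham across weeks, a phenomenological
stand-in for a time-dependent therapeutic effect. Subjects receive
lognormal gain jitter (CV = 0.1) so groups are populations rather than
clones. Walking is modelled as a +2 Hz shift of the band centre and a 0.8×
gain multiplier — the direction reported for behaving animals; magnitudes
are conventions, configurable, since no quantitative description exists to
copy. One master `SeedSequence` spawns one child per cohort cell in fixed
loop order, so any cell is reproducible in isolation.

What the simulator does *not* emulate: non-stationarity within segments,
movement or line-noise artefacts, volume conduction, cross-frequency
coupling, non-Poisson spike history (bursting, refractoriness beyond the
thinning construction), and electrode drift. Passing recovery tests
therefore certify the estimators and the pipeline plumbing, not robustness
to those real-data pathologies.

## Problem sizes and numerical choices

Calibration experiments run at: 200 independent-noise seeds for the
coherence null; 10 000 replicates for Rayleigh type-I; 100 units each for
the STWA null and κ = 4 effect; ≥ 1000 spikes per rung of the κ ladder;
100 seeded cohort replicates (3 groups × 8 subjects) for the effect and
null recovery rates in the test suite, 50 each in the reproduction script.
These sizes put Monte-Carlo error comfortably below the decision margins
they feed. Degenerate inputs fail loudly rather than silently: zero-LFP
shuffle ratios raise, coincident centroids raise, constant samples are
insufficient for KS, single-window coherence is refused.

## Known limitations

- The circular (FFT) filters wrap a few samples at segment edges; STWA
  windows beginning or ending outside the segment are dropped instead.
- The repeated-measures designs of longitudinal data are approximated by
  subject-blocked fixed-effects ANOVA; no mixed models or sphericity
  corrections.
- Spike sorting itself (detection, template matching, curation) is out of
  scope; only its quality metrics are implemented.
- No artefact rejection or notch filtering; inputs are assumed clean, as
  the simulator's outputs are.
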