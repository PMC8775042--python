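# Methods

## Model and procedure

The artifact statistic is the first, fixed-scale stage of detrended
fluctuation analysis. The record `x_1..x_N` (volts) is turned into the
profile `Y(i) = Σ_{k≤i}(x_k − ⟨x⟩)`; the profile is tiled with
non-overlapping segments of `SL` samples; each segment is reduced to

```
F_D(j) = sqrt( (1/SL) Σ_k resid_j(k)² )
```

where `resid_j` is the residual of the least-squares line fitted to the
profile inside segment `j`. No scaling exponent is fitted: the segment
fluctuation itself carries the information. Coarse movement transients
integrate into large profile excursions (high `F_D`); slow drifts produce
profiles that are locally almost linear (`F_D` near zero); the ECG sits in
between.

Two printed forms of the fluctuation exist — a mean of squares and its
square root. The RMS form is the default because the slow-artifact
threshold is derived from it: a segment whose squared residual equals 0.01
at every sample has `F_D = sqrt(0.01) = 0.1` for **any** `SL`, which is
precisely the constant `TH3 = 0.1`. The mean-square form is available
(`form="mean_square"`) for sensitivity analysis but is not used by the
reduction.

### Decision rules

1. **Coarse presence.** `(max x − min x)/2 − sqrt(M) > 1` with
   `M = ⟨x²⟩`. Sparse multi-volt transients stretch the half-range while
   barely moving the RMS; dense equal-magnitude oscillation (half-range ≈
   RMS) and quiet records stay below 1 V. The inequality is strict and
   dimensional — inputs must be in volts (a `scale` argument converts on
   load).
2. **Coarse segments.** When the presence criterion fires, `F_D > TH1`
   eliminates the segment. `TH1` combines an amplitude term
   `(((max−min)/2)² − M)·C·median(F_D)` with a spread term
   `(SD(F_D)+SD(x))/(SD(F_D)·SD(x))·C1`; `C` has units 1/V² (best range
   0.15–0.35, default 0.25, the midpoint), `C1 = 1 V`. Standard
   deviations are the unbiased (n−1) form, the median is the
   midpoint-of-two for even counts, and all segments enter the `F_D`
   statistics — no pre-screening.
3. **Spill-over (adjacency).** An immediate neighbour of a coarse segment
   is eliminated when the coarse segment's `F_D` exceeds the neighbour's
   by more than `TH2 = TH1/2`. Two readings of this rule circulate: the
   difference form implemented here, and a form that compares the
   neighbour's **own** `F_D` with `TH2` (available as
   `adjacency="own"`). The difference form is the default because it is
   the only one that achieves the rule's purpose: a burst fragment
   spilling a few dozen samples into a quiet neighbour cannot raise that
   neighbour's own `F_D` above `TH1/2` (the contribution is bounded by
   fragment area over `sqrt(SL)`), whereas the difference against the
   adjacent coarse segment's large `F_D` flags it reliably. Adjacency is
   single-hop: adjacent-eliminated segments do not propagate further, and
   in a bidirectional grid it acts within each segmentation pass.
4. **Slow segments.** Independently of 1–3, when
   `mean(F_D) − SD(F_D) > TH3` every still-kept segment with
   `F_D ≤ TH3` is eliminated. The guard protects low-amplitude but clean
   records, whose `F_D` distribution sits near `TH3` as a whole, from
   being gutted.

Ties always keep the segment (strict `>` for elimination, `≤` for the
slow rule's boundary on the elimination side as printed). Elimination is
exclusion: kept segments are concatenated; `index_map` maps every cleaned
sample to its original index so that beat intervals spanning a gap can be
invalidated downstream. Zero-variance records raise internally but the
batch entry point returns them unreduced with `degenerate=True` and a
warning, so pipelines keep running.

### Grids

`SL = round(0.5 s · fs)` by default — long enough to hold a full QRS-T,
short enough that a burst rarely shares a segment with more than one
beat. Forward tiling drops the trailing remainder. Records under 10 000
samples use the bidirectional grid (forward plus end-aligned passes,
doubling the segment count, duplicates permitted when `SL` divides `N`)
so the threshold statistics are not starved; `mode="auto"` switches on
that sample count.

### Online mode

The first `init_seconds = 50` s are buffered and processed exactly as a
batch (forward grid); their decisions are emitted first. Each later full
segment appends its `F_D` to the ever-growing collection, the amplitude
aggregates (count, sum, sum of squares, min, max — the running mean
enters the profile incrementally) and the thresholds are refreshed, and
the segment's decision is emitted immediately. Because the profile is
detrended per segment, the running mean's contribution (constant plus a
term linear in the sample index) is absorbed by the linear fit, so online
`F_D` values match batch values computed with a different global mean.
Spill-over can only act causally: a segment following a coarse one is
checked, an already-emitted predecessor is never retracted. On stationary
records online and batch decisions agree on ≥95 % of post-init segments
(tested); disagreement comes from thresholds drifting as statistics
accumulate.

## Binarized entropy

Differential encoding `c_i = 1{x_{i+1} − x_i > 0}` (ties → 0, code length
`N − 1`) makes the estimators invariant to offsets and positive rescaling
— amplitude artifacts only matter through sign changes. Windows of `m`
bits at delay `τ` (default 1) take one of `2^m` symbol values, so
template matching reduces to a histogram multiplied by the precomputed
Hamming-distance indicator `1{h_{kn} ≤ r}`; this is *identically* the
naive O(N²) pairwise comparison (property-tested across `m ≤ 4`,
`τ ≤ 3`, `r ≤ m`) at `O(N + 4^m)` cost. The tolerance `r` is an integer
(Hamming distances are integers); non-integer values are floored with a
warning. Window counts use the code length `N' = N − 1` in all
denominators.

`BinApEn = Φ̂^m − Φ̂^{m+1}` with `Φ̂` the pmf-weighted log of the
within-`r` match probability (natural log; zero-probability symbols
contribute nothing; a realized symbol always matches itself, so the log
is finite). `BinSampEn = −10·log₁₀(Φ̃^{m+1}/Φ̃^m)` where the tilded sums
exclude each window's self-match from numerator and denominator of the
match proportion. The decibel-style −10·log₁₀ form is kept exactly as
defined; note it is a ratio of sums of logs, not a count ratio, so the
value can be negative, and it is undefined — returned as NaN with a
warning, never as 0 — whenever `Φ̃^m = 0` (e.g. any `r ≥ m`, or a
constant record) or the ratio is non-positive.

## Synthetic records

The generator emulates the statistical structure the method is built for,
not cardiac electrophysiology:

* **ECG**: per-beat sum of five Gaussian bumps (P, Q, R, S, T at fixed
  offsets/widths), R amplitude `ecg_amp` (default 0.5 V — between the
  sub-volt car-seat regime and the volt-scale bed regime), placed at RR
  intervals `60/hr_bpm` with 5 % relative Gaussian jitter (default
  70 bpm), plus white measurement noise (SD 0.02 V).
* **Slow artifacts** *replace* the ECG — they model stretches where no R
  peak is discernible — with Gaussian noise FFT-confined to 0.5–15 Hz,
  scaled to `amplitude_ratio` (default 1.0) times the clean-ECG RMS.
  Defaults: 4 intervals of 2–8 s per 300 s record.
* **Coarse artifacts** are *superimposed*: 10 bursts of 0.2–2 s with peak
  amplitude drawn from 2–8 V. The default `spike_train` shape is a
  saturating low-frequency swing (0.4–3 Hz sum of random sinusoids, with
  3–20 Hz transients riding on it, soft-clipped by `tanh` and
  peak-normalized to the drawn amplitude): movement modulates the
  electrode coupling capacitance, producing large near-full-scale swings
  rather than zero-area impulses. `step` and `clip` shapes (sustained
  plateaus) exist but model a failure mode this method cannot see
  mid-interval — see Limitations.
* **Ground truth** is a typed partition of `[0, N)` into
  useful/coarse/slow intervals; R peaks inside artifact intervals are
  removed (an expert could not have marked them). Artifact intervals
  never overlap and keep a 1 s margin from each other and the edges.
* **Bed protocol** (`protocol="bed"`): scripted movement every 60 s in
  the first half (5 s per movement — the cadence is specified, the
  movement duration is not, and 5 s is a typical repositioning time) and
  a rest/move/rest block in the second half (120/60/120 s when the half
  is at least 300 s; the 2:1:2 proportions otherwise). Requires ≥300 s.

One `numpy` generator seeded from `SyntheticConfig.seed` drives
everything; equal seeds give bit-identical records.

What passing on these surrogates does **not** show: robustness to real
electrode physics (clothing-dependent coupling, mains interference,
respiration drift), to pathological rhythms, or to artifact morphologies
outside the modelled families. The generator's artifact distributions
beyond the documented amplitude/band anchors are invented and exposed as
configuration.

## Evaluation conventions

A segment's true label is operational: useful iff it contains ≥1
annotated R peak. At `SL = 0.5` s and ~70 bpm roughly 40 % of artifact-free
segments contain no beat, so specificity against this truth is
structurally low for a conservative reducer; sensitivity and the
preserved-R-peak percentage are the informative numbers. SNR is
`10·log₁₀` of the mean-square power ratio between useful intervals and
the remainder; with multi-volt bursts present it is strongly negative.
pNN50 uses the standard successive-difference definition (|ΔRR| > 50 ms);
the looser share-of-RR-intervals > 50 ms reading is computed alongside
(`pnn50_literal`). Undefined metrics are NaN, never 0. Band power splits
a periodogram across requested bands and normalizes to 100 %.

## Problem sizes and numerical choices

The test suite and the acceptance script use twenty 300 s records at
400 Hz (600 segments each) for the headline percentages and 45–60 s
records elsewhere; these sizes give stable pooled fractions (≈7 000
segments) while keeping a full run in well under a minute. Least-squares
fits go through `numpy.linalg.lstsq` on an explicit design matrix (the
test oracles use `numpy.polyfit` independently); fit positions are
`1..SL`, though residuals are invariant to affine reindexing. The profile
is checked to close to zero within `1e−9·N·max|x|`. Oracle-equivalence
tolerances are 1e−9 relative for fluctuation values and 1e−12 absolute
for the entropies.

## Known limitations

* A sustained constant offset (step/clip burst interiors) is linear in
  the profile and therefore invisible to `F_D`; only its edges are
  caught. This is intrinsic to linear detrending at a single scale.
* Slow-changing artifacts with substantial 2–15 Hz content have `F_D`
  comparable to the ECG and largely survive the `TH3` rule; the method is
  deliberately conservative there, at the cost of specificity.
* `TH1` adapts to the record's own amplitude statistics: a record whose
  strongest burst far exceeds its weakest raises `TH1` for all, so very
  heterogeneous burst amplitudes degrade coarse recall.
* The online mode never discards old `F_D` values; thresholds adapt ever
  more slowly as a session grows, which is the intended behaviour for
  recordings of a few hundred seconds but would need windowing for
  hours-long streams.
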