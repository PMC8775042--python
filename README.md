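# cecgclean

Artifact reduction and binarized entropy for **capacitive ECG (cECG)** —
ECG recorded without skin contact, through clothing, by electrodes built
into a car seat or a bed. Such recordings are dominated by two artifact
families that defeat ordinary band-pass filtering:

* **coarse artifacts** — sparse movement-induced transients of several
  volts that dwarf the sub-volt ECG;
* **slow-changing artifacts** — disturbances of amplitude comparable to
  the ECG whose power sits mostly in 0.5–15 Hz, the band the ECG itself
  occupies.

`cecgclean` implements a segment-wise detrended-fluctuation method that
classifies each fixed-length segment as useful or artifact, eliminates the
artifact segments, and hands downstream HR/HRV analysis a cleaned series
with an index map. It also provides binarized approximate/sample entropy
estimators that work on raw artifact-laden signals, a synthetic cECG
generator with ground truth, and segment-level evaluation metrics.

## The method

For a record `x` of `N` samples, form the cumulative-sum profile of the
mean-centred signal, `Y(i) = Σ_{k≤i}(x_k − ⟨x⟩)`, cut it into
non-overlapping segments of `SL` samples (default 0.5 s; series under
10 000 samples are segmented from both ends, doubling the segment count),
and summarise each segment by its RMS deviation from its own least-squares
line — the per-segment fluctuation `F_D(j)`. Decisions use three
thresholds:

```
TH1 = (((max x − min x)/2)² − M) · C · median(F_D)
      + (SD(F_D) + SD(x)) / (SD(F_D) · SD(x)) · C1          (C = 0.25, C1 = 1 V)
TH2 = TH1 / 2
TH3 = 0.1
```

with `M = ⟨x²⟩` the uncentralized second moment. If the record-level
criterion `(max x − min x)/2 − √M > 1` (volts) detects sparse
high-amplitude transients, every segment with `F_D > TH1` is eliminated as
*coarse*, and a neighbour of a coarse segment is eliminated as *adjacent*
when the coarse segment's `F_D` exceeds its own by more than `TH2` (the
spill-over guard). Independently, when `mean(F_D) − SD(F_D) > TH3`,
segments with `F_D ≤ TH3` — profiles hugging their linear trend, the
signature of a slow-changing artifact — are eliminated as *slow*. An
online mode seeds the statistics on the first 50 s and refreshes the
thresholds as each new segment's `F_D` arrives.

The binarized entropies encode the signal as `c_i = 1` iff
`x_{i+1} > x_i`, histogram the `2^m` possible `m`-bit windows, and compare
windows by Hamming distance `r`:
`BinApEn = Φ̂^m − Φ̂^{m+1}` with
`Φ̂^m = Σ_k p̂(k) ln Σ_n p̂(n)·1{h_{kn} ≤ r}`, and
`BinSampEn = −10·log₁₀(Φ̃^{m+1}/Φ̃^m)` with self-matches excluded. The
histogram × Hamming-matrix path is exactly equal to naive pairwise window
comparison at `O(N + 4^m)` cost.

## Worked example

```
$ cecgclean simulate --duration 120 --coarse-count 4 --slow-count 2 --seed 1 -o rec
$ cecgclean clean rec.csv -o cleaned
$ cecgclean evaluate cleaned.mask.csv rec.json --signal rec.csv
{
 "confusion": {"tp": 117, "fp": 103, "tn": 13, "fn": 7},
 "metrics": {
  "accuracy": 54.166666666666664,
  "sensitivity": 94.35483870967742,
  "specificity": 11.206896551724139,
  "positive_prediction": 53.18181818181818,
  "negative_prediction": 65.0
 },
 "r_peaks_preserved_pct": 94.35483870967742,
 "r_peaks_lost_pct": 5.6451612903225765,
 "snr_db": -27.012269218413177
}
```

Reading the numbers: 94.4 % of segments carrying a true R peak survived
cleaning (sensitivity = preserved R-peak percentage here, since a
segment is "useful" iff it contains an R peak), and only 7 useful
segments were lost. The SNR of the raw record is strongly negative
(−27 dB) because the coarse bursts carry far more power than the useful
signal — exactly the regime the method targets. Specificity is low by
construction of the truth labels: at `SL = 0.5` s many artifact-free
segments simply contain no R peak (RR ≈ 0.86 s), and slow-changing
artifacts of signal-comparable amplitude are intentionally conservative
to eliminate, so most "useless" segments are kept. The thresholds the run
derived are in `cleaned.thresholds.json` (here `TH1 ≈ 13.3`, `TH2 ≈ 6.7`,
`TH3 = 0.1`).

Entropy on the same raw record:

```
$ cecgclean binen rec.csv --m 2 --r 1
{"m": 2, "tau": 1, "r": 1, "bin_ap_en": 0.3979765513958011, "bin_samp_en": -3.7070047781902957}
```

The same pipeline is available as library calls
(`cecgclean.generate_cecg`, `cecgclean.reduce_artifacts`,
`cecgclean.bin_ap_en`, …); see `docs/methods.md` for the model details and
design choices.

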