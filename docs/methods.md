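# Methods

## Problem and scope

`breathmss` implements the signal-processing and statistical pipeline used to
assess the reproducibility of total-expiratory breath measurements made with a
Membrane-type Surface stress Sensor (MSS) array. A measurement alternates
sample-gas injection and room-air purging through a 3-channel sensor at
100 Hz; the analysis extracts windowed feature values from the late, stable
sample/purge cycles and asks (i) how strongly the purge-gas humidity drives
those features, (ii) whether humidity-matched repeat measurements agree
(Bland-Altman), and (iii) whether a target compound (ethanol) in breath is
detectable after normalization. Because no raw dataset of this kind is
publicly deposited, the package ships a synthetic-data generator that
replicates the study design and provides the fixtures all analyses and tests
run on.

## Sensor response model (simulator)

Each channel responds to a stimulus as a first-order sorption process. For a
component with steady-state amplitude `A` the signal relaxes as
`A + (v0 - A)·exp(-t/tau_sorb)` during sample injection and decays as
`v0·exp(-t/tau_desorb)` during purging, with continuity across valve
switches. The total steady-state amplitude is additive and linear:

    A_total = h · (RH_sample − RH_purge) + Σ_v s_v · (c_v,sample − c_v,purge)

with `h` the humidity sensitivity (signal units per %RH) and `s_v` the
sensitivity to compound `v` (per ppm). Gaussian i.i.d. noise (`noise_sd` per
tick) and a linear baseline drift (`drift_rate`, units/s over the record) are
added on top.

Each compound may carry its own time constants (`voc_tau_sorb/desorb`,
defaulting to the channel constants). This matters: if every component shared
one time constant, each noise-free waveform would be a single scaled
exponential and min-max normalization would erase *all* compositional
information, not just amplitude. Giving the lumped endogenous-VOC component
and ethanol faster kinetics than water leaves a shape signature that survives
normalization — which is exactly the mechanism the normalized analyses rely
on.

Assumptions and known limitations: linearity and additivity of stimuli, no
viscoelastic overshoot, no temperature dependence, no sampling-bag aging, and
a single lumped "breath_voc" compound instead of a real VOC mixture. The
channel parameters are free modelling choices that reproduce the qualitative
behaviour of the device classes involved (Ch 1–2 hydrophobic-like and
ethanol-sensitive, Ch 3 hydrophilic-like, ethanol-insensitive, slower
kinetics); they are not estimates of any physical sensor.

### Default parameters

| parameter | Ch 1 | Ch 2 | Ch 3 | units |
|---|---|---|---|---|
| tau_sorb / tau_desorb | 1.2 / 0.9 | 1.5 / 1.1 | 2.5 / 2.0 | s |
| h | 0.010 | 0.008 | 0.012 | signal / %RH |
| s_breath_voc (tau) | 0.08 (0.35 s) | 0.05 (0.40 s) | 0.03 (0.50 s) | signal / ppm |
| s_ethanol (tau) | 0.0008 (0.30 s) | 0.0006 (0.35 s) | 0 | signal / ppm |
| noise_sd | 5e-4 | 5e-4 | 5e-4 | signal |
| drift_rate | 2e-6 | 2e-6 | 2e-6 | signal / s |

The ethanol sensitivities are deliberately small: at 60–120 ppm they add
0.05–0.10 signal units on Ch 1, comparable to the spread of the humidity
amplitude under uncontrolled room air (23.0–41.8 %RH spans ~0.19 units).
That is the regime the protocol addresses — raw-amplitude (offset) features
are confounded by purge humidity while normalized features still discriminate
— and it is what makes the pre/post-ethanol comparison behave realistically
rather than trivially.

### The study fixture

The default study configuration generates 83 breath and 33 reference
(humidified gas only) measurements. Sample-gas RH is drawn uniformly from
70.3–75.3 %RH; the lumped breath compound from N(1.0, 0.08) ppm (clipped at
0). Purge-RH values are **fixed deterministic lists**, not draws: within each
10-%RH bin they form a comb of slots 0.3 %RH apart, with designated matched
pairs 0.06 %RH apart and the reference comb offset 0.17 %RH from the breath
comb. This construction makes the printed design quantities exact and
testable: binning at 20/30/40/50 yields 24/25/34 breath and 10/12/11
reference members, and greedy RH matching at the 0.1 %RH tolerance yields
exactly 29 breath pairs — whether pairing is run on breath records alone or
on the pooled metadata, since every non-pair distance exceeds the tolerance.
All remaining randomness is driven by a single integer seed; the same
configuration and seed reproduce records bit-identically.

A `scale_only` variant disables compounds, noise and drift, so waveforms
differ by a pure scale factor. It isolates the scale-removal argument: a
noisy waveform does not differ from another by amplitude alone, and the
variant exists precisely to test the amplitude-only claim exactly.

### What the generator does not emulate

Real breath VOC mixtures and their day-to-day composition changes,
instrument drift structure beyond a linear term, temperature effects, and
any dependence between sample RH and breath composition. Passing tests
therefore demonstrate that the *pipeline* behaves correctly under the
study's assumed signal structure, not that the real device meets the
reproducibility criterion.

## Sequence, segmentation and waveform selection

The injection sequence is 40 cycles of 5 s, 10 of 10 s and one of 30 s
(sample half followed by purge half of equal length) at 100 Hz — 660 s,
66 000 ticks. The sequence is configuration, not inferred from data. A cycle
is represented as half-open tick intervals `[sample_start, purge_start)` and
`[purge_start, end)`; cycles tile the record exactly. The analysis waveforms
T1–T5 are the last five 10-s cycles (each slice 2000 ticks). The block
ordering follows the listing above; it is configurable since hardware could
schedule the single 30-s cycle elsewhere.

## Processing methods

*Start-point offset*: subtract the value at the sample-injection start tick;
preserves amplitude and therefore the humidity signal.

*Min-max normalization*: map the waveform's minimum to 0 and maximum to 1.
The min/max span defaults to the full cycle slice (sample + purge); a
sample-half-only span is available. A flat waveform is a degenerate input:
error by default, or all-zeros with a warning.

## Feature extraction

Extraction areas are 1.4-s windows with 0.6 s overlap (0.8 s step), anchored
at the sample-injection start and confined to the 10-s sample half, giving 11
areas labelled A–K (A = [0, 1.4] s, K = [8.0, 9.4] s). The stated "50%
overlap" rounds the actual 0.6/1.4 ≈ 43%; the 1.4/0.6 numbers are used
because they reproduce exactly the 11 labelled areas. Within an area the
processed waveform is read at 0.2-s intervals, endpoints inclusive — 8
points, exact ticks at 100 Hz, no interpolation — and the feature value is
their arithmetic mean. A full measurement yields 3 channels × 11 areas × 5
waveforms = 165 features per method; headline analyses use T1.

## Statistics

RH subgroups use left-closed bins (30.0 → "30-40") with the last bin closed
(50.0 → "40-50"); out-of-range values are excluded with a warning. The
Mann-Whitney U test uses the exact distribution when the smaller group has
≤ 8 observations and the pooled data are tie-free, otherwise the
tie-corrected normal approximation with continuity correction (SciPy
implements both behind the module's interface; tests validate the exact
branch against an independent full-enumeration oracle). Kruskal-Wallis uses
the tie-corrected H with a chi-square reference; a pooled spread at or below
1e-9 relative is treated as fully tied (H = 0, p = 1) so that
machine-epsilon residue is never ranked as signal. Bonferroni correction
multiplies by the family size m and caps at 1. The family for one
(channel, area) is all pairwise comparisons actually performed there —
3 within-breath + 3 within-reference + 3 breath-vs-reference per bin, m = 9
by default, recorded with every result. α = 0.01, two-tailed, configurable.
The representative area per channel is the one with the smallest breath
Kruskal-Wallis p.

## Pairing and Bland-Altman

Pair construction is a deterministic greedy match: sort by purge RH (ties by
date, then id), scan in order, and pair each unused measurement with the
next unused one when their RH difference is within tolerance (0.1 %RH).
Differences are first-listed minus second-listed member; bias is their mean;
the SD uses the n−1 denominator; the 95% limits of agreement are
bias ± 1.96 SD. The acceptance band is bias ± k·SD with k = 1 by default —
the study's "30% confidence interval" rule taken literally as 1 × SD of the
differences. k is configurable because a nominal 30% CI of a mean would be
≈ 0.385·SD/√n; the literal reading is the default, and whether "SD of the
bias" means the SD of differences or the standard error of the mean is an
ambiguity resolved in favour of the former. A channel is reproducible iff
zero lies inside the band in every area A–K; the assay iff all channels are.
At least 2 pairs are required (SD undefined below that).

## Pipeline runs and problem sizes

`run_reproducibility_study` simulates the 116-record study, builds both
feature tables, runs the subgroup statistics for both methods, pairs breath
records and computes Bland-Altman results for all 33 (channel, area) cells
plus the verdict; it emits tidy CSVs and a JSON summary with a config-hash
manifest, and is bit-reproducible under its seed. `run_alcohol_study`
simulates the 3-subject × 3-day pre/post design (9 + 9 records, ethanol
60–120 ppm post, 0 pre) and reports per-(channel, area) Mann-Whitney
results for both methods. Tests run these at their natural sizes (116 and
18 full-length records — a run takes a few seconds); the Monte-Carlo checks
use 2000 null replicates for test calibration and 5000 Gaussian pairs for
the limits-of-agreement coverage, sizes at which the binomial error bars are
far tighter than the asserted tolerances.
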