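# Methods

`gravimea` reimplements, as a tested pipeline, the analysis applied to
multi-electrode-array (MEA) recordings of cultured human neural networks
exposed to gravity changes — drop-tower microgravity (~4.7 s of free
fall followed by a 30–40 g impact) and centrifuge hypergravity (4 g / 6 g
plateaus with ~30 s ramps).  Because raw recordings of such experiments
are rarely deposited, the package includes a synthetic-recording
generator with full ground truth, so every stage — filtering,
referencing, detection, sorting, curation, burst detection, phase
segmentation, and the statistics — can be validated end to end.

## Signal chain

**Referencing and filtering.**  Raw 60-channel voltage data (microvolts,
25 kHz by default) are high-pass filtered with a second-order Butterworth
filter (cutoff 100 Hz) and then common-median referenced: at every sample
the across-channel median is subtracted from every channel, cancelling
artifacts shared by all electrodes.  The filter is applied
forward-backward (`scipy.signal.sosfiltfilt`).  Whether the original
toolchains filtered causally is generally unstated in publications; we
choose zero-phase filtering because it leaves spike trough times exactly
in place across gravity-phase boundaries, which matters when phases are
seconds long.  The price is a squared magnitude response — the
single-frequency gain is |H(f)|², i.e. 1/2 rather than 1/√2 at the cutoff
— and the tests assert the squared analytic curve.  The first and last
50 ms are treated as edge transient and excluded from detection.

**Detection.**  Per channel, the noise scale is estimated robustly as
MAD/0.6745, which is immune to the spikes themselves.  Spikes are negative
threshold crossings at 4.5·σ, aligned to the local trough, with a 1 ms
dead time.

**Sorting.**  Electrodes on a standard 60MEA are far enough apart that a
unit's footprint is confined to one electrode, so sorting is per-channel:
snippets (0.5 ms before to 1.1 ms after the trough) are re-aligned to the
running mean template by cross-correlation over ±2 samples (without this,
±1-sample detection jitter appears as spurious discrete clusters),
reduced to 3 principal components, and clustered with k-means for
K = 2..3; the K with the best silhouette wins only if that silhouette
exceeds 0.6, otherwise the channel keeps a single cluster.  Every
detected spike belongs to exactly one unit.  This deliberately replaces a
general-purpose density-graph sorter with a small, transparent one.

**Curation.**  Units are accepted when the ISI-violation rate (fraction
of inter-spike intervals below 1.5 ms) is ≤ 0.2, the SNR (template
trough-to-peak over the channel's MAD-σ) is ≥ 5, and the unit has at
least 10 spikes.  The published criteria name only the first two; the
spike-count floor is ours.  It is needed because band-limited Gaussian
noise crosses a 4.5·σ threshold at ~0.1–0.3 Hz per channel (Rice's
formula), and a "cluster" of one or two such excursions has a template
SNR near 5–6; a minimum count is the standard sorter-QC answer and is
what makes the empty-channel control (below) hold.  On multi-minute
recordings empty channels can accumulate tens of noise crossings whose
pooled template SNR sits right at the SNR ≈ 5 boundary; the control is
therefore run on short recordings, and hour-scale data would need an
additional waveform-shape criterion — a known limitation.

**Bursts.**  The five-parameter interval (MaxInterval) algorithm: a
candidate opens at an ISI ≤ 20 ms, extends while ISIs ≤ 100 ms,
candidates closer than 100 ms are merged, then candidates shorter than
20 ms or with fewer than 2 spikes are dropped — in that order.  With
these canonical parameters the merge step is provably vacuous (any
inter-candidate gap is an ISI that exceeded 100 ms); the tests assert
both this and exact agreement with an independent brute-force
implementation, because the ordering does change results for other
parameter sets.  A burst straddling a window edge is counted once, in the
window containing its start.

## Phases and rate tables

Schedules are ordered, non-overlapping labelled intervals with g-levels.
Presets encode the two platforms: drop (600 s baseline, 4.7 s
microgravity, 5 s impact, 600 s baseline; 150 ms safety margins) and
centrifuge (600 s baseline, ~30 s ramp up, 300 s plateau, ~30 s ramp
down, 300 s post baseline; 2 s margins).  The plateau and the post
baseline are `split` phases: their first and last minute are analysed
separately (hyperG1/hyperG2, post1/post2) to expose adaptation, giving
the seven centrifuge analysis windows.  Safety margins are trimmed from
both ends of every window so no spike near a transition is attributed to
the wrong gravity condition; all windows are half-open `[start, end)`.

A `scale` factor in (0, 1] compresses long phases for desk-scale runs
(600 s → 60 s at scale 0.1); phases shorter than 10 s — the 4.7 s
microgravity window and the 5 s impact, the scientific objects — are
never compressed.  For compressed centrifuge schedules the 2 s margin
scales too (clipped to [0.15, 2] s) and the split sub-window shrinks to
min(60 s, phase/3), so scaled schedules remain valid; at scale 1 the
published values are reproduced exactly.

Mean firing rates are spike counts over the window length; burst rates
count burst starts.  Units with zero firing rate in **any** analysed
window are removed entirely (their silence may be an artifact), and the
burst analysis is additionally restricted to units with at least one
burst in every window — this separate restriction is what makes published
burst-analysis unit counts much smaller than firing-rate counts.  Rates
are then log-transformed (base 10; the base only rescales the log values
linearly and affects no test statistic) — firing and bursting rates of
cultured networks are approximately lognormal, and the repeated-measures
ANOVA wants roughly symmetric within-unit errors.

## Statistics

Units are the "subjects" of a complete one-way within-subject design
(units pooled across runs, as in the published analysis; this ignores
run-level clustering and is replicated as-published, not endorsed).

* **RM-ANOVA + Geisser–Greenhouse.**  Classical decomposition,
  F = MS_condition/MS_error on (k−1, (k−1)(n−1)) df; the GG epsilon
  tr(S)²/((k−1)·tr(S²)) of the double-centred condition covariance
  rescales both dfs.  ε is clipped to [1/(k−1), 1] and equals 1 exactly
  at k = 2, where F equals the squared paired t.  Verified against
  `pingouin.rm_anova` and a step-by-step fixture oracle.
* **Tukey pairwise comparisons.**  q = |mᵢ−mⱼ|/√(MS_error/n) against the
  studentized range with k groups and the *uncorrected* error df — the GG
  correction applies to the omnibus test only, matching common
  statistical-software behaviour; both are configurable.
* **Friedman test** (mid-ranks, tie-corrected χ²) and **ROUT outlier
  screening** for waveform metrics (amplitude, trough half-width).  ROUT
  is adapted to a constant (location-only) model since it is applied to
  scalar shape parameters: median location, RSDR scale (68.27th
  percentile of |residuals|, small-n corrected by n/(n−1), floored at
  machine epsilon for degenerate samples), t-type two-sided p-values at
  n−1 df, Benjamini–Hochberg FDR at rate Q = 1%.
* **Density profiles.**  Gaussian KDE on a linear Hz grid [0, 30],
  Scott bandwidth, renormalized over the grid; a degenerate
  (zero-variance) sample falls back to a fixed 0.25 Hz bandwidth.  Linear
  Hz is used because the published figures are in Hz.
* **Subgroup deltas.**  The k = 10 lowest, middle, and highest firing
  units at the reference phase, ties broken by ascending unit id, with
  paired rates and signs of change.

The drop-design windows are hugely unequal (4.4 s microgravity vs ~60 s
analysed baselines), so measurement variance differs across conditions
and sphericity fails by construction.  The GG correction protects the
omnibus test; for the Tukey pairs the pooled error term means pairs
involving short windows run slightly liberal (~5% observed for the
baseline–microgravity pair under the null at these window lengths, vs
~1% nominal under sphericity) and pairs of long windows run conservative.
This is a faithful property of the replicated procedure, quantified by
the calibration tests rather than hidden.

## Synthetic recordings

The generator emulates the statistical structure the analysis assumes:

* **Baseline rates** are lognormal with σ = 0.5 and μ = ln 3 + σ², so the
  distribution *mode* — what a density-plot peak shows — is 3 Hz, with
  rates spanning roughly 1–25 Hz across 63 units.  Units are labelled
  low/mid/high by baseline-rate tertile.
* **Spike trains.**  Publications rarely state a generative train model;
  ours is chosen so the burst criteria are attainable and per-phase rates
  are exact: in each constant-rate segment the spike *count* is drawn
  Poisson with the exact target mean, then a fraction (0.6) of spikes is
  grouped into bursts (geometric lengths, mean 5 spikes; intra-burst ISIs
  2 ms refractory + exponential, mean 8 ms) at uniform onsets, the rest
  placed uniformly; a final thinning enforces the 2 ms absolute
  refractory everywhere.  Because counts are Poisson by construction,
  empirical rates track true rates at Poisson precision even for strongly
  burst-structured trains (the usual compound-Poisson overdispersion
  would otherwise break rate-recovery guarantees).  Inter-burst gaps
  follow from rate and burst fraction rather than being a free parameter.
* **Waveforms and noise.**  Each spike is a trough-dominant biphasic
  template (1.6 ms window: 0.3 ms half-sine trough carrying 75% of the
  amplitude, 0.5 ms rebound), amplitude lognormal with median 30.5 µV,
  on the unit's single electrode; channels carry 4 µV Gaussian noise, an
  optional common-mode sinusoid, and a configurable fraction of empty
  channels (default 10%).  One unit per electrode, doubling up only when
  more units than occupied electrodes are requested (the default 63 units
  on 54 occupied channels leaves 9 two-unit channels for the sorter to
  separate).  File calibration is 0.1 µV/LSB int16 (±3276 µV range,
  quantization far below the noise floor).
* **Phase effects.**  Modulation is multiplicative per subgroup —
  neurons scale their rates, preserving within-group rank order; absolute
  rate resets would inject unit×phase interaction variance that the
  planted effects never imply.  The drop preset: microgravity ×4/3 on
  low and mid units (moving the 3 Hz density peak to 4 Hz) and an exact
  alternating ±(×4/3, ×3/4) split on high units (a mixed response, half
  up, half down); impact factors move the tertile medians to 8 Hz
  (low+mid) and 20 Hz (high), producing the bimodal impact density.  The
  centrifuge presets: ramps push tertile medians into the 8–13 Hz band,
  and hypergravity onset (hyperG1) suppresses low/mid units toward 2 Hz
  while high units persist.
* **Determinism.**  One root seed; truth and rendering use independent
  `SeedSequence` sub-streams, so identical (config, seed) reproduce
  recordings and ground truth bit for bit.

What the generator does **not** emulate — electrode drift, cross-channel
spillover, bursts with amplitude adaptation, non-stationary noise, LFP,
biophysical membrane dynamics — bounds what passing tests show: they
validate the analysis chain against its own statistical assumptions, not
against all failure modes of real recordings.

## Problem sizes and numerical choices

Validation workloads are sized for a desk-scale single-CPU run: the
effect-recovery experiments run 200 replicates at the spike-train level
(ground-truth trains straight into bursts → rate table → statistics) with
scale 0.1 (60 s baselines), since detection fidelity is established
separately — waveform-level replicates at full scale would add nothing
but rendering time; detection recall/precision uses 20 recordings of
10 s at 25 kHz with 60 channels and 9σ amplitudes; the empty-channel
control uses 100 recordings of 5 s with 30 channels; ANOVA type-I
calibration uses 2000 null simulations (n = 20, k = 4, correlated
lognormal).  Sub-seeds always derive deterministically from one root
seed.  Note that common-median referencing needs tens of channels to be
benign: with very few channels the median tracks each channel enough to
deform the residual distribution and bias the MAD noise estimate low,
which is why detection fixtures use ≥30 channels.

## Known limitations

* The sorter is per-channel PCA + k-means with K ≤ 3; it is not a
  general-purpose sorter and will not resolve more than three units per
  electrode or drifting templates.
* The published curation sentence reads, literally, as accepting units
  with *high* ISI-violation rates; we adopt the standard direction
  (accept low violation, high SNR) and expose both thresholds.
* Pooling units across runs treats correlated units as independent
  subjects; a mixed-effects reanalysis is out of scope.
* The ramp g-profiles are nominal schedule entries, not reconstructed
  from telemetry; an optional threshold-crossing helper
  (`segment_g_trace`) exists for sanity checks only.
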