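# Methods

This note documents the models, estimators and numerical choices behind
`respgamma`, and what the synthetic sessions do and do not emulate.

## Signal model of the synthetic session

The generator (`respgamma.synth`) produces one recording as:

**Respiration.** Cycle rates are drawn per cycle from N(2.5, 0.5²) Hz
(truncated at 3 SD; configuration rejects sd ≥ mean). Each cycle is a
negative half-sine inhalation occupying 40% of the period followed by a
smaller (0.6×) positive exhalation lobe, plus white sensor noise
(sd 0.05 in units of the unit-amplitude waveform). Inhalation onsets are
the cycle starts and are returned as ground truth. Negative airflow =
inhalation, matching the mass-airflow-sensor convention.

**LFP.** Each channel is the sum of

* pink noise, spectrally shaped with power ∝ 1/f (exponent 1), rms 1
  (arbitrary µV scale) — the whitening step's target;
* a respiration-coherent slow wave: the noise-free airflow waveform × 1.5;
* an **evoked beta transient**: 15 Hz carrier with *fixed* phase relative
  to inhalation, Gaussian envelope at latency 100 ms (sd 30 ms),
  amplitude 1.5 (×1.5 during odor cycles);
* an **induced low-gamma burst**: 40 Hz carrier whose phase is drawn
  independently every cycle (wrapped normal, sd 2π ≈ uniform), amplitude
  2.0, Gaussian envelope peaking 200 ms after inhalation with rise sd
  50 ms. Odors prolong the burst by widening only the **decay** sd
  (×2 by default): duration, not amplitude or onset, grows with odor.
  The envelope is truncated at cycle boundaries (inhibition resets with
  each afferent volley), so no odor information precedes the burst.
* Channels at or beyond the reversal channel (default 4 of 8, 50 µm
  spacing) carry the gamma component sign-inverted — a hard laminar
  phase reversal; a smooth linear taper is available for CSD tests.

**Spike trains** are drawn by thinning an inhomogeneous Poisson process
(exact and fully seeded). Baseline rates are log-normal around 1.5 Hz
(EXC), 3 Hz (FBI), 4 Hz (FFI). EXC and FFI carry heterogeneous early-
cycle excitation: a per-cell Gaussian bump at a random latency in
30–90 ms (sd 30 ms) with random depth 0.5–2 — heterogeneity matters,
because a shared early mode would otherwise dominate the population
covariance and the assembly extraction. FBI rate is 1 + 4×envelope
(the feedback population *is* the gamma generator's rate readout).

**Odor trials and the winner-take-all structure.** Odors (6, one second,
every 10 s) tag all inhalations within 1 s of onset. During an odor
cycle a principal cell's rate is multiplied by envelope-gated factors:

* every cell receives a *nonspecific afferent drive* `1 + 2·e(t)`;
* that odor's 10 winners (disjoint sets by default) additionally receive
  `winner_gain × g` with `winner_gain = 8` and a per-cycle shared
  log-normal activation `g` (sd 0.4), each winner participating with
  probability 0.85 — assemblies activate as a unit but not identically
  every sniff;
* non-winners are multiplied by `1 − s·e(t)` with `s = 0.85` (jittered
  ±25% per cell and cycle), which *crushes the nonspecific drive*; their
  residual burst spikes are von Mises phase-locked (κ = 2) to the gamma
  carrier. Odorless cycles get a milder suppression (half depth,
  random per cycle).

This realizes the circuit account the analyses are designed to expose:
in control sessions the winners are the dominant coherent mode (skewed
IC weights, orthogonal assemblies, high gamma-window decoding, losers
dipping below baseline exactly when the envelope peaks); without the
suppression the broad nonspecific drive survives as a mode shared across
cells *and odors*.

**Ablation (TeLC-like).** `ablate_recurrence` scales the gamma amplitude
×0.2, reduces loser suppression to 0.1, removes the FBI–envelope
coupling, and scales the winner gain ×0.35. The last item is a modeling
commitment: the winners' extra drive is recurrent amplification carried
by the same principal-cell output synapses the toxin blocks; without it
an ablated session would keep fully skewed, odor-specific weights, which
is not what losing the recurrent loop means. Ablation is idempotent.

**What the generator does not emulate.** Spike waveforms and sorting
artifacts; 1/f knee structure or line noise; respiratory-rate state
changes (sniffing bouts, anesthesia); odor-concentration effects; overlap
between assemblies (configurable but off by default); gamma frequency
drift within a burst; volume conduction. Passing tests therefore show
that the estimators recover the planted structure under the stated
statistical assumptions — not that real recordings satisfy those
assumptions.

## Estimators and numerical choices

**Filtering.** Band filters are least-squares FIR (`scipy.signal.firls`)
applied forward and backward (zero phase). The order is
`max(3·round(fs/lo), fs/(hi−lo), fs/(0.15·lo))`, capped at a third of
the signal length and at 12,000 taps (the LS design solves a dense
(order/2)² system). The passband is weighted 20× in the fit and the taps
are normalized so the *two-pass* mean passband gain is 1; residual
passband error is under ~1.5%. The first/last `numtaps` samples are
flagged edge-contaminated and excluded from all coupling and spike-phase
estimates. Phase/amplitude come from the Hilbert analytic signal with a
cosine convention (phase 0 at the band-signal peak).

**Modulation index.** 18 equal phase bins on (−π, π]; mean amplitude per
bin, normalized to a distribution; `MI = (Hmax − H)/Hmax` with natural
logs, clamped to [0, 1] against roundoff. An empty phase bin raises by
default; `empty_bin="smooth"` Laplace-smooths with ε = 1e-12 (used for
session-level summaries where slow-band phase coverage can be uneven).
Comodulogram grids: phase bands 1 Hz wide centered 1–8 Hz, amplitude
bands 10 Hz wide centered 20–130 Hz. Significance uses circular
time-shifts of the amplitude series (≥1 s, 200 by default); for
grid-wide nulls the surrogate statistic is the grid *maximum* MI, which
controls the family-wise error over the 96 cells.

**Respiration phase convention.** For respiration-phase analyses a
helper rotates the phase axis so the circular-mean phase at inhalation
onsets maps to 0°.

**Directionality.** Envelope and respiration are z-scored and decimated
to 200 Hz before the VAR (10 lags then span 50 ms rather than 5 ms; the
rate is configurable). Granger magnitude is log of the restricted-vs-
unrestricted ssr F statistic, each direction fitted separately.
Near-identical inputs raise (singular regression).

**CSD.** Triggers are local maxima of the 30–50 Hz reference-channel
envelope above its 90th percentile with a 50 ms refractory; ±50 ms
epochs are averaged per channel and the CSD is −A + 2B − C with NaN at
the outermost channels (no boundary assumption).

**Induced/evoked/ITC.** The whole trace is filtered once and per-trial
windows are cut afterwards, so trial edges are clean. Induced = mean of
per-trial envelopes; evoked = envelope of the mean filtered trial; ITC =
per-timepoint magnitude of the mean unit phasor across trials.

**Opto-tagging.** Per-epoch laser spike counts against equal-duration
immediately-preceding baselines, two-sided rank-sum, p < 0.001 → VGAT⁺;
VGAT⁺ units above the session's layer-boundary depth (metadata; the
generator plants it) are FFI, the rest FBI.

**Specificity index.** 100 ms windows sliding at 37.5 ms (62.5%
overlap); windows with zero summed rate are flagged undefined and
excluded from the population mean with a count.

**Assemblies.** Rates (10 ms Gaussian kernel) inside all 1000 ms
post-inhalation windows of one odor are concatenated and *centered* (not
variance-normalized — weights keep the cells' absolute Hz scale, as when
ICA runs directly on smoothed spiking) before a single FastICA component
is extracted (seeded, 500 iterations, 3-seed retry on non-convergence).
The component sign is fixed so the weight skewness (uncorrected
standardized third moment) is ≥ 0; winners > 95th percentile, losers <
mean weight. Cross-odor similarity is parametric Pearson with Bonferroni
over the 15 pairs. Multi-component mode returns the most-skewed of k
components and reduces to the k = 1 path. In ablation comparisons all
cells are used (no opto labels) with thresholds identical to control.

**Decoding.** Features are per-trial mean rates per window; the SGD-SVM
(hinge, L2, α = 1e-4) and kNN (k = 5) run behind a standard scaler, LDA
with default SVD solver and no shrinkage. Splits are stratified random
2/3–1/3, re-drawn up to 10 times if a class is missing, with per-repeat
seeds spawned from one seed sequence (bit-for-bit reproducible).

**Phase-resolved decoding.** Spikes inside the 100–350 ms post-
inhalation window are pooled by the gamma phase *of the spike* (the
phase-of-window alternative is noted but not implemented) into 8 bins
(empty bins merge into a neighbour with a warning). Trials are split
round-robin per odor into 4 balanced blocks (pseudo-sessions); decoding
runs once per (block, bin). The real MI is the entropy MI of the
block-averaged accuracy profile; each of the 10,000 surrogates rotates
every block's profile by an independent random integer number of bins
before averaging — the profile-level realization of circularly shifting
each session's gamma phases, chosen because a single constant shift of
one session's phases only rotates its own profile and leaves the MI of
that profile unchanged.

## Problem sizes

The packaged analyses run on one CPU with: a 120 s spontaneous session
(8 channels, 200 EXC + 10 FBI + 5 FFI, ~290 breathing cycles), 600 s
odor sessions (~135 odor-tagged inhalations, ~22 per odor), and 420 s
sessions for the phase-resolved analyses; rate matrices are sampled at
200 Hz. These sizes give comfortable margins on every recovery property
while keeping a full pipeline run in the low minutes.

## Known limitations

* The inhalation detector (25 ms moving average, downward zero-crossing
  back-dated from a −0.1 SD threshold crossing, 100 ms refractory) is a
  convention; airflow sensors differ and the polarity flag only covers
  sign flips.
* Granger causality here is time-domain and bivariate only; spectral or
  conditional variants are out of scope.
* The comodulogram's 1 Hz phase bands sit below the capped FIR's nominal
  resolution at 2 kHz; phase estimates are fine, but per-band amplitude
  is not calibrated there.
* FastICA with one component reduces essentially to the leading
  whitened direction; with weak planted structure the extracted weights
  are noise-dominated and the winner set is unstable (this is what the
  ablated condition exploits, but it also bounds sensitivity).
* Decoding accuracies depend on classifier regularization defaults; only
  the qualitative contrasts (window ordering, control vs ablated) are
  stable targets.
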