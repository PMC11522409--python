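# Methods

This note documents the models, parameter choices and numerical conventions
behind `meacircuit`, and what the synthetic-data experiments do and do not
demonstrate about real recordings.

## Conventions

Time is seconds in double precision everywhere; sample indices are 0-based;
every bin is half-open `[t, t + dt)`.  A spike exactly 15 ms after a stimulus
therefore survives the 15 ms blank, and a spike at exactly `k·50 ms` falls in
bin `k`.  Blanked/masked intervals are carried on recordings and spike tables
and excluded from all rate denominators.

## Filtering

Each channel is filtered with a 4th-order Butterworth band-pass
(300–3000 Hz) followed by a second-order IIR notch at 50 Hz, both applied
forward–backward (zero phase).  Band edges are the single-pass −3 dB design
points; the forward–backward pass squares the magnitude response, which is
the common convention and what the pass/stop-band tests assert.  The notch
quality factor is 30 — narrow enough that the 300–3000 Hz band is untouched;
the mains frequency is specified but its bandwidth is an implementation
choice, so the quality factor is exposed in the configuration.  Edge
transients are handled by the filter routines' default odd reflection
padding.

## Spike detection (PTSD)

The detector scans for pairs of opposite-sign local extrema separated by at
most the peak lifetime (1 ms) whose peak-to-peak amplitude reaches `k` noise
SDs; the spike time is the larger-magnitude extremum and a 1.6 ms refractory
follows each accepted spike.  Both polarities are admitted.  Design points:

- **Noise SD** defaults to the MAD estimate (median absolute deviation /
  0.6745): spikes inflate a global SD, and the threshold should track the
  noise floor, not the signal.  A plain global SD remains selectable.
- **Extrema** are found by 3-point comparison on the filtered trace;
  a plateau counts once, at its first sample (a deterministic tie-break).
- Events overlapping a masked interval are rejected entirely.
- `k` defaults to 9; 7.5 is the documented choice for lower-SNR adult
  cultures.

Detection recovery (recall/precision ≥ 0.95) is measured against ground
truth whose trains respect the 1.6 ms dead time: a detector with a
refractory period cannot, by construction, recover spikes closer than that,
so recovery experiments thin the simulated trains to a 2 ms minimum
separation before rendering.

## Bursts and network bursts

The logISI threshold is derived from the histogram of log₁₀(ISI) (10 bins
per decade, 3-bin moving-average smoothing): the intra-burst peak is the
largest mode below the 100 ms cap, and the threshold is the void minimum
between it and a later mode with void parameter
`1 − h(min)/√(h(p₁)h(p₂)) ≥ 0.7`, capped at 100 ms, with the cap as fallback
when no valid structure exists.  Bursts are maximal runs of ≥ 4 consecutive
spikes with ISI ≤ threshold (boundary inclusive).

**Void selection.** When the histogram has more than two modes the choice of
void matters.  Per electrode the *first* qualifying void after the
intra-burst peak is used (the published single-electrode behavior).  For
network bursts the same machinery runs on the pooled burst onsets of all
electrodes (logIBEI), where the interval histogram has an extra intermediate
mode created by internodal conduction delays (~20 ms per tunnel hop); there
the *last* qualifying void — the one bordering the slowest,
between-event mode — is used so that a network burst traversing several
nodes is not fragmented at the hop-delay timescale.  Both choices remain
capped at 100 ms.

An electrode is **active** at ≥ 0.1 Hz over unmasked time (the definition is
not fixed by the underlying analysis and is configurable).  A pooled-onset
group becomes a network burst when it contains at least
`ceil(0.10 × n_active)` distinct bursting electrodes — the 10% rule is
inclusive, so 5 of 50 qualifies.

**Propagation.**  Each network burst gets per-node onsets (tunnel electrodes
excluded), an initiation node (earliest onset; exact ties resolve to the
upstream node and are flagged), a span (length of the chain of consecutive
downstream nodes with strictly increasing onsets, no skipping), and a
feedforward flag (initiated in C, span 4).  The node onset is the earliest
participating burst start *after leading-outlier rejection*: a start more
than 10 ms ahead of the node's next start is discarded.  The rejection is
needed because the maximal-run definition legitimately glues an isolated
tonic spike to the front of a burst whenever it happens to fall within the
ISI threshold, pulling that electrode's start tens of milliseconds early;
with ~10 bursting electrodes per node such contamination scrambles the node
order in a substantial fraction of events, while the order statistics of
genuine onsets (a few ms of within-node spread) are far below the 10 ms gap.

## Synchrony and stimulation responses

The coherence index is `CI = sd(r)/mean(r)` over the binned network firing
rate, with the sample (n−1) SD — on the toy case of one occupied bin among M
this gives exactly √M, which the tests pin down because the √M vs √(M−1)
convention differs between implementations.  The bin width (50 ms, shared
with the correlation binning) is not derivable from the underlying analysis
and is configurable; CI is scale-invariant, so the *trend* across
development or perturbation, not its absolute value, is the meaningful
quantity.

Stimulation recordings are cleaned with SALPA before blanking: within a
post-stimulus epoch (50 ms default) a sliding cubic estimate of the slow
artifact (Savitzky–Golay, 151-sample window at 25 kHz) is subtracted;
with a configured noise band the subtraction stops at the first point where
the estimate stays in-band for a full window ("fit-and-test"), and samples
pegged at the rails are interpolated for the fit, zeroed and masked.  This
is a deliberate simplification of the full adaptive-variance SALPA — here
the filter only needs to clean short post-stimulus epochs that are followed
by a hard 15 ms blank.  A cubic artifact is nulled to numerical precision by
construction.  PSTHs pool spike counts per node in 20 ms bins over the
300 ms after each stimulus (the protocol is 60 stimuli at 5 s intervals) and
report mean and SD across trials; the count-conservation invariant (mean
summed over bins × trials = retained spikes) is tested.

## Connectivity and graphs

Spike trains are binned to 50 ms counts and compared by
`r(l) = Σ x_t y_{t+l} / √(Σx² Σy²)` over lags |l| ≤ 10 bins, taking the
maximum (ties: smallest |l|, then the negative lag).  There is **no mean
subtraction** — the normalization makes autocorrelations 1 at zero lag, and
a consequence is a positive floor for independent trains: for Poisson counts
with mean λ per bin the expected coefficient is λ/(λ+1) (≈ 1/3 at 10 Hz
pooled and 50 ms bins), which the tests measure rather than hide.
Intranodal connectivity averages all within-node pairs; internodal
connectivity correlates the nodes' summed trains, which suppresses the
dependence on how many electrodes happen to be active per node.  Tunnel
electrodes appear in the electrode-level matrix and graphs but never in the
node aggregates.

Graphs keep edges with coefficient ≥ 0.1 ("weaker than 0.1" removed, so an
exactly-0.1 edge survives).  Louvain community detection runs 100 seeded
restarts, keeping the best weighted modularity Q; community ids are
renumbered by smallest member so a fixed seed reproduces results
bit-for-bit.  Whether the metrics run on the thresholded or the full
weighted graph is a configuration switch (`graph_on_thresholded`, default
true, matching the plotted graphs).  Pagerank is weighted, damping 0.85.

## Particle quantification

Images are min–max rescaled to 8-bit; the Kapur maximum-entropy threshold
maximizes the summed Shannon entropies of the background and foreground
intensity distributions; the binary mask is watershed-split on the negated
Euclidean distance transform seeded at local maxima ≥ 3 px apart (the
original tool's seedless binary watershed, made deterministic), and
connected regions are measured.  Particles are retained when the equivalent
circular diameter `2√(area/π)` exceeds 5 µm at 2803/2046 ≈ 1.3700 µm/px;
an area-based cut is available since the "above 5 µm" reading is ambiguous.

**Limitation.**  Maximum-entropy thresholding assumes the image contains a
meaningful foreground class.  On a noisy, essentially blank image (a few
foreground pixels) the entropy criterion can prefer splitting the noise
distribution itself, flooding the mask; measured failure rate on
near-blank disk phantoms is ~1%.  Real quantification images contain
stained tissue, and the phantom experiments mirror that by always including
at least one supra-threshold aggregate; blank-field images should be
excluded upstream, as they would be in an ImageJ workflow.

## Statistics

The exact two-sided Wilcoxon rank-sum p is
`P(|W − E[W]| ≥ |w − E[W]|)` under uniform sampling of all
`C(n_a+n_b, n_a)` rank assignments, computed by a subset-sum count (no
explicit enumeration).  It is used whenever both samples have ≤ 10 values
and the pooled data is tie-free; otherwise midranks with the tie-corrected,
continuity-corrected normal approximation are used and flagged.  With
n = 4 vs 4 the attainable two-sided p-values form a fixed finite set with
minimum 2/70 ≈ 0.0286 — complete separation.  Mixed-model (GLMM) analyses
of longitudinal designs (gamma family, log link, sequential Bonferroni) are
out of scope by design: `group_summary`/tidy metric tables feed directly
into statsmodels or R `lme4`/`glmmTMB`.

## The synthetic generator

`simulate_spike_trains` draws network-burst initiations as a Poisson process
per node (default 15/min/node, so a 15-minute recording holds on the order
of 10³ network bursts, matching mature cultures of this kind); an event in
node *i* reaches node *i+1* with probability `p_tx` (default 0.8) after a
truncated-Gaussian delay (mean 20 ms, SD 5 ms, floor 1 ms — the floor keeps
node order well-defined at small jitter).  Within a reached node each
electrode joins with probability 0.8, its burst start offset by a
half-normal 2 ms jitter, and fires `4 + Poisson(6)` spikes with exponential
ISIs (mean 10 ms).  Independent 0.5 Hz tonic Poisson spiking is superposed.
The amyloid-beta perturbation mode multiplies the initiating-node rate by
1.5 and `p_tx` by 0.7 — the two reported effects — and nothing else, so any
synchrony or connectivity change downstream is emergent, not injected.
Burst-shape statistics are not quantitatively constrained by any published
values and every parameter is configurable.

Raw rendering places a biphasic template at each spike time on white
Gaussian noise at 25 kHz.  The template is two half-sine lobes (negative
first, repolarization lobe at 0.45 amplitude, 0.6 ms trough-to-peak): the
dominant trough defines the spike time, as for perisomatic extracellular
waveforms.  Stimulation artifacts are exponential transients added across
all channels.

**What passing tests show — and don't.**  The generator reproduces the
statistical structure the pipeline assumes (Poisson event timing, Bernoulli
hops, exponential intra-burst ISIs, Gaussian noise, ideal template shapes).
It does not model bursty waveform variability, electrode drift, correlated
noise, multi-unit superposition, plasticity, or astrocytic modulation.
Recovery results (e.g. PTSD recall ≥ 0.95 at 12σ spikes, span-4 fractions
within binomial error of p_tx³) therefore validate the *implementation* of
each method under its own assumptions, not its performance on arbitrary
biological recordings.

## Problem sizes

The packaged experiments use 60 s 59-channel renderings for detection
recovery, ~25-minute spike-table simulations (≈ 500 C-initiated events) for
propagation recovery, 20 × 5 jittered 60 s simulations for the synchrony
trend, 40-electrode planted-partition graphs for community recovery, and
50 disk phantoms of 200×200 px — sizes chosen so the statistical targets
(binomial intervals at n ≈ 500, exact counts) are meaningful while the
whole suite stays desk-scale.
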