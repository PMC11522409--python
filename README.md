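# meacircuit

Analysis pipeline for multielectrode-array (MEA) recordings of engineered
**multinodal feedforward neural circuits** — four culture chambers (a cortical
node `C` feeding hippocampal nodes `H1 → H2 → H3` through unidirectional
microtunnels) recorded at 25 kHz, with electrodes in the chambers and in the
tunnels.  It is written for electrophysiologists and systems-biology groups
who grow such circuits on MEAs and need a tested, scriptable desk-side
analysis: from raw voltage traces (or pre-detected spike tables) to burst
statistics, network-burst propagation, synchrony, functional-connectivity
graphs, stimulation responses, and quantification of amyloid-beta aggregates
in accompanying micrographs.  A seeded synthetic-data generator with full
ground truth makes every stage verifiable without laboratory data.

## What it computes

- **Filtering** — zero-phase 4th-order Butterworth band-pass (300–3000 Hz)
  plus a 50 Hz mains notch.
- **Spike detection (PTSD)** — precise timing spike detection: paired
  opposite-sign extrema within a 1 ms peak lifetime whose peak-to-peak
  amplitude reaches *k*·σ (k = 9 embryonic, 7.5 adult; σ from the MAD),
  1.6 ms refractory.
- **Bursts (logISI)** — the ISI threshold is the void minimum of the
  log₁₀(ISI) histogram (void ≥ 0.7), capped at 100 ms; bursts are maximal
  runs of ≥ 4 spikes with ISI ≤ threshold.
- **Network bursts (logIBEI)** — the same histogram machinery on pooled burst
  onsets; a group qualifies when ≥ 10% of active (≥ 0.1 Hz) electrodes burst.
- **Propagation** — per-node onsets order each network burst into an
  initiation node and a *span* (consecutive downstream nodes reached with
  strictly increasing onsets); *feedforward* = initiated in C with span 4.
- **Synchrony** — coherence index CI = SD/mean of the binned population
  firing rate.
- **Connectivity** — 50 ms binned spike trains, maximum normalized
  cross-correlation over lags ≤ 10 bins (±500 ms), `r(l) = Σ x_t y_{t+l} /
  √(Σx²Σy²)` (autocorrelation = 1 at lag 0, no mean subtraction); intranodal =
  mean pairwise within a node, internodal = correlation of summed node trains.
- **Graphs** — electrodes as vertices, correlations ≥ 0.1 as weighted edges;
  Louvain communities with maximized modularity Q = Σᵢ(eᵢᵢ − aᵢ²); weighted
  pagerank.
- **Stimulation** — SALPA (local cubic fit-and-subtract) artifact suppression,
  15 ms post-stimulus blanking, per-node PSTHs in 20 ms bins over 300 ms.
- **Particle quantification** — 8-bit conversion, Kapur maximum-entropy
  threshold, distance-transform watershed, and the > 5 µm
  equivalent-diameter cut at 2803/2046 µm per pixel.
- **Statistics** — exact two-sided Wilcoxon rank-sum (full enumeration of the
  null rank distribution) and tidy per-DIV/per-condition summaries.

## Worked example

Simulate a four-node circuit for 5 minutes (network-burst events initiate in
every node at 8/min and hop downstream with probability 0.4 per tunnel
crossing), then run the full pipeline:

```python
import meacircuit as mc

cfg = mc.NetworkSimConfig(nb_rate=8.0, p_tx=0.4, seed=42)
table, truth = mc.simulate_spike_trains(cfg, 300.0)
bundle = mc.run_pipeline(table, mc.AnalysisConfig(seed=42))
r = bundle.results
print(r["firing"]["n_spikes"])                              # 23221
print(r["bursts"]["n_bursts"])                              # 1640
print(r["network_bursts"]["n_network_bursts"])              # 148
print(round(r["dynamics"]["coherence_index"], 2))           # 3.0
print(round(r["graph"]["modularity"], 3))                   # 0.324
```

The 148 network bursts are classified by initiation node and span;
`r["propagation"]["percent_feedforward"]` (here 1.4%) is the share initiated
in C that traverses all four nodes — with three independent tunnel hops this
tracks p_tx³ (0.064 here; the ground truth for this run is 0.044).  The
coherence index 3.0 says the population rate is dominated by sparse
synchronized bursts (a steady population would give 0).  Modularity 0.324
with communities aligned to the chambers means the circuit is functionally
segregated despite the feedforward coupling; driving `p_tx` up merges the
communities and drives Q toward 0.

The same stages are available from the shell:

```bash
meacircuit simulate --seed 42 --duration 300 --out sim/
meacircuit run --spikes-csv sim/spikes.csv --duration 300 \
    --electrode-map map.csv --seed 42 --out bundle.json
```

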