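# meaburst

Network-burst propagation-pattern analysis for micro-electrode array
(MEA) recordings of cultured cortical networks.

Mature dissociated cortical cultures on planar MEAs (here the standard
8×8 grid, 60 electrodes, 200 µm pitch) express spontaneous *network
bursts* (NBs): array-wide barrages of single-channel bursts. A small
set of *major leader* (ML) electrodes reliably fires first, and the
subsequent recruitment of the other electrodes follows a few recurring
spatiotemporal templates. `meaburst` implements the full analysis chain
that quantifies this organization and asks whether electrically evoked
responses reproduce the endogenous propagation patterns:

- **Burst detection (logISI).** Per channel, the histogram of
  log₁₀ inter-spike intervals is typically bimodal; the burst threshold
  is the deepest valley between the intra-burst peak (< 100 ms) and the
  inter-burst peak, accepted when the void parameter
  `1 − h_min/√(h_peak1·h_peak2)` reaches 0.7.
- **Network bursts and leadership.** Single-channel bursts are chained
  into NBs when they involve ≥ 20 % of the active channels
  (firing rate > 0.1 spikes/s). Each NB stores its activation rank
  order and per-electrode delays from the first-firing electrode (the
  leader). The leadership score LS(e) is the percentage of NBs led by
  electrode *e*; electrodes with LS ≥ 4 % are major leaders.
- **Stimulus–response analysis.** Post-stimulus time histograms
  (500 ms window, 2 ms bins) summarize responses to 0.2 Hz test pulses.
  The network PSTH is smoothed (20 ms moving average) and the early
  (direct, < ~35 ms) and late (network-burst) components are separated
  at the valley x_min between the first peak (≤ 50 ms) and the late
  peak, accepted when the separation index

      s_j = 1 − PSTH_j(x_min) / √(PSTH_j(x_peak1) · PSTH_j(x_peak2))

  reaches 0.3. Evoked NB patterns are extracted from the late window
  only, with delays referenced to the stimulus.
- **Pattern similarity.** Activation orders are compared by Levenshtein
  edit distance, normalized by a permutation null: both sequences are
  shuffled 200 times and the normalized distance is the fraction of
  null distances strictly below the observed one (an empirical
  p-value); pairs with p < 0.05 are significantly similar.
- **Clustering and evaluation.** Pattern clusters are found by greedy
  core extraction plus significance-gated template matching; similarity
  between groups is the ratio of significantly similar pairs, with
  shuffle controls for chance level, and each stimulated channel is
  classed *similar to spontaneous* when its best spontaneous-cluster
  cross ratio exceeds 10 %.

A fully seeded synthetic-data generator plants leaders, propagation
templates, and early/late response structure with exported ground
truth, so the entire chain runs and is validated without any external
recordings.

## Worked example

```python
import meaburst as mb
from meaburst.pipeline import run_pipeline

layout = mb.mcs_8x8()
cfg = mb.AnalysisConfig(n_shuffles=60, shuffle_control_repeats=10, rng_seed=7)

templates = mb.generate_templates(layout, k=3, seed=7)
spont, gt = mb.simulate_spontaneous(templates, layout,
                                    duration_ms=300_000,
                                    nb_rate_per_min=15, seed=7)
stim_e = sorted(layout.neighbors(list(templates[0].leader_pool)[0]))[0]
stim, log, _ = mb.simulate_stimulated_session(
    templates, layout, stim_e, n_pulses=30, response_prob=0.9,
    base_rates=gt.base_rates, seed=8)

report = run_pipeline(cfg, spont, stim, log, layout=layout, out_dir="out")
ev = report["evaluation"]
print(f"same-ML ratio      {ev['same_ml_ratio']:.3f}")
print(f"different-ML ratio {ev['diff_ml_ratio']:.3f}")
for e, v in ev["per_stim"].items():
    s = v["similarity"]
    print(f"stim {e}: max cross ratio {s.max_ratio:.3f} -> {s.classification}")
```

Output (seed 7):

```
same-ML ratio      0.998
different-ML ratio 0.180
stim 16: max cross ratio 0.997 -> similar_to_spontaneous
```

NBs led by the same planted leader share their propagation pattern
almost always (ratio ≈ 1), different leaders' patterns sit near the
chance level of the permutation test, and stimulating next to a planted
leader evokes patterns overwhelmingly similar to that leader's
endogenous cluster — the qualitative signature the analysis is built to
detect. `out/` contains the leadership table, NB list, distance
matrices (CSV), cluster assignments, early/late splits and the
evaluation summary (JSON).

The same chain is available from the shell:

```bash
meaburst simulate --out-dir data --seed 7 --k-templates 3
meaburst run-all --spont data/spontaneous_events.csv \
    --stim data/stimulated_events.csv --log data/stimulation_log.csv \
    --seed 7 --out-dir out
```

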