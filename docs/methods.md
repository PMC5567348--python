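# Methods

This note documents the models, parameter choices and numerical
decisions behind `meaburst`, and what the synthetic-data validation
does and does not establish.

## Data model

All times are milliseconds from recording start, as floats on a 0.1 ms
grid (10 kHz acquisition). Electrode labels follow the two-digit
column–row convention of the standard 60-electrode MEA (8×8 grid minus
corners, 200 µm pitch); the grid position of an electrode is derived
from its label, which makes geometric distances computable without
extra metadata. One electrode (default "15") is the internal reference,
leaving 59 recording sites. Canonical on-disk formats are CSV event
tables (`electrode,time_ms`) and stimulation logs
(`electrode,onset_ms`); an HDF5 container with one time vector per
electrode is accepted as an alternative input.

## Burst and network-burst detection

Single-channel bursts are detected with the logISI method: the
histogram of log₁₀(ISI) on a fixed grid (10 bins/decade, 3-bin moving
average) is searched for the largest peak below 100 ms (intra-burst
mode). Walking outward from it, the valley to each subsequent peak is
evaluated and the first whose void parameter
`1 − h_min/√(h_peak1·h_peak2)` reaches 0.7 gives the ISI threshold;
peaks need a prominence of 5 % of the histogram maximum, which keeps
near-empty tail bins from posing as modes. Channels without an
acceptable valley fall back to 100 ms. The threshold actually used for
burst detection is additionally capped at 100 ms
(`max_isi_threshold_ms`): intra-burst intervals are short, and an
uncapped valley on a high-rate channel can chain background spikes into
recording-long "bursts" that bridge separate network events. Bursts are
maximal runs of ≥ 3 spikes with consecutive ISIs at or below the
threshold.

Network bursts chain single-channel bursts that overlap or follow
within 100 ms (`nb_chain_gap_ms`; "quasi-synchronous" is not otherwise
quantified, so this is an exposed sensitivity parameter). A chain is an
NB when it involves at least `ceil(0.20 × active channels)` distinct
channels, with the active set defined by firing rate strictly above
0.1 spikes/s. A channel's activation time is the first spike of its
burst within the chain; channels spiking without bursting are not part
of the pattern. Ties in activation time (possible on the 0.1 ms grid)
are broken lexicographically by label and flagged. The leadership score
is the percentage of NBs led; the major-leader cutoff (4 %) is
inclusive.

## Stimulus–response analysis

PSTHs use a 500 ms window with 2 ms bins; the area (mean spikes per
stimulus) equals the total in-window count divided by the trial count,
exactly. Channels with area below 1 are non-responding. Two
normalizations are provided: per recording channel across stimulation
sites (comparing stimulation from MLs vs followers) and per stimulation
site across channels (comparing responses of MLs vs followers); the
same machinery applies to first-spike latencies.

The early/late separation smooths the network PSTH (sum over responding
channels) with a centered 10-bin (20 ms) moving average, edges
truncated to the available bins. Peak detection runs on the smoothed
curve padded with a single zero per side — there is no evoked response
outside the window, and without the pad a genuine early peak adjacent
to the window edge loses its prominence. Peaks need a prominence of 5 %
of the curve maximum (`peak_prominence_frac`); when several peaks fall
in one phase the highest is used. The valley is the minimum between the
two phase peaks (first bin on ties), and the split is accepted when the
separation index reaches 0.3. The accepted x_min is applied to all
responding channels of that stimulation site; evoked patterns are then
extracted per trial from the (x_min, 500] ms window by the same
burst/participation rules as spontaneous NBs, with delays referenced to
stimulus onset. Stimulation sites evoking an NB in fewer than half of
the pulses (boundary inclusive) are dropped.

## Pattern distance

The raw distance between two activation orders is the unit-cost
Levenshtein distance (computed with edlib after mapping electrode
labels to a compact symbol alphabet; a pure-Python dynamic-programming
implementation serves as the independent oracle in the tests). The
normalized distance shuffles *both* sequences independently 200 times
and reports the fraction of null distances strictly lower than the
observed one. Strictly-lower counting means ties favor similarity; the
consequences are documented under *Limitations*. Null distributions
depend only on the two lengths and the shared-symbol count (an
exchangeability property verified by tests), so they are cached per
profile; the cached null draws 10× the per-pair shuffle count because a
single cached sample serves many pairs and its Monte-Carlo error is
correlated across them. Caching can be disabled
(`cache_nulls=False`) for exact per-pair reproduction; per-pair seeds
are derived from the pair ids so matrix entries are order-independent.
Spontaneous inputs are truncated to the first 2500 NBs in time.

## Clustering

Stage 1 extracts cores greedily: the pattern with the most significant
neighbors (normalized distance < 0.05) seeds a core; a candidate joins
only if it is significantly similar to at least half of the candidate
set (`core_consistency_frac`). This consistency gate is the package's
concrete reading of the loosely specified "slight modifications" to the
published core-finding idea: without it, the tie-inflated chance
significance (see *Limitations*) drags members of other clusters into
every core. Cores need ≥ 5 members (`min_core_size`). Stage 2 assigns
each leftover to the core with the smallest median distance to core
members, if that median is itself significant; the median (rather than
a single centroid) is robust to core outliers and is config-switchable.
Everything else is discarded as unclassified and excluded from
downstream ratios. Per-cluster delay maps report the median delay per
electrode, flagging electrodes present in under half the members.

## Evaluation

Group similarity is the ratio of significantly similar pairs over all
pairs (within-group: unordered pairs without self-pairs). Chance levels
come from shuffle controls that permute each pattern's symbol order and
recompute the target ratio (default 100 repeats); the 95th percentile
is the chance ceiling. Each stimulated channel's evoked patterns are
compared against every spontaneous cluster; the maximum cross ratio
classifies the channel as *similar to spontaneous* (strictly above
10 %) or *different*. Reliability correlation is the Pearson
correlation between that maximum and the mean of the matched clusters'
within-cluster ratios. Major-leader involvement reports, per
(stimulation site, ML): the median relative recruitment order
(normalized rank, 0 = recruited first; switchable to raw rank), the
per-site-normalized early-response PSTH area (bins ≤ x_min), and the
Euclidean electrode distance in µm. Group comparisons pre-check
normality (Kolmogorov–Smirnov at 0.01) and fall back to Mann–Whitney /
Kruskal–Wallis with Bonferroni-corrected pairwise follow-ups.
Multidimensional scaling is the classical (Torgerson) double-centering
eigendecomposition, with Kruskal stress-1 reported.

## Synthetic data

The generator emulates the statistics the analysis assumes rather than
any biophysics:

- **Templates.** k recurring propagation motifs, each spanning 90 % of
  the recording electrodes by default, with distinct leader pools (1–3
  electrodes) and non-leader delays spread over ~[9, 60] ms, kept
  distinct on the 0.1 ms grid. A disjoint-support mode (~10 % shared
  members) exists for negative controls.
- **Spontaneous activity.** NB onsets follow a gamma(2) renewal process
  with a 300 ms refractory floor at the configured rate (default
  19.3 NB/min); each NB instantiates a uniformly chosen template with
  Gaussian delay jitter (default 5 ms) and independent member dropout
  (participation 0.9). Member bursts draw 6–24 spikes with exponential
  10 ms ISIs. Background is per-electrode Poisson with lognormal rates
  (median 0.5 Hz, σ = 1), yielding ~50 active channels and an overall
  mean rate near 4.65 spikes/s — the regime the detector is built for.
  Background is suppressed in a 200 ms window before each NB onset,
  modeling the brief network quiescence that precedes burst ignition in
  cultured networks; without it, stray background spikes attach to
  burst fronts and randomly reassign the measured leader in most
  events, which no detector downstream could undo.
- **Stimulation.** 0.2 Hz pulse trains (default 100 pulses). Each pulse
  responds with configurable probability: early spikes on the
  stimulated electrode's grid neighborhood plus the nearest planted
  leader (latencies U(2, 20) ms, 90 % per-channel reliability), then a
  late NB from the template whose leader pool is geometrically closest
  to the stimulation site (onset U(40, 150) ms).

What passing tests show: the chain recovers exactly what was planted
under realistic noise, and the published decision rules are implemented
at their stated boundaries. What they do not show: performance on real
recordings, whose bursts have richer internal structure (rate
modulation, adaptation, electrode-specific waveform effects) and whose
background is not stationary Poisson.

## Validation problem sizes

The packaged tests run the chain at 10-minute recordings with ~200 NBs,
40 stimulated sessions for threshold recovery, 60-shuffle distance
matrices for clustering recovery, and 3 seeds per end-to-end control;
these sizes give stable pass/fail margins for every property while
keeping the suite fast.

## Limitations

- **Tie behavior of the permutation p-value.** Counting only strictly
  lower null distances makes ties count as evidence of similarity. The
  null of the edit distance between shuffled patterns is concentrated
  on a few integer values, and the observed distance of an *unrelated*
  pair is drawn from essentially the same atoms, so the entire
  probability mass at the lower boundary maps to p ≈ 0. Measured
  chance-level significance for unrelated patterns is ~8–10 % when the
  two patterns share nearly all their symbols, 12–30 % at partial
  overlap, and 100 % in the fully disjoint limit (all null distances
  equal the observed one). Consequently the fixed 10 % threshold for
  "similar to spontaneous" sits at, not above, chance for low-overlap
  comparisons, and a disjoint-support negative control is *not*
  reliably classed "different". The shuffle-control ceiling reported
  alongside every classification is the robust guard; the positive
  controls exceed it by an order of magnitude.
- Leadership identification assumes the pre-burst quiescence present in
  the generator (and typical of real cultures); with heavy stationary
  background at the burst fronts, per-event leader assignment degrades
  gracefully into a noisy vote, and only the ML set (not each event's
  leader) remains recoverable.
- The logISI threshold cap at 100 ms, the 100 ms NB chaining window and
  the min-core size of 5 are exposed configuration, not claims; results
  in the validated regime are insensitive to moderate changes, but
  pathological inputs (e.g. tonic 50 Hz channels) will move bursts
  across the cap.
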