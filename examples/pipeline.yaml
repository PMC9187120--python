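# Two simulated groups (Novice / Expert), full analysis chain.
# Run with: spikesight run --config examples/pipeline.yaml --out results/
seed: 1

simulate:
  novice:
    group: Novice
    seed: 11
    n_units:
      wS1: {RS: 6, FS: 4}
      wM1: {RS: 6, FS: 4}
      ALM: {RS: 5, FS: 3}
      tjM1: {RS: 5, FS: 3}
    trial_counts: {hit: 30, miss: 8, CR: 30, FA: 8}
  expert:
    group: Expert
    seed: 12
    n_units:
      wS1: {RS: 6, FS: 4}
      wM1: {RS: 6, FS: 4}
      ALM: {RS: 5, FS: 3}
      tjM1: {RS: 5, FS: 3}
    trial_counts: {hit: 30, miss: 8, CR: 30, FA: 8}

modulation:
  alpha: 0.025
  n_perm: 2000

latency:
  n_perm: 2000

connectivity:
  pairs: [[wS1, wM1]]
  n_resamples: 100
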