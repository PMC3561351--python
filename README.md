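# psfnet

Phase-synchrony functional brain networks. `psfnet` builds weighted
connectivity networks from regional time series using the time-averaged
phase-synchrony degree (the mean resultant length of the Hilbert-phase
difference), compares them against Pearson-correlation networks, derives
group statistical difference networks via edge-wise one-tailed t-tests,
analyzes community structure (modularity maximization, Q-vs-k curves) and
node roles (within-community degree z-score, inter-community ratio, role
classes T1–T6), and classifies subjects with k-means on the per-subject
modularity statistic. A synthetic coupled-phase-oscillator cohort
generator with a planted "additional network" in the case group makes the
whole pipeline testable end-to-end without external data.

## Layout

| module | purpose |
| --- | --- |
| `psfnet.regions` | bundled 116-region anatomical label table (90 cerebral + 26 cerebellar/vermal) |
| `psfnet.synthcohort` | synthetic two-cohort generator with known phase-coupling ground truth |
| `psfnet.phasesync` | band-pass filter, Hilbert instantaneous phase, PS degree, n:m locking test |
| `psfnet.netbuild` | per-subject PS / Pearson networks, binarization, graph metrics |
| `psfnet.groupdiff` | edge-wise one-tailed t-test difference networks D+ / D- |
| `psfnet.community` | modularity, community detection, node-role analysis |
| `psfnet.classify` | Lloyd k-means and the cluster-to-group accuracy rate |
| `psfnet.experiments` | threshold sweeps: group Q curves, metric curves, classification accuracy |
| `psfnet.cli` | `psfnet` command-line pipeline |

## CLI

Every stage reads and writes plain TSV and logs its parameters, config
hash and seed to `run_log.yaml` in the output directory; re-running with
the same inputs and seed reproduces artifacts byte-for-byte.

```sh
# 1. simulate a cohort (spec fields may come from a YAML config)
psfnet simulate --n-regions 20 --out runs/cohort --n-control 27 --n-case 21 --seed 1

# 2. one weighted functional network per subject (ps or pearson)
psfnet fw --manifest runs/cohort/manifest.tsv --out runs/fw --method ps

# 3. group difference networks D+ / D-
psfnet diffnet --fw-dir runs/fw --out runs/diff --alpha 0.05 --correction bh

# 4. community structure of a difference network, then node roles
psfnet communities --network runs/diff/d_plus.tsv --out runs/comm --seed 1
psfnet roles --network runs/diff/d_plus.tsv --partition runs/comm/partition.tsv --out runs/roles

# threshold sweeps and subject classification
psfnet sweep --manifest runs/cohort/manifest.tsv --out runs/sweep --metric q
psfnet classify --manifest runs/cohort/manifest.tsv --out runs/clf --method ps
```

## Notes

- PS weights lie in [0, 1]; the estimator excludes the first/last 5 % of
  samples (Hilbert end transients) and is amplitude-scale invariant.
- Binarization keeps edges with weight strictly greater than the
  threshold; graph metrics use the Latora–Marchiori zero convention for
  disconnected pairs.
- Community detection is greedy agglomerative merging with seeded
  restarts and Kernighan–Lin-style local refinement; it records the best
  Q at every candidate community count. An exhaustive-search oracle
  (`community.exhaustive_max_modularity`, n ≤ 10) backs the tests.
- All randomness flows from explicit integer seeds.
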