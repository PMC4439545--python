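# spikeinfer

Estimate two coupling parameters of a small neuronal network — an
inhibitory conductance `g_i` and a gap-junctional conductance `g_c` — from
spike-train data alone, by simulation-based hierarchical Bayesian
inference.

The pipeline:

1. **Simulate** a surrogate 3×3 coupled-neuron network over a discrete
   `(g_i, g_c)` grid (default 31×41 cells, step 0.05 over
   [0, 1.5] × [0, 2.0] mS/cm²).
2. **Describe** each 50-s spike segment by a 68-component feature vector:
   firing rate, local variation, 20 autocorrelogram bins, 20
   crosscorrelogram bins, a 25-bin minimal-distance histogram, and the
   adaptive spike-train dissimilarity (all implemented natively).
3. **Compress** the features: mutual-information ranking selects the top 25,
   which are standardized and projected onto 3 principal components.
4. **Fit a forward model**: one variational-Bayes Gaussian mixture per grid
   cell over the 3-D scores (goodness of fit checked by the two-sample
   energy test with permutation p-values).
5. **Invert**: given a control recording paired with a pharmacological one
   (PIX blocks `g_i`, CBX blocks `g_c`), a delta-function commonality prior
   ties the unblocked parameter across conditions, and a hierarchical prior
   lets per-segment parameters jitter around neuron-level values with
   variances (σ1, σ2, σ3) chosen by exhaustive evidence maximization.
   A non-segmental Bayesian estimator and a minimum-score-error baseline
   are provided for comparison; with all σ fixed to zero the segmental
   estimator reduces bit-exactly to the non-segmental one.

## CLI

A single entry point with subcommands:

```sh
spikeinfer simulate out.csv --gi 0.5 --gc 1.0 --duration 200 --seed 1
spikeinfer spikes validate out.csv
spikeinfer features out.csv --out features.csv
spikeinfer fixture fx/ --gi 0.5 --gc 1.0 --pha-label PIX --seed 1
spikeinfer forward fit config.yaml --out model.json
spikeinfer estimate --forward-model model.json --con con.csv --pha pha.csv \
    --pha-label PIX --method segmental
spikeinfer pipeline config.yaml     # simulate -> features -> model -> estimate
```

Spike files are plain CSV with commented headers
(`# duration_s=…`, `# condition=…`, `# neurons=…`, then
`neuron_id,time_s` rows) at a fixed 0.1-ms time resolution; forward models
are JSON bundles containing the grid, the per-cell mixtures and the fitted
feature transform; pipeline runs write a manifest with seeds, wall times
and checksums.

## Layout

```
src/spikeinfer/
  spike_data.py     spike-train types, CSV I/O, segmentation, binning
  surrogate_sim.py  parameter grid + surrogate network simulator (numba)
  features.py       the 68-component segment feature vector
  feature_space.py  MI ranking, PCA transform, sensitivity maps
  forward_model.py  per-cell VB-GMM likelihoods, energy test, persistence
  inference.py      segmental / non-segmental Bayes, min-error baseline
  fixtures.py       seeded renewal + surrogate fixture generators
  pipeline.py       orchestration, config, manifests
  cli.py            click command-line interface
```

Note on the simulator: the original biophysical network model this method
was developed against is not reproduced here; a documented surrogate
(leaky integrate-and-fire lattice with slow oscillatory drive, inhibitory
and excitatory conductance inputs, and diffusive/spikelet gap coupling)
preserves the qualitative roles of the two parameters — `g_i` controls
single-cell firing, `g_c` controls cross-cell synchrony — so the full
inverse pipeline is exercisable end to end. Absolute conductance estimates
are therefore not comparable to any particular biological preparation.
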