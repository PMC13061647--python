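# latentevo

Closed-loop evolution of images in generator latent spaces, exercised
end-to-end on synthetic generators and synthetic spiking neurons, together
with the downstream analyses used to characterize how well a neuron's tuning
aligns with each latent-image manifold.

## What is in the box

| Module | Contents |
| --- | --- |
| `latentevo.generators` | Two bundled image generators with contrasting priors: a high-dimensional linear Gabor-dictionary ("texture") generator and a low-dimensional parametric blob-scene ("object") generator with separate class/noise latent sub-blocks. Any `GeneratorContract` (deterministic, continuous latent→image map) can be plugged in. |
| `latentevo.neurons` | Synthetic visually tuned spiking neurons with early/late temporal kernels bound to (possibly different) local feature preferences, plus inhomogeneous-Poisson spike simulation on a 1 ms grid over the [−50, 400) ms window. |
| `latentevo.optim` | A from-scratch (mu/mu_w, lambda)-CMA-ES maximizer (ask/tell), with orthonormal-subspace restriction for high-dimensional spaces. |
| `latentevo.evolution` | The paired closed-loop driver: two interleaved optimization threads (one per generator), seeded reference images, per-image scoring by the 50–200 ms mean firing rate. |
| `latentevo.alignment` | Hill-climbing success tests, normalized/padded trajectory averaging, GPR-smoothed 80%-of-increase convergence times, per-generation win rates, pooled success rates with Wilson intervals. |
| `latentevo.psth` | Mass-conserving Gaussian-smoothed PSTHs, normalized difference-PSTH temporal attribution, time-binned evolution trajectories with paired tests and Benjamini–Hochberg correction, absolute/signed PSTH area distances. |
| `latentevo.landscape` | Finite-difference pullback (Riemannian) Hessians of image metrics, class/noise sub-block eigen-axes, distance-matched bisection line search, nine-distance tuning curves with ANOVA gating and bell/ramp classification (linear + Gaussian + GPR fits), population summaries and two-proportion z contrasts. |
| `latentevo.attribution` | Seeded filter-bank local feature extraction, per-location regression attribution masks (adjusted R²), largest-region weight vectors, mask correlations, total variation, perceptual similarity heatmaps with concentration scores, and factorized encoding-model feature exemplars re-optimized through CMA-ES. |
| `latentevo.session_io` / `latentevo.cli` | Checksummed JSON+CSV session serialization and the `latentevo` command-line interface. |

## CLI

```bash
latentevo simulate-neuron --seed 1 --outdir work
latentevo evolve --neuron work/neuron.json --blocks 40 --popsize 30 \
    --seed 1 --outdir work/session
latentevo analyze-alignment work/session --outdir work/alignment
latentevo analyze-psth work/session --bin-ms 10 --outdir work/psth
latentevo hessian-tune --session work/session --outdir work/tuning
latentevo attribute --session work/session --outdir work/attribution
latentevo run-pipeline --config config.json   # chains all of the above
```

Config files are JSON (keys: `seed`, `outdir`, `blocks`, `popsize`,
`trials_per_image`, `n_reference`, `sigma_a`, `sigma_b`, `size`, `alpha`,
`bin_ms`, `axes`, `reps`). Outputs are CSV tables with units columns, JSON
summaries/manifests, and PNG stimuli/figures.

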