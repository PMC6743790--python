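# protdeconv

Deconvolution of multiplexed protease activity signatures.

Proteases are promiscuous: one enzyme cleaves many peptide substrates,
so when a library of activity probes is exposed to a cocktail of
proteases, every probe reports a convolved mixture of activities.
`protdeconv` estimates the individual protease concentrations in such a
mixture from substrate-cleavage kinetics, and answers two experimental
design questions on top of that estimator: *how few substrates suffice*,
and *when should correlated proteases be deconvolved as families rather
than individuals*. It is aimed at groups building substrate-library
assays (fluorogenic or mass-barcoded) who want to size their library
and set expectations for deconvolution accuracy before running
experiments.

## Model and estimator

Fraction-uncleaved substrate `S ∈ [0,1]` under protease concentration
`α` follows a saturating Michaelis–Menten law with a floor `β` at which
cleavage stops:

    dS/dt = −α V (S−β)^n / ((S−β)^n + K^n),   S(0) = 1

For a mixture of N proteases against substrate *i*, the rates add:

    dS_i/dt = −Σ_j α_j V_ij (S_i−β_ij)^n_ij / ((S_i−β_ij)^n_ij + K_ij^n_ij)

The workflow is two nested least-squares problems:

1. **Calibration** — fit `(V, K, n, β)` for every protease–substrate
   pair from single-protease timecourses;
2. **Deconvolution** — given a mixture's M×Q read-out, estimate the
   nonnegative `α` by re-integrating the mixture model inside a
   bound-constrained optimizer.

Accuracy over `P` repeated mixtures is summarised by the per-protease
RMSE `R_j = sqrt(mean_k (α̂_jk − α_jk)²)` and its mean across
proteases. Greedy backward elimination removes, at each round, the
substrate whose loss hurts RMSE least; single-linkage Euclidean
clustering of protease activity signatures (cutoff 0.6) groups
correlated proteases into families that are deconvolved as units.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from protdeconv import (SimConfig, sample_kinetic_matrix,
                        evaluate_panel, greedy_substrate_reduction)

cfg = SimConfig(M=7, N=3, P=20, seed=0)       # 7 substrates, 3 proteases
km = sample_kinetic_matrix(cfg)               # ground-truth kinetics

report = evaluate_panel(km, km.substrates, cfg)
for protease, r in zip(report.ids, report.per_protease):
    print(f"{protease}: RMSE = {r:.4f}")
print(f"overall: {report.overall:.4f}")

trace = greedy_substrate_reduction(km, cfg)
for step in trace.steps:
    print(f"{len(step.substrate_set)} substrates  removed={step.removed}"
          f"  RMSE={step.rmse:.4f}")
```

prints

```
E1: RMSE = 0.0000
E2: RMSE = 0.0000
E3: RMSE = 0.0000
overall: 0.0000
7 substrates  removed=None  RMSE=0.0000
6 substrates  removed=S6  RMSE=0.0000
5 substrates  removed=S5  RMSE=0.0000
4 substrates  removed=S4  RMSE=0.0000
3 substrates  removed=S1  RMSE=0.0364
2 substrates  removed=S2  RMSE=0.2576
```

Reading: with kinetics *fitted from simulated calibration assays* (not
the truth), 20 mixtures of 3 independent proteases are deconvolved
essentially exactly with 7 substrates, and the greedy trace shows the
accuracy holding down to 3 substrates before collapsing at 2 — three
independent proteases need at least three substrates.

A `protdeconv` command-line tool exposes the same pipeline as
subcommands (`simulate`, `fit-kinetics`, `deconvolve`, `sweep-lambda`,
`select-substrates`, `cluster`, `family-deconvolve`); every run writes
a `manifest.json` with the config echo and seed, so outputs are
byte-reproducible:

```sh
protdeconv simulate --seed 42 --out out/panel
protdeconv fit-kinetics --assays out/panel/single_assays.csv --seed 42 --out out/fit
protdeconv deconvolve --mixture out/panel/mixture.csv \
    --kinetics out/fit/kinetic_matrix_fitted.json --seed 42 --out out/deconv
```

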