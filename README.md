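# wintercmr

Winter PIT-telemetry capture–mark–recapture analysis for stream fish.

Tracking PIT-tagged fish (brown trout, European sculpin) through a frozen-over
boreal stream poses a double inference problem: the *return rate* — the
fraction of tagged fish found at a tracking occasion — is the product of
**apparent survival** φ (surviving and staying in the reach) and **detection
probability** p (being found, given present), and both vary strongly over a
winter. Surface ice thickens, shrinking the effective range of the reader
antenna, most severely for small 12-mm tags; fish condition in autumn governs
who survives to spring. `wintercmr` implements the full analysis chain a
winter tracking study needs:

- **Ice model** — the Stefan equation coupled to a snow layer,
  `h_i = sqrt(2 k_s/i S* / (ρ L))` with the series conductivity
  `k_s/i = (h_i + h_s) / (h_i/k_i + h_s/k_s)` solved self-consistently per
  day from freezing degree-days `S`, including mid-winter snow-shoveling
  resets (snow layer → 3 cm).
- **Encounter histories** — movement-based fate classification (residents
  show upstream or lateral moves beyond the 0.5-m tracking accuracy;
  never-redetected fish and stationary/downstream-drifting tags are
  transients), mortality truncation, and biweekly pooling.
- **CJS engine** — Cormack–Jolly–Seber likelihood on the logit scale with
  design-matrix model strings such as `{φ(t × cond)p(g × ice + complex × t)}`
  (groups, time, individual covariates, and ice as a linear temporal
  constraint), quasi-Newton fitting with simulated-annealing fallback,
  delta-method SEs, and numerical estimability (the terminal φ·p confound is
  detected and reported).
- **Selection & GOF** — QAICc ranking with Akaike weights and the
  simulation-based median-ĉ overdispersion estimate; SEs inflate by √ĉ.
- **Association** — continuity-corrected Mantel–Haenszel test and risk
  ratio for maturity (spawning/spent) versus detection-history class.
- **Synthetic data** — a generator that emulates the study conditions
  (3 groups of 182/50/161 fish, 26 weekly occasions, ice-driven detection,
  condition-driven survival, transients and shed tags) with a ground-truth
  sidecar, so every stage is testable without field data.

## Worked example

```python
from wintercmr import fit, simulate_dataset
from wintercmr.pipeline import prepare_cjs_data
from wintercmr.synthetic import weekly_ice_covariate

ds = simulate_dataset(seed=11)                       # 393 tagged fish, 26 weekly trackings
data, per_fish = prepare_cjs_data(ds.registry, ds.tracking, ds.reach,
                                  weekly_ice_covariate(ds.ice, 26))
f = fit("{phi(cond)p(g x ice)}", data, seed=0)
print(f.summary())
```

prints (abridged)

```
             parameter   beta     se
              phi:cond  1.486  3.543
       p:g=sculpin:ice -7.127  0.353
p:g=juvenile_trout:ice -4.616  0.639
   p:g=adult_trout:ice -3.978  1.087
```

The positive `phi:cond` coefficient says better-conditioned fish have higher
biweekly apparent survival; the negative ice slopes say detection drops as
ice thickens, with the steepest decline for sculpin (12-mm tags: biweekly p
falls from 0.83 in open water to 0.17 under peak ice) and the shallowest for
adult trout (23-mm tags stay above 0.9). The `examples/` directory walks
through each capability — ice growth, simulation, history construction,
fitting, selection/GOF, and the maturity association — as short narrative
scripts; a thin CLI (`wintercmr simulate|ice|build-histories|fit|select|gof|assoc|report`)
wraps the same pipeline for shell use.

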