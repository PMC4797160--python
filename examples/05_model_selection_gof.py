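"""Overdispersion (median c-hat) and QAICc candidate-model ranking.

The covariate-free global model is checked for lack of fit by simulating
datasets at known overdispersion levels; the resulting c-hat adjusts the
likelihoods before QAICc weights pick the most parsimonious structure.
"""

import warnings

from wintercmr import ModelResult, adjust_for_overdispersion, fit, median_chat, rank_models, simulate_dataset
from wintercmr.pipeline import prepare_cjs_data
from wintercmr.synthetic import weekly_ice_covariate

warnings.filterwarnings("ignore")

ds = simulate_dataset(seed=11)
data, _ = prepare_cjs_data(ds.registry, ds.tracking, ds.reach, weekly_ice_covariate(ds.ice, 26))

est = median_chat("{phi(g)p(g x t)}", data, n_rep=30, seed=1)
c_hat = max(1.0, est.c_hat)
print(f"median c-hat = {est.c_hat:.3f} (SE {est.se:.3f}); "
      "values slightly above 1 reflect mild individual heterogeneity")

candidates = [
    "{phi(cond)p(g x ice + complex)}",
    "{phi(cond)p(g x ice)}",
    "{phi(1)p(g x ice)}",
    "{phi(cond)p(g)}",
    "{phi(1)p(g)}",
]
results = []
for m in candidates:
    fitted = adjust_for_overdispersion(fit(m, data, seed=0, use_annealing=False), c_hat)
    results.append(ModelResult.from_fit(fitted, c_hat=c_hat, name=m))
table = rank_models(results)
print(table[["rank", "model", "delta_qaicc", "weight", "K"]].to_string(index=False))
print("\nThe QAICc weight is the relative support for each structure; ice-driven")
print("detection should dominate because the generator made it true.")
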