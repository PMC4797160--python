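"""From tracking records to pooled encounter histories and return rates.

Classifies fates by movement pattern (0.5 m accuracy), builds weekly
detection histories, pools adjacent weeks, and summarises per-group return
rates — the raw detected fraction that confounds survival with detection.
"""

import warnings

import numpy as np

from wintercmr import build_history, return_rate, simulate_dataset
from wintercmr.pipeline import prepare_cjs_data
from wintercmr.synthetic import weekly_ice_covariate

warnings.filterwarnings("ignore")

ds = simulate_dataset(seed=11)
ice_w = weekly_ice_covariate(ds.ice, 26)
data, per_fish = prepare_cjs_data(ds.registry, ds.tracking, ds.reach, ice_w)

print(per_fish.groupby(["group", "fate"]).size().unstack(fill_value=0))
print(f"\n{data.n} residents enter the model with {data.T} pooled occasions "
      f"(marking + 13 biweekly)")

by_fish = {f.fish_id: [] for f in ds.registry}
for r in ds.tracking:
    by_fish[r.fish_id].append(r)
for group in ("sculpin", "juvenile_trout", "adult_trout"):
    hists = [build_history(f.fish_id, by_fish[f.fish_id], 26)
             for f in ds.registry if f.group == group and f.fate == "resident"]
    rr = return_rate(hists)
    factor = f"{rr['factor']:.1f}" if np.isfinite(rr["factor"]) else "undefined (a zero week)"
    print(f"{group:16s} mean return rate {rr['rates'].mean():.2f}, "
          f"CV {rr['cv']:.2f}, max/min factor {factor}")
print("\nSmall-tag groups crash to near-zero return in mid-winter (thick ice),")
print("adult trout with 23-mm tags stay detectable — the motivation for modelling")
print("detection probability instead of reading return rates at face value.")
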