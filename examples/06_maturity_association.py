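"""Is spawning state associated with turning transient?

Adult trout tagged near the end of the spawning season may leave the reach
when returning to home habitat. A continuity-corrected Mantel-Haenszel test
on the (spawning/spent) x (transient/resident) table, plus the descriptive
risk ratio.
"""

import warnings

from wintercmr import mantel_haenszel, risk_ratio, simulate_dataset
from wintercmr.assoc import maturity_fate_table
from wintercmr.pipeline import prepare_cjs_data
from wintercmr.synthetic import weekly_ice_covariate

warnings.filterwarnings("ignore")

ds = simulate_dataset(seed=3)
prepare_cjs_data(ds.registry, ds.tracking, ds.reach, weekly_ice_covariate(ds.ice, 26))

adults = [f for f in ds.registry if f.maturity in ("spawning", "spent")]
tbl = maturity_fate_table(adults)
print(f"2x2 counts (spawning/spent x transient/resident): "
      f"a={tbl.a} b={tbl.b} c={tbl.c} d={tbl.d}")
stat, p = mantel_haenszel(tbl)
rr = risk_ratio(tbl)
print(f"Mantel-Haenszel chi-square = {stat:.2f}, P = {p:.4f}")
print(f"risk ratio (spawning vs spent transience) = {rr:.2f}")
if p < 0.05:
    print(f"\nSpawning adults are ~{rr:.1f}x as likely to leave the reach permanently —")
    print("the post-spawning-return signal the test is designed to pick up.")
else:
    print("\nNo significant association in this replicate: with ~160 adults and this")
    print("effect size the test has moderate power, so some datasets read as null.")
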