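"""Generate a synthetic referral study and tabulate its decisions.

The generator emulates a vignette study in which 252 family physicians
each decide on 48 cases (24 above and 24 below the 3% cancer-risk
referral threshold), choosing urgent referral, routine referral or no
referral.
"""

from sdtrefer import SimConfig, generate_study, pooled_rates, tabulate_decisions

ds, truth = generate_study(SimConfig(seed=1))
tab = tabulate_decisions(ds)

print(tab.to_frame())
print()
print("decision mix (% of all decisions):", tab.decision_percent)
h, fa = pooled_rates(ds)
print(f"pooled hit rate {h:.2f}, pooled false-alarm rate {fa:.2f}")
print()
print("The hit rate is the share of above-threshold cases referred "
      "urgently; the false-alarm rate is the share of below-threshold "
      "cases referred urgently. A hit rate well above the false-alarm "
      "rate means responders discriminate, and both being high means an "
      "overall lenient (refer-prone) response style.")
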