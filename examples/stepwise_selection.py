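"""Select covariates by stepwise AIC search.

The fixture generates counts that depend on the bad-health indicator but
not on age (its true coefficient is zero), so a correct search keeps badh
and leaves age out.
"""

import gwreg

df = gwreg.fixtures("badhealth_like", n=1500, seed=8)
null_fit = gwreg.fit_gw(gwreg.build_design(df, "numvisit", []))

selected, trace = gwreg.step_select(null_fit, scope=["badh", "age"], direction="both")

print(f"start AIC (intercept only): {null_fit.aic:.1f}")
for i, rnd in enumerate(trace):
    cands = ", ".join(f"{c['action']} {c['term']}: {c.get('AIC', float('nan')):.1f}"
                      for c in rnd["candidates"])
    print(f"round {i}: current {rnd['current_terms']}, candidates [{cands}]")
print(f"selected terms: {selected.design.terms}  (AIC {selected.aic:.1f})")
print("age is excluded because its AIC penalty is not repaid by fit improvement.")
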