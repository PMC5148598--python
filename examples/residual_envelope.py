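"""Check model adequacy with a simulated residual envelope.

Refits the model to 19 datasets simulated from itself and bands the ordered
residuals rank by rank.  When the model is right, the largest absolute
residual escapes the band with probability 1/20, so a point cloud inside
the band is consistent with the model.
"""

import gwreg

df = gwreg.fixtures("badhealth_like", n=400, seed=12)
fit = gwreg.fit_gw(gwreg.build_design(df, "numvisit", ["badh"]))

env = gwreg.simulate_envelope(fit, type="deviance", rep=19, seed=99)
print(f"{env.n_outside} of {fit.n} ordered residuals fall outside the rep=19 band")
print(f"largest |residual| escapes every simulated replicate: {env.extreme_escapes}")

gwreg.plot_envelope(env, "envelope.svg")
print("wrote envelope.svg (residuals vs normal order statistics with the band)")
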