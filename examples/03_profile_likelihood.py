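"""Profile-likelihood confidence interval for the opening time constant.

Re-optimises (kd, c3) along a grid of ku values around the global
estimate and reports where the objective stays below the 95%
likelihood-ratio threshold.
"""

import numpy as np

import photodyn as P

params = P.ModelParameters.default()
spec = P.IrradianceProfileSpec(mode="chamber_fluctuating", duration=3600, seed=108)
trace = P.generate_environment(spec)
dataset = P.generate_gas_exchange(trace, params, P.NoiseSpec(seed=208))

fit_result = P.fit(dataset, seed=1, population=60)
ku_hat = fit_result.estimates["ku"]
grid = np.linspace(ku_hat - 25, ku_hat + 25, 11)
prof = P.profile_likelihood(dataset, "ku", grid, fixed=params,
                            fit_result=fit_result)

print(f"ku estimate: {ku_hat:.1f} s (truth 179.4 s)")
print(f"objective threshold: {prof.threshold:.4f}")
for v, o in zip(prof.grid, prof.objective):
    marker = "*" if prof.interval[0] <= v <= prof.interval[1] else " "
    print(f"  ku={v:7.1f}  O={o:.4f} {marker}")
print(f"95% interval: [{prof.interval[0]:.1f}, {prof.interval[1]:.1f}] s")

# Interpretation: the profile is a parabola-like valley around the
# estimate; the starred grid values lie inside the 95% confidence
# interval.  An hour of step-rich data at 2 s cadence pins ku to a
# few seconds.
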