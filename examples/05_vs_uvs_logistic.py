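"""Logistic link between sw1 omega-lineage and the VS/UVS condition.

Traits are generated under the published coefficients (4.44, -79.91);
the fit recovers them and the ancestral condition (omega = 0) is
strongly violet-sensitive.
"""

import numpy as np
import pandas as pd

from opsinevol import logistic_fit, predict_probability, simulate_traits

rng = np.random.default_rng(3)
omegas = pd.Series(rng.uniform(0, 0.1, size=500),
                   index=[f"sp{i}" for i in range(500)])
traits = simulate_traits(omegas, beta0=4.44, beta1=-79.91, seed=4)

fit = logistic_fit(omegas, traits)
print(f"VS log-odd score = {fit.beta0:.2f} {fit.beta1:+.2f} * omega "
      f"(n = {fit.n})")
print(f"Wald z for slope = {fit.z_beta1:.2f}, p = {fit.p_beta1:.3g}")
print(f"P(VS | omega = 0) fitted    : {predict_probability(fit, 0.0):.3f}")
print(f"P(VS | omega = 0) published : "
      f"{predict_probability((4.44, -79.91), 0.0):.3f}")
# A strongly negative slope means accelerated sw1 lineages are UVS; at
# the ancestral omega of 0 the violet-sensitive state is ~99% probable.
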