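"""Estimate intra- and interspecific transmission rates from sentinel trials.

Simulates a season in which intraspecific transmission dominates
(beta_FF = 0.10) and interspecific transmission is an order of magnitude
weaker (beta_FA = 0.01), fits both the multi-host FOI model and the nested
single-host model, and compares them by DIC.
"""

import numpy as np

from foidecomp import (
    SentinelDesign,
    SimulationConfig,
    credible_interval,
    dic,
    gen_field_season,
    make_sentinel_loglik,
    run_mcmc,
)
from foidecomp.foi import FOI_PRIOR, SINGLE_HOST_PRIOR

# weekly trials with short exposures keep infestation probabilities off the
# ceiling, which is what identifies how FOI scales with host density
design = SentinelDesign(weeks=tuple(range(1, 20)), n_exposed=40, duration_days=3.0)
cfg = SimulationConfig(seed=1, sentinel=design)
fields, trials = gen_field_season(cfg)
print(f"{len(trials)} sentinel trials; infested counts:", [t.n_infested for t in trials])

settings = dict(n_chains=3, n_iter=8000, burn_in=4000)
ll_multi = make_sentinel_loglik(trials, fields)
ll_single = make_sentinel_loglik(trials, fields, single_host=True)
multi = run_mcmc(ll_multi, FOI_PRIOR, seed=2, **settings)
single = run_mcmc(ll_single, SINGLE_HOST_PRIOR, seed=2, **settings)
pd_m, dic_m = dic(multi, ll_multi)
pd_s, dic_s = dic(single, ll_single)

print("\nMulti-host posterior (median and 95% credible interval):")
for name, ci in credible_interval(multi).items():
    print(f"  {name}: {ci.point:.4f} ({ci.lower:.4f}, {ci.upper:.4f})")
print(f"multi-host  pD = {pd_m:.2f}, DIC = {dic_m:.2f}")
print(f"single-host pD = {pd_s:.2f}, DIC = {dic_s:.2f}")
print(
    "\nThe beta_FF interval should cover the generating 0.10 while the beta_FA "
    "interval stretches toward zero — the interspecific signal is weak — and "
    "k_FA stays wide: with so little interspecific transmission the data cannot "
    "say how it scales with density. A small DIC difference means adding "
    "interspecific transmission barely improves fit."
)
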