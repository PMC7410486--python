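"""Simulate a stool-like stochastic logistic community.

Draws the default 100-species blueprint (lognormal steady states spanning
several decades, growth rates in the white-pink band, large linear noise),
integrates it for 1000 days of daily samples, and prints basic facts about
the resulting series.
"""

import numpy as np

from stochglv import CommunityBlueprint, rank_abundance, simulate_blueprint

bp = CommunityBlueprint(seed=0)
series, params, steady_state = simulate_blueprint(bp)

profile = rank_abundance(series)
span = np.log10(profile.abundances[0] / profile.abundances[-1])
cv = series.values.std(axis=0) / series.values.mean(axis=0)

print(f"species:                {series.n_species}")
print(f"samples:                {series.n_times} at interval {series.sampling_interval}")
print(f"rank-abundance span:    {span:.1f} decades (heavy-tailed by construction)")
print(f"self-interaction span:  {np.log10((-params.self_interactions).max() / (-params.self_interactions).min()):.1f} decades")
print(f"median per-species CV:  {np.median(cv):.2f} (large fluctuations, as observed)")
print(f"total-abundance CV:     {series.values.sum(axis=1).std() / series.values.sum(axis=1).mean():.2f} "
      "(community total fluctuates less than typical members)")
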