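"""Decide whether landscape routes or straight-line distance explains a
region's genetic covariance.

Data are simulated under the routes scenario (a random dispersal-path tree),
then fitted twice: once with the tree's own covariance and once with the
covariance implied by geodesic distances between the same sites. The
BIC-type score (higher is better; equal parameter counts, so the comparison
reduces to maximum log-likelihood) should prefer the generating scenario.
"""

from dispmix import (
    HmcConfig,
    RegionConfig,
    heuristic_covariance,
    linear_distances,
    model_score,
    run_hmc,
    simulate_region,
)

sim = simulate_region(RegionConfig(seed=101, n_sites=8, n_snps=100, scenario="routes"))
v_routes = sim.V
v_linear = heuristic_covariance(linear_distances(sim.sites, sim.center))

cfg = HmcConfig(chains=2, length=2000, seed=7, compute_diagnostics=False)
score_routes = model_score(run_hmc(sim.counts, v_routes, cfg))
score_linear = model_score(run_hmc(sim.counts, v_linear, cfg))

print(f"score under routes covariance: {score_routes:.1f}")
print(f"score under linear covariance: {score_linear:.1f}")
winner = "routes" if score_routes > score_linear else "linear"
print(f"selected scenario: {winner} (data were generated under routes)")
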