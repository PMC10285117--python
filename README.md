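# dispmix

Dispersal-aware allele-frequency inference and windowed admixture-graph
estimation for pooled SNP data from georeferenced population samples.

`dispmix` is aimed at population geneticists working with landrace or wild
population collections where each geographic region was sampled at several
known sites and genotypes are pooled into per-site allele counts. It answers
two questions that standard population-structure tools conflate:

1. **Within a region** — what are the region's *representative* (ancestral)
   allele frequencies, given that each sampling site has drifted away from
   the regional ancestor along a dispersal path across the landscape? And did
   dispersal follow landscape routes (least-cost paths) or straight lines?
2. **Between regions** — which admixture history (a tree plus one or more
   mixture events, possibly nested, with any number of sources) best explains
   the regional frequencies, window by window along the genome, and how does
   each admixed population's variance decompose into source contributions?

## Model core

Allele frequencies enter as log-balances `x = log((1-f)/f)`. Within a
region with M sites, SNP i follows

    x_i  ~ MvN( xA_i·1 ,  s_i · V · g(fA_i) ),     y_ji ~ Bin(n_ji, f_ji),

where `V` is the dispersal covariance — `V_jk` = shared center-to-site path
length of sites j and k under a "routes" (least-cost) or "linear" (geodesic)
scenario, computed from the heuristic `ρ_jk = (d_j + d_k − x_jk)/2`, exact on
additive path trees — `s_i ~ Exp(1)` is a per-SNP drift scale, and
`g(fA) = 1/(fA(1−fA))` maps Wright–Fisher drift to the balance scale.
Posteriors are sampled by Hamiltonian Monte Carlo with analytic gradients;
candidate diffusion centers (a 4×4 grid over the region) and scenarios are
ranked by a BIC-type score, higher better.

Between P populations, a migration hypothesis (base tree + admixture events
`y = Σ_q w_q z_q` with own variance `t_y` and source-sharing fractions
`α_q`) parametrizes `D_jk = V_jj + V_kk − 2V_jk`, and each genomic window w
(3 Mb, step 1 Mb, ≥10 SNPs) is scored by

    f(D, w) = Σ_{j<k} log N( d_w(j,k) | 0, D_jk ) + (λ−1) Σ_q log w_q,

with `d_w` the RMS balance distance in the window and a Dirichlet(λ = 0.9)
regularizer on the weights.

## Worked example

`examples/` holds one short script per capability. Simulating a region and
recovering its ancestral frequencies (`examples/01_simulate_and_fit_region.py`):

```text
simulated: 8 sites x 100 SNPs, drift scale mean 0.051
sampler: acceptance 0.82, max R-hat 1.020 (values < 1.1 indicate converged chains)
ancestral frequency recovery: RMSE = 0.048 over 100 SNPs
first five SNPs (truth -> estimate):
  snp0000: 0.382 -> 0.364
  snp0001: 0.704 -> 0.691
```

The RMSE of 0.048 says the hierarchical model undoes site-level drift and
binomial sampling noise to within ~5 frequency points per SNP. Scenario
selection (`examples/02_scenario_selection.py`) prints the two scores —

```text
score under routes covariance: -11928.2
score under linear covariance: -11965.3
selected scenario: routes (data were generated under routes)
```

— a 37-point score gap in favour of the generating scenario. Windowed
admixture estimation (`examples/03_windowed_admixture.py`) recovers a 70/30
two-source mixture with per-window medians near the truth and decomposes the
admixed population's variance into source and own shares.

The same functionality is scriptable from the shell via the thin `dispmix`
CLI (`dispmix sim`, `dispmix popdisp`, `dispmix migadmi`, `dispmix
fixture`); every output file carries a provenance header with version, seed
and a config hash, and identical invocations produce byte-identical outputs.

## Documentation

`docs/methods.md` describes both models, their priors and sampling scheme,
the window objective and its regularization, the variance-decomposition
rule, what the simulator does and does not emulate, and known limitations.
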