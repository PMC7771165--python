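# flankscr

Bayesian spatial capture–recapture (SCR) for camera-trap surveys with
**partially identified bilateral marks** — the situation faced when a
species (wildcats, leopards, other patterned carnivores) is identified
by its flank patterns, the two flanks of one animal cannot be matched
unless it was photographed from both sides simultaneously, and the
survey therefore yields a mix of fully identified individuals and
unlinked single left-flank / right-flank records.

`flankscr` estimates closed-population abundance N and density from
such data by jointly sampling the latent matching between single-flank
records, the animals' activity centers, and all model parameters.

## The model

Each detected individual *i* has a latent activity center *s_i* on a
discrete state space (a buffered grid of habitat-cell centroids,
optionally restricted by a habitat-suitability mask *h_q*). Detection
of individual *i* at trap *j* on occasion *t* follows a complementary
log–log model

    cloglog(p_ijt) = x_jt' β + log g(d_ij),     g(d) = exp(−d²/2σ²),

with the half-normal (or exponential) distance kernel and trap
covariates *x_jt* (intercept; standardized trap elevation; enduring
behavioral response to first capture — the candidate set
M0, Me, Mc, Me+c). Conditional on a detection, the photograph is a
left flank (probability δ₁), a right flank (δ₂), both flanks
non-simultaneously ((1−δ₁−δ₂)(1−α)) or both simultaneously
((1−δ₁−δ₂)α) — only the last resolves identity. Encounter codes
0–4 record these five outcomes per individual × trap × occasion.

Inference uses the **semi-complete data likelihood** for a closed
population,

    [Y, s, z | β, σ, δ, α, N] ∝ ∏_{i,j,t} π_ijt · N!/(N−n)! (1−p*)^{N−n},

where n is the number of distinct detected individuals implied by the
current matching, and p* — the probability an animal in the state
space is detected at least once — is approximated by averaging over
the suitable grid cells. The undetected part of the population is
handled analytically, so no data augmentation is needed; the exact
conditional of N is n plus a Negative-Binomial(n, p*) draw under the
1/N prior. The matching itself is sampled with reversible
link/unlink/swap moves validated against exhaustive enumeration.
Multimodel inference over {M0, Me, Mc, Me+c} uses reversible-jump
Gibbs sampling of a model indicator with moment-matched multivariate
normal pseudo-priors.

## Worked example

Simulate a survey-scale data set (64 traps on an 8×8 lattice, 20
occasions, ~30 animals on masked habitat), fit the constant-detection
model, and report density per 100 km² of suitable habitat:

```python
import numpy as np
from flankscr import simulate_study, run, MCMCConfig, density_summary, hr_radius, hr_area

data, truth, traps, grid = simulate_study("wildcat_like", seed=3)
print(data.n_known, data.n1, data.n2)      # 17 known, 5 left, 5 right records

fit = run(data, grid, traps, "M0",
          config=MCMCConfig(n_chains=3, n_iter=6000, n_adapt=800,
                            n_burn=1200, thin=2, seed=13,
                            store_centers=False))
N = fit.stacked("N")
dens = density_summary(N, grid.suitable_area_km2)
print(round(dens.median, 1), [round(v, 1) for v in dens.ci])
# 26.5 [21.1, 33.6]   animals per 100 km^2 suitable habitat (truth: N = 30)

sigma_km = np.median(fit.stacked("sigma")) / 1000
r = hr_radius(sigma_km)
print(r, hr_area(r))                       # 1.92 km radius, 11.6 km^2 home range
print(round(fit.diagnostics["max_psrf"], 3))  # 1.003
```

The posterior median density of 26.5 (95% credible interval
21.1–33.6) per 100 km² recovers the simulated truth (N = 30 on
128 km² of suitable habitat ⇒ 23.4/100 km²); the movement scale σ
converts to a 95% home-range radius r = σ·√(χ²₀.₉₅;₂) under a
bivariate-normal space-use model.

A command-line interface covers the same pipeline on files
(`traps.csv`, `detections.csv`, `habitat.asc`):

```bash
flankscr simulate -c sim.yml
flankscr fit -c fit.yml
flankscr modelavg -c fit.yml
flankscr report -c fit.yml --samples-dir fit_M0
```

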