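# Methods

## The estimation problem

Camera-trap surveys of bilaterally marked animals produce three kinds
of records: individuals photographed from both sides simultaneously at
least once (identity certain, encounter codes 0–4 fully observed),
single left-flank histories (codes 0/1), and single right-flank
histories (codes 0/2). Two single-flank records may or may not be the
same animal, so both the latent encounter histories Y and the number
of distinct detected individuals n are unknown. The package treats
the matching between left and right singles as a latent partial
bipartite matching and samples it jointly with everything else.

Mark-type convention: type 1 = left flank, type 2 = right flank. The
model is symmetric in the two marks; the convention only fixes the
code values.

## Model

**Detection.** cloglog(p_ijt) = x_jt'β + log g(d_ij), with the
half-normal kernel g(d) = exp(−d²/2σ²) (exponential optional) and
d_ij the distance from trap j to the activity center s_i. A handy
identity under this link: log(1 − p) = −exp(η), so survival terms
need a single exponential. The linear predictor is clipped at ±50
before the double exponentiation. Trap elevation is standardized
(mean 0, sd 1 over traps) before entering x'β, because the N(0, 1.75)
coefficient prior is scale-sensitive. The behavioral covariate (Mc)
is the *enduring global* indicator: 1 from the occasion after the
individual's first detection at any trap. It is recomputed whenever
the latent matching changes (merging two singles can move the first
detection earlier).

**Encounter types.** Conditional on detection, codes 1/2/3/4 occur
with probabilities δ₁, δ₂, (1−δ₁−δ₂)(1−α), (1−δ₁−δ₂)α. The per-cell
probabilities π_ijt are: 1 − m_jt z_i p_ijt for a non-detection
(hence exactly 1 for ghost records with z = 0, and 1 when the trap
was dark), and m_jt p_ijt times the code's probability otherwise.

**Population.** The semi-complete likelihood conditions the ñ records
on detection and handles the N − n undetected animals through the
binomial factor N!/(N−n)! (1−p*)^{N−n}; the 1/p*^n of the
conditional-on-detection construction cancels the binomial's p*^n and
is never computed. p* is approximated by averaging the per-cell
probability of at least one detection over the suitable cells of the
state-space grid — the same grid that supports the activity centers.
In p* the behavioral covariate is held at 0: before its first
detection an animal is by definition uncaptured, so first-detection
probability does not involve the behavior coefficient.

**State space.** Axis-aligned bounding box of the traps plus a buffer
(2.5σ by convention), gridded into square cells with ceil rounding;
centroid-based distances; a binary habitat flag per cell with no
partial-area weighting. Activity centers have a discrete uniform
prior over suitable centroids. Masks are read from ESRI ASCII grids
or x,y,h CSV.

**Priors** (all user-settable; defaults): β_k ~ N(0, 1.75),
σ ~ Uniform(10 m, 16 550 m), δ ~ Dirichlet(1,1,1) — or, under the
default δ₁ = δ₂ constraint, u = δ₁+δ₂ ~ Beta(1,1) with δ₁ = δ₂ = u/2 —
α ~ Beta(1,1), ψ ~ Beta(1,1), N ∝ 1/N. ψ is the probability that an
observed record is a distinct individual; ghosts (the right member of
a linked pair) have z = 0.

## Sampler

Per iteration: random-walk Metropolis on β (joint block) and on
log σ (with the σ'/σ Jacobian against the uniform prior);
exact conjugate draws u | counts ~ Beta(a+c₁+c₂, c+c₃+c₄),
α | counts ~ Beta(a+c₄, b+c₃), ψ | z ~ Beta(a+n, b+#ghosts); the
exact conditional N = n + M, M ~ NegBin(n, p*); vectorized Metropolis
moves of all activity centers (±2-cell window proposal, 10% global
draws over suitable cells, proposals off-grid or into unsuitable
cells auto-rejected); and a batch of matching moves.

**Matching moves** (LINK / UNLINK / SWAP, chosen 40/40/20): LINK
merges a uniformly chosen unmatched left and right record; the merged
individual keeps the left record's center and the right record
becomes a ghost. UNLINK splits a uniformly chosen pair and draws the
reactivated right record's center from the softmax of that record's
per-cell log-likelihood — an independence proposal whose density
cancels the new center's likelihood in the acceptance ratio, so
link/unlink decisions effectively marginalize over it (only the
logsumexp over cells remains). SWAP exchanges the partners of two
pairs. Acceptance ratios include the likelihood change, the
ψ-Bernoulli and center-prior terms, the population binomial factor
(n changes by ±1), and the full proposal asymmetry. The number of
attempts per iteration scales with the number of single-flank records
(⌈(n₁+n₂)/4⌉) — singles are the only records the matching can move,
and this count keeps per-iteration cost proportional to the matchable
data while total attempts across a run remain in the hundreds of
thousands.

**Adaptation.** Robbins–Monro scaling of the two random-walk scales
toward 30% acceptance during the first `n_adapt` iterations only;
frozen afterwards so detailed balance holds for every retained draw.

**Initialization.** All singles unmatched; each center at the
suitable cell nearest the record's mean detection location; β = 0;
σ at the geometric midpoint of its prior bounds;
N = ⌈n / max(p*, 0.1)⌉. Non-finite posteriors trigger
re-initialization up to a retry cap.

**Implementation.** A per-parameter cache holds the log-survival
matrix over suitable cells × traps; record likelihoods are evaluated
on demand (single-cell point evaluations in acceptance ratios, full
per-cell columns only for the UNLINK softmax), and the running
detection log-likelihood is updated incrementally across accepted
moves. Its agreement with a direct reference evaluation of the
likelihood is asserted along running chains in the tests, for all
four detection models. Single-mark (conventional SCR) fits reuse the
same engine with the encounter-type constants set to one and no
matching, δ/α or ψ updates.

**Diagnostics.** Univariate split-chain PSRF and bulk ESS via arviz
on log N, log σ, the coefficients, and logit-transformed
probabilities; the Brooks–Gelman multivariate PSRF is computed
directly (largest eigenvalue of W⁻¹B/n). A full-scale analysis of
field data uses 5 chains × 320 000 iterations (10 000 adaptation,
20 000 burn-in); simulation experiments here use 3 × 20 000 or
smaller, stated with each experiment.

## Multimodel inference

Each candidate model is fitted separately; a multivariate normal
pseudo-prior is moment-matched to each posterior on transformed
scales (raw β, log σ, logit u/α/ψ), with diagonal inflation if the
sample covariance is singular. A model indicator is then
Gibbs-sampled: the current model's parameters are drawn from its
stored chain, the others from their pseudo-priors, and the indicator's
conditional only needs w_k L_k π_k / g_k per model. Model-averaged
samples of shared quantities (N, σ, density) are collected from the
currently selected model. For the SCR models the latent matching is
not part of the jump: it is resampled for a few sweeps conditional on
the proposed parameters before the joint density is evaluated. That
makes the SCR log-joint stochastic (a pseudo-marginal flavor); the
continuous machinery is validated exactly on a conjugate two-model
toy with a closed-form Bayes factor.

## Simulator

The generator draws N activity centers uniformly over suitable cells,
then per occasion (sequentially, so the behavioral response can act)
per trap Bernoulli detections with the model's p, then the encounter
code from (δ₁, δ₂, (1−δ₁−δ₂)(1−α), (1−δ₁−δ₂)α). Observed data are
spawned deterministically: any individual with a code-4 event becomes
a known record; others dissolve into unlinked single-flank records.
The population is closed — no births, deaths or movement of centers
within a survey.

Two presets define the standard study conditions:

* `wildcat_like` — 64 traps on an 8×8 lattice at 1.25 km spacing,
  20 occasions (3-day blocks of a 60-day survey), N = 30, σ = 870 m,
  δ₁ = δ₂ = 0.3, α = 0.7, cloglog intercept −2.7, 75% of cells
  suitable. These values reproduce the sparsity of a real wildcat
  survey of this design: ~27 observed records of which ~12 known, and
  ~65 detection events (a survey of this kind yielded 21 records / 64
  events, with some singles matched from post-survey information).
* `recovery` — 25 traps on a 5×5 lattice at 1 km, 10 occasions,
  N = 50, σ = 700 m, δ₁ = δ₂ = 0.3, α = 0.4, intercept −1; used for
  the repeated simulate-and-refit experiments. Its state space uses
  625 m cells (≈ 0.9σ; σ/2 to σ is standard SCR practice) with the
  2.5σ buffer.

What the simulator does *not* emulate: sex or other individual
heterogeneity in σ or p (a known source of negative bias in real
surveys), misidentification other than the bilateral structure,
camera failures beyond the operation matrix, attractant decay, or
inhomogeneous density. Passing recovery tests therefore demonstrate
correctness of the estimator under its own assumptions, not
robustness to their violation.

## Numerical choices

Log-space throughout; `lgamma` for factorial ratios; probabilities
floored at 1e−300 before logs; η clipped to ±50; p* clipped away
from 1 in log1p(−p*) by 1e−12. Ties in the within-occasion collapse
resolve by code strength (4 > 3 > 1/2; a left and a right event in
the same record × trap × occasion combine to 3), so simultaneity is
never lost by aggregation. Occasions are 1-based externally, 0-based
internally; records keep stable string ids and file order.

## Limitations

Single survey (closed population) only; two mark types; no
individual covariates; discrete activity centers (grid-resolution
bias if cells are much larger than σ); the RJ model-averaging scheme
relies on adequately mixed per-model chains and, for the SCR set, on
the latent-resampling approximation described above. Density is
reported per unit of suitable habitat or of total state space — with
fragmented habitat the two differ substantially and only the former
is comparable across study areas.
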