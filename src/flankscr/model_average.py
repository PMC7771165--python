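"""Bayesian multimodel inference over the detection-model set.

Posterior model probabilities for {M0, Me, Mc, Me+c} are obtained by
the Gibbs-sampling reversible-jump scheme of Barker and Link: each
model is first fitted separately; a multivariate-normal pseudo-prior is
matched to each model's posterior on transformed scales (log sigma,
raw coefficients, logit probabilities); then a model indicator is
Gibbs-sampled, drawing the current model's parameters from its stored
posterior chain and the other models' parameters from their
pseudo-priors.  The indicator's full conditional only involves the
ratio  w_k * L_k(theta_k) * prior_k(theta_k) / pseudo_k(theta_k).

For the SCR models the latent matching is not given its own
pseudo-prior: it is resampled conditional on the proposed model's
parameters before the joint density is evaluated.  This keeps the
sampler valid for the model-specific parameters while avoiding
reversible jumps across the shared discrete latent space; the scheme
is validated against a closed-form Bayes-factor oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import PriorSpec
from .sampler import PosteriorSamples


@dataclass
class MvnPseudoPrior:
    """Multivariate normal proposal matched to a model's posterior."""

    mean: np.ndarray
    cov: np.ndarray
    _chol: np.ndarray = field(init=False, repr=False)
    _logdet: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = _regularize(np.atleast_2d(np.asarray(self.cov, dtype=float)))
        self._chol = np.linalg.cholesky(self.cov)
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    @property
    def dim(self) -> int:
        return self.mean.size

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.mean + self._chol @ rng.standard_normal(self.dim)

    def logpdf(self, x: np.ndarray) -> float:
        dev = np.asarray(x, dtype=float) - self.mean
        sol = np.linalg.solve(self._chol, dev)
        return float(-0.5 * (self.dim * math.log(2 * math.pi) + self._logdet
                             + sol @ sol))


def _regularize(cov: np.ndarray, min_ratio: float = 1e-8) -> np.ndarray:
    """Force positive definiteness by diagonal inflation if needed."""
    cov = 0.5 * (cov + cov.T)
    scale = max(float(np.max(np.diag(cov))), 1e-12)
    jitter = 0.0
    for _ in range(40):
        try:
            np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, min_ratio * scale)
    else:
        raise np.linalg.LinAlgError("could not regularize covariance")
    if jitter > 0:
        import warnings
        warnings.warn("singular posterior covariance: diagonal inflation applied")
        cov = cov + jitter * np.eye(cov.shape[0])
    return cov


def _logit(x):
    x = np.clip(x, 1e-9, 1 - 1e-9)
    return np.log(x / (1 - x))


def transform_draws(samples: PosteriorSamples) -> tuple[np.ndarray, list]:
    """Pooled draws on the pseudo-prior scale.

    Layout: [beta..., log sigma] plus, for two-mark fits,
    [logit(delta1 + delta2), logit(alpha), logit(psi)].
    """
    cols = [samples.stacked("beta")]
    names = list(samples.coef_names)
    cols.append(np.log(samples.stacked("sigma"))[:, None])
    names.append("log_sigma")
    if samples.marks == "dual":
        u = samples.stacked("delta1") + samples.stacked("delta2")
        cols.append(_logit(u)[:, None])
        cols.append(_logit(samples.stacked("alpha"))[:, None])
        cols.append(_logit(samples.stacked("psi"))[:, None])
        names += ["logit_u", "logit_alpha", "logit_psi"]
    return np.column_stack(cols), names


def build_pseudopriors(draws_per_model: dict) -> dict:
    """Fit an MVN pseudo-prior to each model's posterior draws.

    ``draws_per_model`` maps model name to an (M, P) draw matrix (or a
    :class:`PosteriorSamples`, transformed automatically).  Requires a
    healthy number of draws per model (>= 1000) so the moment match is
    stable.
    """
    out = {}
    for name, draws in draws_per_model.items():
        if isinstance(draws, PosteriorSamples):
            draws, _ = transform_draws(draws)
        draws = np.atleast_2d(np.asarray(draws, dtype=float))
        if draws.shape[0] < 1000:
            raise ValueError(
                f"model {name!r}: need >= 1000 posterior draws to build a "
                f"pseudo-prior, got {draws.shape[0]}")
        out[name] = MvnPseudoPrior(mean=draws.mean(axis=0),
                                   cov=np.cov(draws, rowvar=False))
    return out


@dataclass
class ModelEntry:
    """One candidate model for the RJ indicator sampler.

    ``draws``: (M, P) posterior draw matrix on the transformed scale.
    ``log_joint``: callable(theta) -> unnormalized log(likelihood x
    prior) of the model at transformed parameters theta.
    ``shared``: dict of per-draw arrays (length M) of shared reporting
    quantities, e.g. N and sigma, pooled for model-averaged summaries.
    """

    draws: np.ndarray
    log_joint: object
    shared: dict = field(default_factory=dict)


def rjmcmc_weights(models: dict, n_draws: int = 10000,
                   seed: int | np.random.Generator = 0,
                   prior_weights: dict | None = None) -> dict:
    """Posterior model probabilities by Gibbs sampling a model indicator.

    ``models`` maps name -> :class:`ModelEntry`.  Returns posterior
    weights, the indicator trace, and model-averaged samples of every
    shared quantity (drawn from the currently selected model).
    """
    names = list(models)
    if not names:
        raise ValueError("empty model set")
    rng = np.random.default_rng(seed)
    if prior_weights is None:
        prior_weights = {k: 1.0 / len(names) for k in names}
    wsum = sum(prior_weights[k] for k in names)
    log_w = {k: math.log(prior_weights[k] / wsum) for k in names}
    pseudo = build_pseudopriors({k: models[k].draws for k in names})

    counts = {k: 0 for k in names}
    indicator = np.empty(n_draws, dtype=object)
    shared_keys = set()
    for k in names:
        shared_keys.update(models[k].shared.keys())
    averaged = {key: np.empty(n_draws) for key in shared_keys}

    for it in range(n_draws):
        scores = np.empty(len(names))
        chosen_idx = {}
        for i, k in enumerate(names):
            entry = models[k]
            m = entry.draws.shape[0]
            idx = int(rng.integers(m))
            chosen_idx[k] = idx
            theta = entry.draws[idx]
            scores[i] = (log_w[k] + float(entry.log_joint(theta))
                         - pseudo[k].logpdf(theta))
        probs = np.exp(scores - scores.max())
        probs /= probs.sum()
        ki = int(rng.choice(len(names), p=probs))
        k = names[ki]
        counts[k] += 1
        indicator[it] = k
        for key in shared_keys:
            arr = models[k].shared.get(key)
            averaged[key][it] = arr[chosen_idx[k]] if arr is not None else np.nan
    weights = {k: counts[k] / n_draws for k in names}
    return {"weights": weights, "indicator": indicator, "averaged": averaged}


# ---------------------------------------------------------------------------
# SCR pipeline adapter

def scr_model_entries(fits: dict, data, grid, traps, priors: PriorSpec | None = None,
                      latent_sweeps: int = 2, seed: int = 0) -> dict:
    """Wrap fitted SCR models as RJ model entries.

    ``fits`` maps model name -> :class:`PosteriorSamples` from
    :func:`flankscr.sampler.run` on identical data.  The log-joint of a
    model at transformed parameters is evaluated with the latent
    matching resampled for a few sweeps conditional on those
    parameters.
    """
    from .sampler import _Chain, MCMCConfig
    from .detection import ModelSpec
    priors = priors or PriorSpec()
    rng = np.random.default_rng(seed)
    entries = {}
    for name, samples in fits.items():
        model = ModelSpec(samples.model)
        chain = _Chain(data, grid, traps, model, priors,
                       MCMCConfig(n_iter=3, n_adapt=1, n_burn=1),
                       np.random.default_rng(rng.integers(2 ** 31)),
                       marks=samples.marks)
        draws, tnames = transform_draws(samples)

        def log_joint(theta, chain=chain, model=model, tnames=tnames):
            K = model.n_coef
            chain.beta = np.asarray(theta[:K], dtype=float)
            chain.sigma = float(np.exp(theta[K]))
            if chain.marks == "dual":
                u = 1.0 / (1.0 + math.exp(-theta[K + 1]))
                chain.delta1 = chain.delta2 = u / 2.0
                chain.alpha = 1.0 / (1.0 + math.exp(-theta[K + 2]))
                chain.psi = 1.0 / (1.0 + math.exp(-theta[K + 3]))
            if not priors.sigma_lo <= chain.sigma <= priors.sigma_hi:
                return -np.inf
            chain._refresh_cache()
            for _ in range(latent_sweeps):
                chain._update_centers()
                if chain.marks == "dual":
                    for _ in range(chain.data.n1 + chain.data.n2):
                        chain._update_matching()
                chain._update_N()
            lp = chain.log_posterior_value()
            # add the sigma-uniform and beta-normal constants so joints
            # are comparable across models of different dimension
            lp -= math.log(priors.sigma_hi - priors.sigma_lo)
            lp -= 0.5 * model.n_coef * math.log(2 * math.pi * priors.var_beta)
            return lp

        entries[name] = ModelEntry(
            draws=draws, log_joint=log_joint,
            shared={"N": samples.stacked("N"),
                    "sigma": samples.stacked("sigma")})
    return entries


def weights_table(result: dict, prior_weights: dict | None = None) -> pd.DataFrame:
    names = list(result["weights"])
    if prior_weights is None:
        prior_weights = {k: 1.0 / len(names) for k in names}
    return pd.DataFrame({
        "model": names,
        "prior_weight": [prior_weights[k] for k in names],
        "posterior_weight": [result["weights"][k] for k in names],
    })
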