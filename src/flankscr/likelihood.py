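"""Semi-complete data likelihood and posterior for the two-mark SCR model.

For a latent configuration (a matching of single left/right records into
individuals, activity centers s, and parameters) the likelihood is

    [Y, s, z | beta, sigma, delta, alpha, N]
        propto prod_{i,j,t} pi_ijt  x  N!/(N-n)! (1-p*)^(N-n),

where the per-cell encounter probabilities are

    pi_ijt = 1 - m_jt z_i p_ijt                     y_ijt = 0
           = m_jt p_ijt delta_1                     y_ijt = 1
           = m_jt p_ijt delta_2                     y_ijt = 2
           = m_jt p_ijt (1-delta_1-delta_2)(1-a)    y_ijt = 3
           = m_jt p_ijt (1-delta_1-delta_2) a       y_ijt = 4

(the 1/p*^n factor of the conditional-on-detection construction cancels
against the binomial p*^n term and is never computed).  Ghost records
(z = 0, all-zero history) contribute exactly zero to the log-likelihood.

This module is the *reference* evaluation path, written for clarity and
used directly by the exhaustive enumeration oracle on micro instances;
the MCMC engine keeps an equivalent fast path that is cross-checked
against it in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, betaln

from .encounter_data import (
    ObservedEncounterData, MatchState, TrapArray, merge_pair,
)
from .state_space import HabitatGrid
from .detection import DetectionParams, ModelSpec, cloglog_inv, log_kernel_g, pstar

_LOG_EPS = 1e-300


@dataclass
class PriorSpec:
    """Prior hyperparameters (all user-specifiable).

    Defaults follow the wildcat analysis: beta_k ~ N(0, 1.75),
    sigma ~ Uniform(10 m, 16550 m), flat Dirichlet/Beta priors on the
    encounter-type and matching probabilities, scale prior 1/N on
    population size, and the two single-flank probabilities constrained
    equal (delta_1 = delta_2).
    """

    mu_beta: float = 0.0
    var_beta: float = 1.75
    sigma_lo: float = 10.0        # meters
    sigma_hi: float = 16550.0     # meters
    a_delta: float = 1.0          # Dirichlet(a, b, c) on (d1, d2, 1-d1-d2)
    b_delta: float = 1.0
    c_delta: float = 1.0
    a_alpha: float = 1.0
    b_alpha: float = 1.0
    a_psi: float = 1.0
    b_psi: float = 1.0
    delta_constraint: str = "equal"   # "equal" (d1 = d2) or "free"

    def __post_init__(self) -> None:
        if not 0 < self.sigma_lo < self.sigma_hi:
            raise ValueError("need 0 < sigma_lo < sigma_hi")
        for name in ("var_beta", "a_delta", "b_delta", "c_delta",
                     "a_alpha", "b_alpha", "a_psi", "b_psi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.delta_constraint not in ("equal", "free"):
            raise ValueError("delta_constraint must be 'equal' or 'free'")


@dataclass
class ChainState:
    """One point of the Markov chain: latent structure + parameters.

    ``s`` holds the activity-center cell index (into the full grid) of
    each *active* record, aligned with :func:`build_latent` ordering:
    known records, linked pairs (carried by the left member), unmatched
    lefts, unmatched rights.
    """

    match: MatchState
    s: np.ndarray
    params: DetectionParams
    delta1: float
    delta2: float
    alpha: float
    psi: float
    N: int

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=int)
        if self.delta1 < 0 or self.delta2 < 0 or self.delta1 + self.delta2 > 1:
            raise ValueError("need delta1, delta2 >= 0 with delta1 + delta2 <= 1")
        if not 0 <= self.alpha <= 1 or not 0 <= self.psi <= 1:
            raise ValueError("alpha and psi must lie in [0, 1]")


def build_latent(match: MatchState, data: ObservedEncounterData) -> list[np.ndarray]:
    """Latent histories of the active (z = 1) records under a matching.

    Canonical order: known records, then linked pairs in ``match.pairs``
    order (merged history), then unmatched lefts, then unmatched rights.
    """
    matched_left = {l for l, _ in match.pairs}
    matched_right = {r for _, r in match.pairs}
    latent = [h.copy() for h in data.known]
    latent += [merge_pair(data.left[l], data.right[r]) for l, r in match.pairs]
    latent += [data.left[i] for i in range(data.n1) if i not in matched_left]
    latent += [data.right[i] for i in range(data.n2) if i not in matched_right]
    return latent


def log_pi(y: int, m: int, z: int, p: float,
           delta1: float, delta2: float, alpha: float) -> float:
    """Log encounter-type probability for one individual x trap x occasion."""
    if y == 0:
        return math.log(max(1.0 - m * z * p, _LOG_EPS))
    if m == 0:
        return -math.inf  # a detection at a non-operating trap-occasion
    if y == 1:
        val = p * delta1
    elif y == 2:
        val = p * delta2
    elif y == 3:
        val = p * (1.0 - delta1 - delta2) * (1.0 - alpha)
    elif y == 4:
        val = p * (1.0 - delta1 - delta2) * alpha
    else:
        raise ValueError(f"invalid encounter code {y}")
    return math.log(max(val, _LOG_EPS)) if val > 0 else -math.inf


def _behavior_flags(history: np.ndarray) -> np.ndarray:
    """b_t = 1 if the individual was detected on any strictly prior occasion."""
    seen = (history > 0).any(axis=0)
    out = np.zeros(history.shape[1], dtype=bool)
    out[1:] = np.cumsum(seen[:-1]) > 0
    return out


def record_loglik_by_cell(history: np.ndarray, grid: HabitatGrid,
                          traps: TrapArray, model: ModelSpec,
                          params: DetectionParams,
                          delta1: float, delta2: float, alpha: float,
                          cells: np.ndarray | None = None) -> np.ndarray:
    """Log-likelihood of one active record's history at candidate cells.

    Vector over ``cells`` (default: all suitable cells).  Handles the
    behavioral covariate by splitting occasions at the record's first
    detection.
    """
    if cells is None:
        cells = grid.suitable_cells
    X = model.trap_covariates(traps)
    xb = X @ params.beta
    d = np.linalg.norm(grid.centroids[cells][:, None, :] - traps.xy[None, :, :], axis=2)
    eta0 = xb[None, :] + log_kernel_g(d, params.sigma, params.kernel)
    b_coef = model.behavior_coef(params.beta)
    bflags = _behavior_flags(history) if model.has_behavior else np.zeros(
        history.shape[1], dtype=bool)
    const = {
        1: math.log(max(delta1, _LOG_EPS)),
        2: math.log(max(delta2, _LOG_EPS)),
        3: math.log(max((1 - delta1 - delta2) * (1 - alpha), _LOG_EPS)),
        4: math.log(max((1 - delta1 - delta2) * alpha, _LOG_EPS)),
    }
    total = np.zeros(len(cells))
    m = traps.operation
    for b in (False, True):
        occ = np.flatnonzero(bflags == b)
        if occ.size == 0:
            continue
        eta = eta0 + (b_coef if b else 0.0)
        p = cloglog_inv(eta)                       # (C, J)
        log1mp = -np.exp(np.clip(eta, -50, 50))
        sub = history[:, occ]                      # (J, len(occ))
        msub = m[:, occ]
        # nondetections at operating trap-occasions
        n_zero = ((sub == 0) & (msub == 1)).sum(axis=1).astype(float)  # per trap
        total += log1mp @ n_zero
        # detection events
        for j, k in zip(*np.nonzero(sub)):
            y = int(sub[j, k])
            if msub[j, k] == 0:
                return np.full(len(cells), -np.inf)
            with np.errstate(divide="ignore"):
                total += np.log(np.maximum(p[:, j], _LOG_EPS)) + const[y]
    return total


def log_semicomplete(state: ChainState, data: ObservedEncounterData,
                     grid: HabitatGrid, traps: TrapArray,
                     model: ModelSpec) -> float:
    """Semi-complete data log-likelihood of a full latent configuration."""
    latent = build_latent(state.match, data)
    n = len(latent)
    if state.N < n:
        return -math.inf
    if len(state.s) != n:
        raise ValueError("one activity center per active record required")
    if np.any(grid.h[state.s] == 0):
        return -math.inf
    total = 0.0
    for hist, cell in zip(latent, state.s):
        ll = record_loglik_by_cell(hist, grid, traps, model, state.params,
                                   state.delta1, state.delta2, state.alpha,
                                   cells=np.array([cell]))
        total += float(ll[0])
    ps = pstar(state.params, model, grid, traps)
    total += gammaln(state.N + 1) - gammaln(state.N - n + 1)
    if state.N > n:
        if ps >= 1.0:
            return -math.inf
        total += (state.N - n) * math.log1p(-ps)
    return total


def log_prior(state: ChainState, data: ObservedEncounterData,
              grid: HabitatGrid, model: ModelSpec, priors: PriorSpec) -> float:
    """Joint log prior density of the chain state (up to constants in data)."""
    lp = 0.0
    # sigma ~ Uniform(lo, hi)
    if not priors.sigma_lo <= state.params.sigma <= priors.sigma_hi:
        return -math.inf
    lp -= math.log(priors.sigma_hi - priors.sigma_lo)
    # beta_k ~ Normal
    lp += float(np.sum(-0.5 * (state.params.beta - priors.mu_beta) ** 2
                       / priors.var_beta
                       - 0.5 * math.log(2 * math.pi * priors.var_beta)))
    # activity centers: discrete uniform over suitable cells
    n_suit = int(grid.h.sum())
    lp -= len(state.s) * math.log(n_suit)
    # z | psi
    z = state.match.z_flags(data)
    psi = min(max(state.psi, _LOG_EPS), 1 - 1e-16)
    lp += float(z.sum()) * math.log(psi) + float((1 - z).sum()) * math.log1p(-psi)
    # delta prior
    d1, d2 = state.delta1, state.delta2
    d3 = 1.0 - d1 - d2
    if priors.delta_constraint == "equal":
        # u = delta1 + delta2 ~ Beta(a_delta, c_delta), delta1 = delta2 = u/2
        u = d1 + d2
        lp += ((priors.a_delta - 1) * math.log(max(u, _LOG_EPS))
               + (priors.c_delta - 1) * math.log(max(1 - u, _LOG_EPS))
               - betaln(priors.a_delta, priors.c_delta))
    else:
        lp += ((priors.a_delta - 1) * math.log(max(d1, _LOG_EPS))
               + (priors.b_delta - 1) * math.log(max(d2, _LOG_EPS))
               + (priors.c_delta - 1) * math.log(max(d3, _LOG_EPS))
               + gammaln(priors.a_delta + priors.b_delta + priors.c_delta)
               - gammaln(priors.a_delta) - gammaln(priors.b_delta)
               - gammaln(priors.c_delta))
    # alpha, psi ~ Beta
    a = min(max(state.alpha, _LOG_EPS), 1 - 1e-16)
    lp += ((priors.a_alpha - 1) * math.log(a)
           + (priors.b_alpha - 1) * math.log1p(-a)
           - betaln(priors.a_alpha, priors.b_alpha))
    lp += ((priors.a_psi - 1) * math.log(psi)
           + (priors.b_psi - 1) * math.log1p(-psi)
           - betaln(priors.a_psi, priors.b_psi))
    # N ~ 1/N (improper scale prior)
    if state.N < 1:
        return -math.inf
    lp -= math.log(state.N)
    return lp


def log_posterior(state: ChainState, data: ObservedEncounterData,
                  grid: HabitatGrid, traps: TrapArray, model: ModelSpec,
                  priors: PriorSpec) -> float:
    lp = log_prior(state, data, grid, model, priors)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_semicomplete(state, data, grid, traps, model)


# ---------------------------------------------------------------------------
# Exhaustive enumeration on micro instances (validation oracle)

def _all_matchings(n_left: int, n_right: int):
    """Yield every partial matching as a list of (left, right) pairs."""
    from itertools import combinations, permutations
    yield []
    for k in range(1, min(n_left, n_right) + 1):
        for lsub in combinations(range(n_left), k):
            for rsub in permutations(range(n_right), k):
                yield list(zip(lsub, rsub))


def _log_sum_N(n: int, log_1m_pstar: float, n_max: int = 20000) -> float:
    """log sum_{N>=n} N!/(N-n)! (1-p*)^(N-n) / N, truncated at n + n_max."""
    M = np.arange(0, n_max + 1)
    terms = (gammaln(n + M + 1) - gammaln(M + 1) + M * log_1m_pstar
             - np.log(n + M))
    return float(_logsumexp(terms))


def _logsumexp(a):
    a = np.asarray(a, dtype=float)
    m = np.max(a)
    if not np.isfinite(m):
        return m
    return m + math.log(np.sum(np.exp(a - m)))


def enumerate_match_posterior(data: ObservedEncounterData, grid: HabitatGrid,
                              traps: TrapArray, model: ModelSpec,
                              params: DetectionParams,
                              delta1: float, delta2: float, alpha: float,
                              priors: PriorSpec) -> dict:
    """Exact posterior over matchings at fixed detection parameters.

    Marginalizes activity centers over the suitable cells (the sum
    factorizes per record), the population size N over its 1/N prior
    times the binomial factor, and psi over its Beta prior (conjugate:
    the z-likelihood integrates to a Beta function ratio).  Tractable
    only for a handful of single-flank records; used as the independent
    correctness oracle for the MCMC matching moves.

    Returns posterior probability of each matching plus P(any link).
    """
    suit = grid.suitable_cells
    n_suit = suit.size
    ps = pstar(params, model, grid, traps)
    log_1m_ps = math.log1p(-ps) if ps < 1 else -math.inf
    results = []
    logw = []
    nt = data.n_records
    for pairs in _all_matchings(data.n1, data.n2):
        match = MatchState(pairs=pairs)
        latent = build_latent(match, data)
        n = len(latent)
        lw = 0.0
        for hist in latent:
            ll = record_loglik_by_cell(hist, grid, traps, model, params,
                                       delta1, delta2, alpha, cells=suit)
            lw += _logsumexp(ll) - math.log(n_suit)  # center prior sum
        # z | psi integrated against Beta(a_psi, b_psi): n z=1, nt-n z=0
        lw += betaln(priors.a_psi + n, priors.b_psi + nt - n) \
            - betaln(priors.a_psi, priors.b_psi)
        lw += _log_sum_N(n, log_1m_ps)
        results.append(pairs)
        logw.append(lw)
    logw = np.asarray(logw)
    w = np.exp(logw - _logsumexp(logw))
    w /= w.sum()
    p_linked = float(sum(wi for pairs, wi in zip(results, w) if pairs))
    return {"matchings": results, "probs": w, "p_linked": p_linked,
            "pstar": ps}
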