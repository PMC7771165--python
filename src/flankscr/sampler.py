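"""MCMC engine for the two-mark semi-complete-likelihood SCR model.

Per iteration the sampler performs one sweep of

* random-walk Metropolis updates of the detection coefficients and of
  log sigma (Robbins-Monro scale adaptation during the adaptation
  phase, frozen afterwards),
* exact conjugate draws of the encounter-type probabilities (delta,
  alpha) and of the matching probability psi,
* an exact draw of N: N - n is Negative-Binomial(n, p*) under the 1/N
  prior,
* vectorized Metropolis moves of all activity centers (local window
  proposals with an occasional global draw over suitable cells),
* Metropolis-Hastings moves on the latent matching of single left- and
  right-flank records: LINK, UNLINK and SWAP, proposed 40/40/20.  The
  reactivated center in UNLINK is drawn from the softmax of the right
  record's per-cell log-likelihood, so the link/unlink acceptance
  ratios marginalize over that center analytically.

Likelihood bookkeeping: a per-parameter "detection cache" holds the
log-survival matrix log(1 - p) over suitable cells x traps, from which
each record's log-likelihood is evaluated on demand — at a single cell
(point evaluation) for acceptance ratios, or as a full per-cell column
only where a logsumexp/softmax over the state space is required.  The
running site log-likelihood is tracked incrementally across accepted
moves.  Encounter-type constants (delta/alpha factors) are kept out of
the cached quantities so conjugate draws never invalidate them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .encounter_data import ObservedEncounterData, MatchState, TrapArray, is_feasible
from .state_space import HabitatGrid
from .detection import ModelSpec
from .likelihood import PriorSpec

_EPS = 1e-300
_CLIP = 50.0


def _lse(col: np.ndarray) -> float:
    """log-sum-exp of a dense vector (hot path; avoids scipy overhead)."""
    m = float(col.max())
    return m + math.log(float(np.exp(col - m).sum()))


@dataclass
class MCMCConfig:
    """Run-length, proposal and seeding settings for one fit.

    The full-scale configuration used for a real survey of this kind is
    5 chains x 320,000 iterations (10,000 adaptation, 20,000 burn-in);
    the defaults here are the scaled-down settings used for simulation
    experiments.
    """

    n_chains: int = 3
    n_iter: int = 20000
    n_adapt: int = 2000
    n_burn: int = 3000
    thin: int = 1
    seed: int = 0
    beta_scale: float = 0.3
    logsigma_scale: float = 0.3
    center_window: int = 2        # +-cells of the local center proposal
    center_global_prob: float = 0.1
    adapt_target: float = 0.3
    store_centers: bool = True
    debug_checks: bool = False

    def __post_init__(self) -> None:
        if self.n_adapt + self.n_burn >= self.n_iter:
            raise ValueError("need n_adapt + n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSamples:
    """Retained draws (per chain) plus diagnostics and run metadata."""

    draws: dict                      # name -> (n_chains, n_kept[, K]) arrays
    coef_names: list
    center_trace: list | None        # per chain: list of full-grid cell arrays
    diagnostics: dict
    model: str
    marks: str
    config: MCMCConfig
    seeds: list

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled, shape (n_chains * n_kept, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        nc, nk = self.draws["N"].shape
        cols["chain"] = np.repeat(np.arange(nc), nk)
        cols["iteration"] = np.tile(np.arange(nk), nc)
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                cols[name] = arr.reshape(-1)
            else:
                for k in range(arr.shape[2]):
                    cols[self.coef_names[k]] = arr[:, :, k].reshape(-1)
        return pd.DataFrame(cols)

    def save(self, directory) -> None:
        """Samples as CSV plus a JSON metadata sidecar."""
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / "samples.csv", index=False)
        meta = {
            "model": self.model,
            "marks": self.marks,
            "coef_names": self.coef_names,
            "seeds": [int(s) for s in self.seeds],
            "config": {k: (v if not isinstance(v, np.generic) else v.item())
                       for k, v in asdict(self.config).items()},
            "diagnostics": _jsonable(self.diagnostics),
        }
        with open(directory / "run_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


class _Entity:
    """One active (z = 1) latent individual in the chain state."""

    __slots__ = ("kind", "obs", "ev_j", "ev_t", "ev_y", "ev_b", "f",
                 "counts", "center", "A", "B")

    def __init__(self, kind, obs, ev_j, ev_t, ev_y, f):
        self.kind = kind          # "known" | "left" | "right" | "pair"
        self.obs = obs            # observed-record index or (left, right)
        self.ev_j = ev_j
        self.ev_t = ev_t
        self.ev_y = ev_y
        self.f = f                # first-detection occasion (0-based)
        self.ev_b = None          # behavior flag per event (Mc)
        self.counts = np.bincount(ev_y, minlength=5)[1:].astype(float)
        self.center = -1          # index into suitable cells
        self.A = None             # (J,) pre-first-capture occasion counts (Mc)
        self.B = None


class _Chain:
    """Workspace and update sweep for a single Markov chain."""

    def __init__(self, data: ObservedEncounterData, grid: HabitatGrid,
                 traps: TrapArray, model: ModelSpec, priors: PriorSpec,
                 config: MCMCConfig, rng: np.random.Generator,
                 marks: str = "dual"):
        self.data = data
        self.grid = grid
        self.traps = traps
        self.model = model
        self.priors = priors
        self.config = config
        self.rng = rng
        self.marks = marks
        self.kernel = "halfnormal"

        # --- static geometry -------------------------------------------------
        self.suit = grid.suitable_cells
        self.Qs = self.suit.size
        S = grid.centroids[self.suit]
        d = np.linalg.norm(S[:, None, :] - traps.xy[None, :, :], axis=2)
        self.dist = d                              # (Qs, J)
        self.dist2 = d ** 2
        self.full2suit = np.full(grid.n_cells, -1, dtype=int)
        self.full2suit[self.suit] = np.arange(self.Qs)
        self.suit_row, self.suit_col = grid.rowcol(self.suit)

        self.J = traps.n_traps
        self.T = traps.n_occasions
        op = traps.operation.astype(float)
        self.effT = op.sum(axis=1)                 # (J,)
        self.cumop = np.cumsum(op, axis=1)         # (J, T)

        self.X = model.trap_covariates(traps)
        self.K = model.n_coef

        # --- observed records ------------------------------------------------
        if marks == "single":
            hists = list(data.known) + list(data.left) + list(data.right)
            kinds = ["known"] * len(hists)
        else:
            hists = list(data.known) + list(data.left) + list(data.right)
            kinds = (["known"] * data.n_known + ["left"] * data.n1
                     + ["right"] * data.n2)
        self.n_obs = len(hists)
        if self.n_obs == 0:
            raise ValueError("no observed records")
        self.obs_kind = kinds
        self.obs_ev = []
        for h in hists:
            if np.any((h > 0) & (traps.operation == 0)):
                raise ValueError("detection at a non-operational trap-occasion")
            jj, tt = np.nonzero(h)
            order = np.argsort(tt, kind="stable")
            jj, tt = jj[order], tt[order]
            self.obs_ev.append((jj.astype(int), tt.astype(int),
                                h[jj, tt].astype(int)))
        self.obs_f = np.array([ev[1][0] for ev in self.obs_ev])
        # flattened per-record events for column refreshes
        self.OEV_rec = np.concatenate([np.full(len(ev[0]), r)
                                       for r, ev in enumerate(self.obs_ev)])
        self.OEV_j = np.concatenate([ev[0] for ev in self.obs_ev])
        self.OEV_t = np.concatenate([ev[1] for ev in self.obs_ev])
        self.OEV_b = (self.OEV_t > self.obs_f[self.OEV_rec]) \
            if model.has_behavior else np.zeros(len(self.OEV_j), dtype=bool)
        self.obs_bounds = np.searchsorted(self.OEV_rec,
                                          np.arange(self.n_obs + 1))
        if model.has_behavior:
            fA = self.cumop[:, self.obs_f]                 # (J, n_obs)
            self.obs_A = fA
            self.obs_B = self.effT[:, None] - fA
        # left/right observed-record index offsets (dual-mark mode)
        self.off_left = data.n_known if marks == "dual" else 0
        self.off_right = data.n_known + data.n1 if marks == "dual" else 0

        # --- dynamic state ---------------------------------------------------
        self.entities: list[_Entity] = []
        self.pairs: list[tuple[int, int]] = []     # (left obs-local, right obs-local)
        self.delta1 = 0.25
        self.delta2 = 0.25
        self.alpha = 0.5
        self.psi = 0.5
        self.beta = np.zeros(self.K)
        self.sigma = math.sqrt(priors.sigma_lo * priors.sigma_hi)
        self.N = 1
        self.cache: dict | None = None
        self._aev_dirty = True
        self._idx_dirty = True
        self._ll_site = -math.inf
        self.beta_scale = config.beta_scale
        self.logsigma_scale = config.logsigma_scale
        self.acc = {"beta": 0, "sigma": 0, "center": 0, "match": 0}
        self.tries = {"beta": 0, "sigma": 0, "center": 0, "match": 0}
        self._init_state()

    # -- initialization -------------------------------------------------------

    def _make_entity(self, kind, obs) -> _Entity:
        if kind == "pair":
            l, r = obs
            gl, gr = self.off_left + l, self.off_right + r
            j1, t1, y1 = self.obs_ev[gl]
            j2, t2, y2 = self.obs_ev[gr]
            keys = np.concatenate([j1 * self.T + t1, j2 * self.T + t2])
            ys = np.concatenate([y1, y2])
            order = np.argsort(keys, kind="stable")
            keys, ys = keys[order], ys[order]
            if len(keys) > 1:
                dup = keys[1:] == keys[:-1]
                if dup.any():                  # 1 + 2 at one trap-occasion -> 3
                    ys[:-1][dup] = 3
                    keep = np.ones(len(keys), dtype=bool)
                    keep[1:][dup] = False
                    keys, ys = keys[keep], ys[keep]
            ev_j, ev_t = keys // self.T, keys % self.T
            ev_y = ys
            f = int(ev_t.min())
        else:
            g = {"known": obs, "left": self.off_left + obs,
                 "right": self.off_right + obs}[kind]
            ev_j, ev_t, ev_y = self.obs_ev[g]
            f = int(self.obs_f[g])
        ent = _Entity(kind, obs, ev_j, ev_t, ev_y, f)
        if self.model.has_behavior:
            ent.ev_b = ev_t > f
            ent.A = self.cumop[:, f].copy()
            ent.B = self.effT - ent.A
        else:
            ent.ev_b = np.zeros(len(ev_j), dtype=bool)
        return ent

    def _init_state(self) -> None:
        # all singles start unmatched; every record is its own individual
        for g, kind in enumerate(self.obs_kind):
            if self.marks == "single":
                ent = self._make_entity("known", g)
            elif kind == "known":
                ent = self._make_entity("known", g)
            elif kind == "left":
                ent = self._make_entity("left", g - self.off_left)
            else:
                ent = self._make_entity("right", g - self.off_right)
            # center: suitable cell nearest the mean detection location
            mean_xy = self.traps.xy[ent.ev_j].mean(axis=0)
            dist = np.linalg.norm(self.grid.centroids[self.suit] - mean_xy, axis=1)
            ent.center = int(np.argmin(dist))
            self.entities.append(ent)
        self._refresh_cache()
        ps = self.cache["pstar"]
        self.N = max(self.n, math.ceil(self.n / max(ps, 0.1)))
        if not math.isfinite(self._detect_loglik_current()):
            raise RuntimeError("non-finite log-likelihood at initialization")

    # -- derived quantities ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.entities)

    @property
    def log_n_suit(self) -> float:
        return math.log(self.Qs)

    def _log_consts(self) -> np.ndarray:
        """log encounter-type constants for codes 1..4 at current delta/alpha."""
        if self.marks == "single":
            return np.zeros(4)
        d1, d2, a = self.delta1, self.delta2, self.alpha
        rest = max(1.0 - d1 - d2, _EPS)
        return np.log(np.maximum(
            [d1, d2, rest * (1 - a), rest * a], _EPS))

    def counts_total(self) -> np.ndarray:
        c = np.zeros(4)
        for e in self.entities:
            c += e.counts
        return c

    # -- detection cache ------------------------------------------------------

    def _build_cache(self, beta: np.ndarray, sigma: float) -> dict:
        xb = self.X @ beta
        if self.kernel == "halfnormal":
            logg = self.dist2 * (-0.5 / sigma ** 2)
        else:
            logg = self.dist * (-1.0 / sigma)
        eta0 = np.minimum(xb[None, :] + logg, _CLIP)
        l1p0 = -np.exp(eta0)                       # log(1 - p)
        cache = {"l1p0": l1p0, "base0": l1p0 @ self.effT}
        if self.model.has_behavior:
            eta1 = np.minimum(eta0 + self.model.behavior_coef(beta), _CLIP)
            cache["l1p1"] = -np.exp(eta1)
        cache["pstar"] = float(1.0 - np.exp(cache["base0"]).mean())
        return cache

    @staticmethod
    def _corr_of(l1p_vals: np.ndarray) -> np.ndarray:
        """log p - log(1 - p) from gathered log-survival values."""
        return np.log(np.maximum(-np.expm1(l1p_vals), _EPS)) - l1p_vals

    def _refresh_cache(self) -> None:
        """Recompute the detection cache and site likelihood in place."""
        self.cache = self._build_cache(self.beta, self.sigma)
        self._ll_site = self._site_ll(self.cache)

    # per-record likelihood columns are never stored: they are built on
    # demand (full column only where a logsumexp/softmax over cells is
    # needed; otherwise single-cell point evaluations)

    def _col_from(self, ev_j, ev_b, A, B) -> np.ndarray:
        cache = self.cache
        if self.model.has_behavior:
            col = cache["l1p0"] @ A + cache["l1p1"] @ B
            for j, b in zip(ev_j, ev_b):
                vals = cache["l1p1"][:, j] if b else cache["l1p0"][:, j]
                col = col + self._corr_of(vals)
            return col
        col = cache["base0"].copy()
        for j in ev_j:
            col += self._corr_of(cache["l1p0"][:, j])
        return col

    def _col_entity(self, ent: _Entity) -> np.ndarray:
        return self._col_from(ent.ev_j, ent.ev_b, ent.A, ent.B)

    def _col_obsrec(self, g: int) -> np.ndarray:
        """Column of observed record g, memoized per detection cache."""
        cols = self.cache.setdefault("cols", {})
        col = cols.get(g)
        if col is None:
            sl = slice(self.obs_bounds[g], self.obs_bounds[g + 1])
            A = self.obs_A[:, g] if self.model.has_behavior else None
            B = self.obs_B[:, g] if self.model.has_behavior else None
            col = self._col_from(self.OEV_j[sl], self.OEV_b[sl], A, B)
            cols[g] = col
        return col

    def _point_from(self, ev_j, ev_b, A, B, c: int) -> float:
        cache = self.cache
        if self.model.has_behavior:
            base = float(cache["l1p0"][c] @ A + cache["l1p1"][c] @ B)
            vals = np.where(ev_b, cache["l1p1"][c, ev_j], cache["l1p0"][c, ev_j])
        else:
            base = float(cache["base0"][c])
            vals = cache["l1p0"][c, ev_j]
        return base + float(self._corr_of(vals).sum())

    def _point_entity(self, ent: _Entity, c: int) -> float:
        return self._point_from(ent.ev_j, ent.ev_b, ent.A, ent.B, c)

    def _point_obsrec(self, g: int, c: int) -> float:
        sl = slice(self.obs_bounds[g], self.obs_bounds[g + 1])
        A = self.obs_A[:, g] if self.model.has_behavior else None
        B = self.obs_B[:, g] if self.model.has_behavior else None
        return self._point_from(self.OEV_j[sl], self.OEV_b[sl], A, B, c)

    def _global_idx(self, ent: _Entity) -> int:
        if ent.kind == "known":
            return ent.obs
        if ent.kind == "left":
            return self.off_left + ent.obs
        return self.off_right + ent.obs

    def _refresh_aev(self) -> None:
        """Flat active-event arrays for fast likelihood at current centers."""
        ents = self.entities
        lens = [len(e.ev_j) for e in ents]
        self.AEV_ent = np.repeat(np.arange(len(ents)), lens)
        self.AEV_j = np.concatenate([e.ev_j for e in ents])
        self.AEV_b = np.concatenate([e.ev_b for e in ents])
        if self.model.has_behavior:
            self.act_A = np.column_stack([e.A for e in self.entities])
            self.act_B = np.column_stack([e.B for e in self.entities])
        self._aev_dirty = False

    def _site_ll(self, cache: dict) -> float:
        """Detection log-likelihood of all active records at their centers
        under ``cache`` (no population binomial factor)."""
        if self._aev_dirty:
            self._refresh_aev()
        centers = self._centers_arr()
        if self.model.has_behavior:
            rows0 = cache["l1p0"][centers]        # (n, J)
            rows1 = cache["l1p1"][centers]
            base = np.einsum("ij,ji->i", rows0, self.act_A) \
                + np.einsum("ij,ji->i", rows1, self.act_B)
            vals = np.where(self.AEV_b,
                            cache["l1p1"][centers[self.AEV_ent], self.AEV_j],
                            cache["l1p0"][centers[self.AEV_ent], self.AEV_j])
        else:
            base = cache["base0"][centers]
            vals = cache["l1p0"][centers[self.AEV_ent], self.AEV_j]
        return float(base.sum() + self._corr_of(vals).sum())

    def _centers_arr(self) -> np.ndarray:
        return np.fromiter((e.center for e in self.entities), dtype=int,
                           count=self.n)

    def _binom_term(self, pstar: float) -> float:
        n, N = self.n, self.N
        total = float(gammaln(N + 1) - gammaln(N - n + 1))
        if N > n:
            if pstar >= 1.0:
                return -math.inf
            total += (N - n) * math.log1p(-pstar)
        return total

    def _detect_loglik_current(self) -> float:
        return self._ll_site + self._binom_term(self.cache["pstar"])

    # -- parameter updates ----------------------------------------------------

    def _update_beta(self, adapt: bool, step: int) -> None:
        self.tries["beta"] += 1
        prop = self.beta + self.beta_scale * self.rng.standard_normal(self.K)
        cache = self._build_cache(prop, self.sigma)
        ls_new = self._site_ll(cache)
        lr = (ls_new - self._ll_site
              + self._binom_term(cache["pstar"])
              - self._binom_term(self.cache["pstar"])
              - 0.5 * float(np.sum((prop - self.priors.mu_beta) ** 2)
                            - np.sum((self.beta - self.priors.mu_beta) ** 2))
              / self.priors.var_beta)
        accepted = math.log(self.rng.random() + _EPS) < lr
        if accepted:
            self.acc["beta"] += 1
            self.beta = prop
            self.cache = cache
            self._ll_site = ls_new
        if adapt:
            gamma = min(0.25, 1.0 / math.sqrt(step + 1))
            self.beta_scale *= math.exp(
                gamma * ((1.0 if accepted else 0.0) - self.config.adapt_target))

    def _update_sigma(self, adapt: bool, step: int) -> None:
        self.tries["sigma"] += 1
        prop = self.sigma * math.exp(self.logsigma_scale * self.rng.standard_normal())
        accepted = False
        if self.priors.sigma_lo <= prop <= self.priors.sigma_hi:
            cache = self._build_cache(self.beta, prop)
            # uniform prior on sigma, log-scale proposal => Jacobian sigma'/sigma
            ls_new = self._site_ll(cache)
            lr = (ls_new - self._ll_site
                  + self._binom_term(cache["pstar"])
                  - self._binom_term(self.cache["pstar"])
                  + math.log(prop) - math.log(self.sigma))
            accepted = math.log(self.rng.random() + _EPS) < lr
            if accepted:
                self.acc["sigma"] += 1
                self.sigma = prop
                self.cache = cache
                self._ll_site = ls_new
        if adapt:
            gamma = min(0.25, 1.0 / math.sqrt(step + 1))
            self.logsigma_scale *= math.exp(
                gamma * ((1.0 if accepted else 0.0) - self.config.adapt_target))

    def _update_delta_alpha_psi(self) -> None:
        if self.marks == "single":
            return
        c1, c2, c3, c4 = self.counts_total()
        pr = self.priors
        if pr.delta_constraint == "equal":
            u = self.rng.beta(pr.a_delta + c1 + c2, pr.c_delta + c3 + c4)
            self.delta1 = self.delta2 = u / 2.0
        else:
            d = self.rng.dirichlet([pr.a_delta + c1, pr.b_delta + c2,
                                    pr.c_delta + c3 + c4])
            self.delta1, self.delta2 = float(d[0]), float(d[1])
        self.alpha = float(self.rng.beta(pr.a_alpha + c4, pr.b_alpha + c3))
        n_ghost = len(self.pairs)
        self.psi = float(self.rng.beta(pr.a_psi + self.n,
                                       pr.b_psi + n_ghost))

    def _update_N(self) -> None:
        ps = self.cache["pstar"]
        if ps <= 0.0:
            raise RuntimeError("p* = 0: conditional for N is improper")
        if ps >= 1.0:
            self.N = self.n
            return
        self.N = self.n + int(self.rng.negative_binomial(self.n, ps))

    # -- activity-center moves ------------------------------------------------

    def _update_centers(self) -> None:
        n = self.n
        centers = self._centers_arr()
        w = self.config.center_window
        u = self.rng.random(2 * n)
        use_global = u[:n] < self.config.center_global_prob
        # local window proposal on the full-grid row/col lattice
        dd = self.rng.integers(-w, w + 1, size=2 * n)
        row = self.suit_row[centers] + dd[:n]
        col = self.suit_col[centers] + dd[n:]
        ok = (row >= 0) & (row < self.grid.nrow) & (col >= 0) & (col < self.grid.ncol)
        cand = np.full(n, -1, dtype=int)
        full = row[ok] * self.grid.ncol + col[ok]
        cand[ok] = self.full2suit[full]            # -1 if unsuitable
        glob = self.rng.integers(0, self.Qs, size=n)
        cand = np.where(use_global, glob, cand)
        valid = cand >= 0
        cand_safe = np.where(valid, cand, centers)
        if self._aev_dirty:
            self._refresh_aev()
        cache = self.cache
        if self.model.has_behavior:
            base_new = np.einsum("ij,ji->i", cache["l1p0"][cand_safe], self.act_A) \
                + np.einsum("ij,ji->i", cache["l1p1"][cand_safe], self.act_B)
            base_old = np.einsum("ij,ji->i", cache["l1p0"][centers], self.act_A) \
                + np.einsum("ij,ji->i", cache["l1p1"][centers], self.act_B)
            rows_new = cand_safe[self.AEV_ent]
            rows_old = centers[self.AEV_ent]
            vals_new = np.where(self.AEV_b, cache["l1p1"][rows_new, self.AEV_j],
                                cache["l1p0"][rows_new, self.AEV_j])
            vals_old = np.where(self.AEV_b, cache["l1p1"][rows_old, self.AEV_j],
                                cache["l1p0"][rows_old, self.AEV_j])
        else:
            base_new = cache["base0"][cand_safe]
            base_old = cache["base0"][centers]
            vals_new = cache["l1p0"][cand_safe[self.AEV_ent], self.AEV_j]
            vals_old = cache["l1p0"][centers[self.AEV_ent], self.AEV_j]
        ev_delta = np.bincount(self.AEV_ent,
                               weights=self._corr_of(vals_new)
                               - self._corr_of(vals_old), minlength=n)
        delta = base_new - base_old + ev_delta
        delta[~valid] = -np.inf
        accept = np.log(u[n:] + _EPS) < delta
        self.tries["center"] += n
        self.acc["center"] += int(accept.sum())
        if accept.any():
            for i in np.flatnonzero(accept):
                self.entities[i].center = int(cand[i])
            self._ll_site += float(delta[accept].sum())

    # -- matching moves -------------------------------------------------------

    def _entity_indices(self):
        if self._idx_dirty:
            lefts, rights, prs = [], [], []
            for i, e in enumerate(self.entities):
                if e.kind == "left":
                    lefts.append(i)
                elif e.kind == "right":
                    rights.append(i)
                elif e.kind == "pair":
                    prs.append(i)
            self._lists = (lefts, rights, prs)
            self._idx_dirty = False
        return self._lists

    def _log1m_ps(self) -> float:
        return math.log1p(-min(self.cache["pstar"], 1 - 1e-12))

    def _update_matching(self, lc: np.ndarray | None = None) -> None:
        """One LINK/UNLINK/SWAP attempt (40/40/20)."""
        self.tries["match"] += 1
        u = self.rng.random()
        lefts, rights, prs = self._entity_indices()
        if lc is None:
            lc = self._log_consts()
        psi = min(max(self.psi, 1e-12), 1 - 1e-12)
        if u < 0.4:       # LINK
            if not lefts or not rights:
                return
            li = lefts[int(self.rng.integers(len(lefts)))]
            ri = rights[int(self.rng.integers(len(rights)))]
            eL, eR = self.entities[li], self.entities[ri]
            merged = self._make_entity("pair", (eL.obs, eR.obs))
            merged.center = eL.center
            dconst = float((merged.counts - eL.counts - eR.counts) @ lc)
            colR = self._col_obsrec(self.off_right + eR.obs)
            lseR = _lse(colR)
            pm = self._point_entity(merged, eL.center)
            pl = self._point_entity(eL, eL.center)
            dsite = pm - pl - float(colR[eR.center])
            logA = (pm - pl + dconst
                    - lseR
                    - math.log(self.N - self.n + 1) + self._log1m_ps()
                    + self.log_n_suit
                    + math.log1p(-psi) - math.log(psi)
                    - math.log(len(prs) + 1)
                    + math.log(len(lefts)) + math.log(len(rights)))
            if math.log(self.rng.random() + _EPS) < logA:
                self.acc["match"] += 1
                for i in sorted((li, ri), reverse=True):
                    del self.entities[i]
                self.entities.append(merged)
                self.pairs.append((eL.obs, eR.obs))
                self._ll_site += dsite
                self._after_match_change()
        elif u < 0.8:     # UNLINK
            if not prs:
                return
            if self.N - self.n < 1:
                return
            pi = prs[int(self.rng.integers(len(prs)))]
            eM = self.entities[pi]
            lobs, robs = eM.obs
            gl, gr = self.off_left + lobs, self.off_right + robs
            colR = self._col_obsrec(gr)
            # reactivated center ~ softmax of the right record's column
            cmax = float(colR.max())
            cw = np.cumsum(np.exp(colR - cmax))
            lseR = cmax + math.log(float(cw[-1]))
            s_r = int(np.searchsorted(cw, self.rng.random() * float(cw[-1])))
            eLn = self._make_entity("left", lobs)
            eRn = self._make_entity("right", robs)
            dconst = float((eLn.counts + eRn.counts - eM.counts) @ lc)
            pl = self._point_obsrec(gl, eM.center)
            pm = self._point_entity(eM, eM.center)
            dsite = pl + float(colR[s_r]) - pm
            logA = (pl - pm + dconst
                    + lseR
                    + math.log(self.N - self.n) - self._log1m_ps()
                    - self.log_n_suit
                    + math.log(psi) - math.log1p(-psi)
                    + math.log(len(prs))
                    - math.log(len(lefts) + 1) - math.log(len(rights) + 1))
            if math.log(self.rng.random() + _EPS) < logA:
                self.acc["match"] += 1
                eLn.center = eM.center
                eRn.center = s_r
                del self.entities[pi]
                self.entities.extend([eLn, eRn])
                self.pairs.remove((lobs, robs))
                self._ll_site += dsite
                self._after_match_change()
        else:             # SWAP
            if len(prs) < 2:
                return
            k1, k2 = self.rng.choice(len(prs), size=2, replace=False)
            p1, p2 = self.entities[prs[k1]], self.entities[prs[k2]]
            (l1, r1), (l2, r2) = p1.obs, p2.obs
            m1 = self._make_entity("pair", (l1, r2))
            m2 = self._make_entity("pair", (l2, r1))
            m1.center, m2.center = p1.center, p2.center
            dconst = float((m1.counts + m2.counts - p1.counts - p2.counts) @ lc)
            dsite = (self._point_entity(m1, m1.center)
                     + self._point_entity(m2, m2.center)
                     - self._point_entity(p1, p1.center)
                     - self._point_entity(p2, p2.center))
            logA = dsite + dconst
            if math.log(self.rng.random() + _EPS) < logA:
                self.acc["match"] += 1
                self.entities[prs[k1]] = m1
                self.entities[prs[k2]] = m2
                self.pairs.remove((l1, r1))
                self.pairs.remove((l2, r2))
                self.pairs.extend([(l1, r2), (l2, r1)])
                self._ll_site += dsite
                self._after_match_change()

    def _after_match_change(self) -> None:
        self._aev_dirty = True
        self._idx_dirty = True
        if self.N < self.n:
            self.N = self.n
        if self.config.debug_checks and self.marks == "dual":
            assert is_feasible(MatchState(pairs=list(self.pairs)), self.data)

    # -- sweep ----------------------------------------------------------------

    def sweep(self, it: int) -> None:
        adapt = it < self.config.n_adapt
        self._update_beta(adapt, it)
        self._update_sigma(adapt, it)
        self._update_delta_alpha_psi()
        self._update_N()
        self._update_centers()
        if self.marks == "dual" and (self.data.n1 or self.data.n2):
            # several attempts per sweep scale with the number of single-
            # flank records (the only records the matching can move)
            n_attempts = max(1, (self.data.n1 + self.data.n2 + 3) // 4)
            lc = self._log_consts()
            for _ in range(n_attempts):
                self._update_matching(lc)

    def log_posterior_value(self) -> float:
        """Unnormalized log posterior at the current state (for traces)."""
        lp = self._detect_loglik_current()
        lp += float(self.counts_total() @ self._log_consts())
        pr = self.priors
        lp += -0.5 * float(np.sum((self.beta - pr.mu_beta) ** 2)) / pr.var_beta
        lp -= math.log(self.N)
        lp -= self.n * self.log_n_suit
        if self.marks == "dual":
            psi = min(max(self.psi, 1e-12), 1 - 1e-12)
            lp += self.n * math.log(psi) + len(self.pairs) * math.log1p(-psi)
        return lp


# ---------------------------------------------------------------------------
# Diagnostics

def multivariate_psrf(chains: np.ndarray) -> float:
    """Brooks-Gelman multivariate potential scale reduction factor.

    ``chains``: (m, n, k) array of m chains, n draws, k parameters.
    """
    m, n, k = chains.shape
    means = chains.mean(axis=1)
    W = np.zeros((k, k))
    for c in range(m):
        dev = chains[c] - means[c]
        W += dev.T @ dev / (n - 1)
    W /= m
    grand = means.mean(axis=0)
    dev_m = means - grand
    B_over_n = dev_m.T @ dev_m / (m - 1)
    lam = np.linalg.eigvals(np.linalg.solve(W + 1e-10 * np.eye(k), B_over_n))
    lam1 = float(np.max(lam.real))
    return math.sqrt((n - 1) / n + (m + 1) / m * lam1)


def split_psrf(chains: np.ndarray) -> float:
    """Classic univariate split-chain Gelman-Rubin statistic.

    ``chains``: (m, n) array; each chain is split in half, giving 2m
    sequences, and the usual between/within variance ratio is returned.
    """
    m, n = chains.shape
    half = n // 2
    seqs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    n2 = half
    means = seqs.mean(axis=1)
    W = seqs.var(axis=1, ddof=1).mean()
    B = n2 * means.var(ddof=1)
    var_hat = (n2 - 1) / n2 * W + B / n2
    return math.sqrt(var_hat / W)


def _diagnostics(draws: dict, coef_names: list, marks: str) -> dict:
    import logging
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az
    logging.getLogger("arviz").setLevel(logging.ERROR)
    mon = {"log_N": np.log(draws["N"].astype(float)),
           "log_sigma": np.log(draws["sigma"])}
    for k, name in enumerate(coef_names):
        mon[name] = draws["beta"][:, :, k]
    def logit(x):
        x = np.clip(x, 1e-9, 1 - 1e-9)
        return np.log(x / (1 - x))
    if marks == "dual":
        mon["logit_u"] = logit(draws["delta1"] + draws["delta2"])
        mon["logit_alpha"] = logit(draws["alpha"])
        mon["logit_psi"] = logit(draws["psi"])
    out = {"psrf": {}, "ess": {}}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={k: v for k, v in mon.items()})
        rhat = az.rhat(idata, method="split")
        ess = az.ess(idata)
    for k in mon:
        out["psrf"][k] = float(rhat[k].values)
        out["ess"][k] = float(ess[k].values)
    names = [k for k in mon if np.ptp(mon[k]) > 1e-12]
    if len(names) >= 1 and draws["N"].shape[0] >= 2:
        stack = np.stack([mon[k] for k in names], axis=-1)
        out["mpsrf"] = multivariate_psrf(stack)
    out["max_psrf"] = max(out["psrf"].values())
    out["min_ess"] = min(out["ess"].values())
    return out


# ---------------------------------------------------------------------------
# Driver

def run(data: ObservedEncounterData, grid: HabitatGrid, traps: TrapArray,
        model: ModelSpec | str, priors: PriorSpec | None = None,
        config: MCMCConfig | None = None, marks: str = "dual",
        max_init_retries: int = 10) -> PosteriorSamples:
    """Fit the model by MCMC and return retained posterior draws.

    ``marks="dual"`` fits the two-mark partial-identity model (latent
    matching sampled); ``marks="single"`` fits the conventional SCR
    model treating every record as an identified individual (no
    encounter-type probabilities, no matching).
    """
    if isinstance(model, str):
        model = ModelSpec(model)
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    if marks not in ("dual", "single"):
        raise ValueError("marks must be 'dual' or 'single'")
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_chains)
    keep_from = config.n_adapt + config.n_burn
    kept_iters = range(keep_from, config.n_iter, config.thin)
    n_kept = len(kept_iters)
    kept_set = set(kept_iters)

    all_draws = {k: [] for k in ("N", "sigma", "beta", "delta1", "delta2",
                                 "alpha", "psi", "n", "pstar", "logpost")}
    center_trace: list | None = [] if config.store_centers else None
    seeds_used = []
    for c, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        seeds_used.append(cs.entropy if isinstance(cs.entropy, int) else config.seed)
        chain = None
        for attempt in range(max_init_retries):
            try:
                chain = _Chain(data, grid, traps, model, priors, config, rng,
                               marks=marks)
                break
            except RuntimeError:
                continue
        if chain is None:
            raise RuntimeError("failed to initialize chain with finite posterior")
        rec = {k: np.empty(n_kept) for k in all_draws}
        rec["beta"] = np.empty((n_kept, chain.K))
        ctrace = [] if config.store_centers else None
        pos = 0
        for it in range(config.n_iter):
            chain.sweep(it)
            if it in kept_set:
                rec["N"][pos] = chain.N
                rec["sigma"][pos] = chain.sigma
                rec["beta"][pos] = chain.beta
                rec["delta1"][pos] = chain.delta1
                rec["delta2"][pos] = chain.delta2
                rec["alpha"][pos] = chain.alpha
                rec["psi"][pos] = chain.psi
                rec["n"][pos] = chain.n
                rec["pstar"][pos] = chain.cache["pstar"]
                rec["logpost"][pos] = chain.log_posterior_value()
                if ctrace is not None:
                    cells = chain.suit[[e.center for e in chain.entities]]
                    ctrace.append(cells.copy())
                pos += 1
        for k in all_draws:
            all_draws[k].append(rec[k])
        if center_trace is not None:
            center_trace.append(ctrace)

    draws = {k: np.stack(v) for k, v in all_draws.items()}
    coef_names = model.coef_names
    diags = _diagnostics(draws, coef_names, marks)
    return PosteriorSamples(draws=draws, coef_names=coef_names,
                            center_trace=center_trace, diagnostics=diags,
                            model=model.name, marks=marks, config=config,
                            seeds=[config.seed + i for i in range(config.n_chains)])
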