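"""Distance-based detection probability under the cloglog link.

The per-occasion detection probability of individual i at trap j is

    cloglog(p_ij) = x_j' beta + log g(d_ij)

with g the half-normal kernel exp(-d^2 / (2 sigma^2)) (or exponential
exp(-d / sigma)) and d_ij the Euclidean distance from the trap to the
individual's activity center.  A convenient identity under this link:
log(1 - p) = -exp(eta), so survival probabilities need one exponential.

Candidate detection models:

    M0    constant baseline (intercept only)
    Me    + standardized trap elevation
    Mc    + enduring behavioral response to first capture
    Me+c  additive elevation and behavioral effects
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encounter_data import TrapArray
from .state_space import HabitatGrid

# linear predictor clip before double exponentiation
_ETA_CLIP = 50.0

MODEL_NAMES = ("M0", "Me", "Mc", "Me+c")


@dataclass
class DetectionParams:
    """Detection-scale parameters: coefficients + spatial scale."""

    beta: np.ndarray        # (K,) cloglog-scale coefficients, intercept first
    sigma: float            # meters
    kernel: str = "halfnormal"

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.kernel not in ("halfnormal", "exponential"):
            raise ValueError(f"unknown kernel: {self.kernel!r}")


@dataclass
class ModelSpec:
    """One of the four candidate detection models.

    Coefficient layout: [intercept, elevation?, behavior?].  The trap
    elevation covariate is standardized (mean 0, sd 1 over traps) so the
    weakly informative normal coefficient priors act on a common scale.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}")

    @property
    def has_elevation(self) -> bool:
        return self.name in ("Me", "Me+c")

    @property
    def has_behavior(self) -> bool:
        return self.name in ("Mc", "Me+c")

    @property
    def n_coef(self) -> int:
        return 1 + self.has_elevation + self.has_behavior

    @property
    def coef_names(self) -> list[str]:
        names = ["beta0"]
        if self.has_elevation:
            names.append("beta_elev")
        if self.has_behavior:
            names.append("beta_behav")
        return names

    def trap_covariates(self, traps: TrapArray) -> np.ndarray:
        """Static (J, K) design matrix; the behavior column is all zero.

        The behavioral state is individual- and occasion-specific and is
        applied by adding the behavior coefficient to the linear
        predictor when the individual has a prior capture.
        """
        cols = [np.ones(traps.n_traps)]
        if self.has_elevation:
            elev = traps.elevation
            sd = elev.std()
            cols.append((elev - elev.mean()) / sd if sd > 0 else np.zeros_like(elev))
        if self.has_behavior:
            cols.append(np.zeros(traps.n_traps))
        return np.column_stack(cols)

    def behavior_coef(self, beta: np.ndarray) -> float:
        return float(beta[-1]) if self.has_behavior else 0.0


def kernel_g(d, sigma: float, kernel: str = "halfnormal"):
    """Distance kernel g(d): 1 at d = 0, strictly decreasing."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if kernel == "halfnormal":
        return np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    if kernel == "exponential":
        return np.exp(-d / sigma)
    raise ValueError(f"unknown kernel: {kernel!r}")


def log_kernel_g(d, sigma: float, kernel: str = "halfnormal"):
    d = np.asarray(d, dtype=float)
    if kernel == "halfnormal":
        return -(d ** 2) / (2.0 * sigma ** 2)
    return -d / sigma


def cloglog_inv(eta):
    """p = 1 - exp(-exp(eta)), with eta clipped to +-50 for stability."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return -np.expm1(-np.exp(eta))


def log1m_p(eta):
    """log(1 - p) = -exp(eta) under the cloglog link."""
    return -np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def p_detect(x: np.ndarray, params: DetectionParams, d) -> np.ndarray:
    """Detection probability for covariate row(s) x at distance(s) d."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    xb = x @ params.beta if x.ndim > 0 else x * params.beta
    return cloglog_inv(xb + log_kernel_g(d, params.sigma, params.kernel))


def detection_eta(params: DetectionParams, model: ModelSpec,
                  grid_xy: np.ndarray, traps: TrapArray) -> np.ndarray:
    """Linear predictor eta[q, j] at behavior state 0 for given points."""
    X = model.trap_covariates(traps)
    xb = X @ params.beta  # (J,)
    d = np.linalg.norm(grid_xy[:, None, :] - traps.xy[None, :, :], axis=2)
    return xb[None, :] + log_kernel_g(d, params.sigma, params.kernel)


def pstar(params: DetectionParams, model: ModelSpec,
          grid: HabitatGrid, traps: TrapArray) -> float:
    """P(detected at least once), averaged over suitable grid cells.

    p* = 1 - sum_q h_q prod_j prod_t (1 - m_jt p_qjt) / sum_q h_q.
    The behavioral covariate (Mc) is held at 0: before its first
    detection an individual is by definition uncaptured, so first-
    detection probability does not involve the behavior coefficient.
    """
    suit = grid.suitable_cells
    if suit.size < 1:
        raise ValueError("no suitable cells")
    eta = detection_eta(params, model, grid.centroids[suit], traps)
    eff = traps.operation.sum(axis=1).astype(float)  # occasions operating per trap
    log_surv = log1m_p(eta) @ eff                    # (Qs,) log P(never detected | s_q)
    return float(1.0 - np.exp(log_surv).mean())
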