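"""Derived quantities: density, home-range conversions, posterior surfaces.

Density is reported per 100 km^2 of a reference area — either the full
state space or the suitable-habitat portion of it; in fragmented
landscapes the two can differ substantially and the suitable-habitat
figure is the one comparable across study areas.

The movement scale sigma of a bivariate-normal space-use model converts
to a 95% home-range radius r = sigma * sqrt(chi^2_{0.95, df=2}) and a
home-range area pi r^2.  Reporting follows the printed-arithmetic
convention: the radius is rounded to 2 decimals first and the area is
computed from the rounded radius, then rounded to 1 decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .encounter_data import TrapArray
from .state_space import HabitatGrid
from .detection import DetectionParams, ModelSpec
from .sampler import PosteriorSamples

# sqrt of the 95% quantile of chi-square with 2 df
_HR_FACTOR = math.sqrt(chi2.ppf(0.95, 2))


@dataclass
class DensityResult:
    """Posterior summary of abundance N and density per ``per`` km^2."""

    n_draws: np.ndarray
    density_draws: np.ndarray
    area_km2: float
    per: float
    reference: str = "suitable"

    @property
    def mean(self) -> float:
        return float(self.density_draws.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.density_draws))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.density_draws, [2.5, 97.5])
        return float(lo), float(hi)

    def summary_row(self) -> dict:
        lo, hi = self.ci
        return {"area_km2": self.area_km2, "reference": self.reference,
                "density_mean": self.mean, "density_median": self.median,
                "density_lo95": lo, "density_hi95": hi}


def density_summary(n_samples: np.ndarray, area_km2: float,
                    per: float = 100.0, reference: str = "suitable") -> DensityResult:
    """Scale posterior N draws to density per ``per`` km^2 of ``area_km2``."""
    if area_km2 <= 0:
        raise ValueError("reference area must be > 0")
    n_samples = np.asarray(n_samples, dtype=float)
    return DensityResult(n_draws=n_samples,
                         density_draws=n_samples / area_km2 * per,
                         area_km2=area_km2, per=per, reference=reference)


def hr_radius(sigma_km: float) -> float:
    """95% home-range radius (km) of a bivariate-normal movement model,
    rounded to 2 decimals for reporting."""
    if sigma_km < 0:
        raise ValueError("sigma must be >= 0")
    return round(sigma_km * _HR_FACTOR, 2)


def hr_area(radius_km: float) -> float:
    """Circular home-range area (km^2) from a (rounded) radius,
    rounded to 1 decimal."""
    if radius_km < 0:
        raise ValueError("radius must be >= 0")
    return round(math.pi * radius_km ** 2, 1)


def capture_rate(events: int, trap_nights: float) -> float:
    """Detection events per 100 trap nights, rounded to 2 decimals."""
    if trap_nights <= 0:
        raise ValueError("trap_nights must be > 0")
    if events < 0:
        raise ValueError("events must be >= 0")
    return round(events / trap_nights * 100.0, 2)


def density_surface(samples: PosteriorSamples, grid: HabitatGrid,
                    traps: TrapArray, model: ModelSpec | str,
                    include_undetected: bool = True,
                    max_draws: int = 2000) -> np.ndarray:
    """Posterior expected number of activity centers per grid cell.

    For each retained draw the detected individuals' centers are
    tallied into their cells; the N - n undetected individuals are
    allocated to suitable cells with probability proportional to the
    per-cell probability of total nondetection (their exact
    conditional).  Cells outside suitable habitat get exactly zero.
    The surface sums to the posterior mean of N (within Monte Carlo
    error of the draw subset used).
    """
    if samples.center_trace is None:
        raise ValueError("activity-center traces were not stored; "
                         "rerun with store_centers=True")
    if isinstance(model, str):
        model = ModelSpec(model)
    suit = grid.suitable_cells
    d = np.linalg.norm(grid.centroids[suit][:, None, :] - traps.xy[None, :, :],
                       axis=2)
    effT = traps.operation.sum(axis=1).astype(float)
    X = model.trap_covariates(traps)

    surface = np.zeros(grid.n_cells)
    total = 0
    n_chains = len(samples.center_trace)
    for c in range(n_chains):
        trace = samples.center_trace[c]
        stride = max(1, math.ceil(len(trace) * n_chains / max_draws))
        for i in range(0, len(trace), stride):
            cells = trace[i]
            np.add.at(surface, cells, 1.0)
            if include_undetected:
                N = samples.draws["N"][c, i]
                n = len(cells)
                if N > n:
                    beta = samples.draws["beta"][c, i]
                    sigma = samples.draws["sigma"][c, i]
                    params = DetectionParams(beta=beta, sigma=sigma)
                    xb = X @ params.beta
                    if params.kernel == "halfnormal":
                        logg = -(d ** 2) / (2 * sigma ** 2)
                    else:
                        logg = -d / sigma
                    eta = np.clip(xb[None, :] + logg, -50, 50)
                    log_surv = (-np.exp(eta)) @ effT
                    wts = np.exp(log_surv - log_surv.max())
                    wts /= wts.sum()
                    surface[suit] += (N - n) * wts
            total += 1
    return surface / max(total, 1)


def plot_density_surface(surface: np.ndarray, grid: HabitatGrid,
                         traps: TrapArray | None = None, path=None,
                         log_scale: bool = True):
    """Map of log E[number of activity centers] per grid cell.

    Returns the matplotlib figure; writes it to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    vals = surface.reshape(grid.nrow, grid.ncol)
    if log_scale:
        with np.errstate(divide="ignore"):
            vals = np.where(vals > 0, np.log(vals), np.nan)
    extent = (grid.xll, grid.xll + grid.ncol * grid.cell_size,
              grid.yll, grid.yll + grid.nrow * grid.cell_size)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(vals, origin="lower", extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax,
                 label="log E[activity centers]" if log_scale else "E[activity centers]")
    if traps is not None:
        ax.scatter(traps.xy[:, 0], traps.xy[:, 1], s=8, c="black", marker="o",
                   label="traps")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def summary_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean/median and 95% interval for every scalar parameter."""
    rows = []
    for name in ("N", "sigma", "delta1", "delta2", "alpha", "psi", "n", "pstar"):
        if name not in samples.draws:
            continue
        x = samples.stacked(name)
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append({"parameter": name, "mean": x.mean(),
                     "median": float(np.median(x)),
                     "lo95": lo, "hi95": hi})
    beta = samples.stacked("beta")
    for k, cname in enumerate(samples.coef_names):
        lo, hi = np.percentile(beta[:, k], [2.5, 97.5])
        rows.append({"parameter": cname, "mean": beta[:, k].mean(),
                     "median": float(np.median(beta[:, k])),
                     "lo95": lo, "hi95": hi})
    return pd.DataFrame(rows)
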