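"""Range-wide minimum population size with propagated parameter uncertainty.

The central estimate is the product of the taxon's range area, the fraction
of survey plots where it was present, and its median minimum adult density.
Uncertainty reflects only the published spread of the behavioural
parameters (ma, mp, ms), propagated either by Monte-Carlo resampling from
truncated normals or by the first-order delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import TaxonParameters

__all__ = [
    "StateEstimate",
    "extrapolate_state",
    "propagate_uncertainty",
    "estimate_state",
]


@dataclass(frozen=True)
class StateEstimate:
    """Minimum adult population within a taxon's range, with uncertainty."""

    taxon: str
    central: float
    sd: float
    range_area_km2: float
    plot_presence_fraction: float
    median_mafd: float
    method: str

    def __post_init__(self) -> None:
        if self.central < 0 or self.sd < 0:
            raise ValueError("central estimate and sd must be non-negative")


def extrapolate_state(
    median_mafd: float, presence_fraction: float, range_area_km2: float
) -> float:
    """Central minimum population size: range area × presence fraction × density."""
    if median_mafd < 0 or range_area_km2 < 0:
        raise ValueError("density and range area must be non-negative")
    if not 0 <= presence_fraction <= 1:
        raise ValueError(f"presence fraction must be in [0, 1], got {presence_fraction}")
    return range_area_km2 * presence_fraction * median_mafd


def _effective_ms(params: TaxonParameters) -> tuple[float, float]:
    # Taxa with stratum-specific sex ratios are collapsed to the midpoint for
    # the range-wide uncertainty; the two SDs combine in quadrature over 2.
    if params.ms_large is None:
        return params.ms, params.sd_ms
    ms = (params.ms + params.ms_large) / 2.0
    sd = math.hypot(params.sd_ms, params.sd_ms_large) / 2.0
    return ms, sd


def _truncnorm_draws(
    rng: np.random.Generator, loc: float, sd: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, loc)
    # proportions live in (0, 1]
    lo, hi = (1e-9 - loc) / sd, (1.0 - loc) / sd
    return stats.truncnorm.rvs(lo, hi, loc=loc, scale=sd, size=n, random_state=rng)


def propagate_uncertainty(
    params: TaxonParameters,
    central: float,
    n_draws: int = 100_000,
    seed: int | None = 0,
    method: str = "mc",
) -> float:
    """Standard deviation of the population estimate from parameter SDs.

    ``method='mc'`` resamples ma, mp and ms from normal distributions
    truncated to (0, 1], rescales the estimate by the ratio of the nominal
    to the resampled detection product, and reports the sample SD
    (deterministic under a fixed seed).  ``method='delta'`` combines the
    relative SDs of the parameters in quadrature.  All-zero SDs give 0.
    """
    ms, sd_ms = _effective_ms(params)
    if params.sd_ma == 0 and params.sd_mp == 0 and sd_ms == 0:
        return 0.0
    if method == "delta":
        rel = math.sqrt(
            (params.sd_ma / params.ma) ** 2
            + (params.sd_mp / params.mp) ** 2
            + (sd_ms / ms) ** 2
        )
        return central * rel
    if method != "mc":
        raise ValueError(f"method must be 'mc' or 'delta', got {method!r}")
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    rng = np.random.default_rng(seed)
    ma = _truncnorm_draws(rng, params.ma, params.sd_ma, n_draws)
    mp = _truncnorm_draws(rng, params.mp, params.sd_mp, n_draws)
    ms_d = _truncnorm_draws(rng, ms, sd_ms, n_draws)
    nominal = params.ma * params.mp * ms
    draws = central * nominal / (ma * mp * ms_d)
    return float(np.std(draws, ddof=1))


def estimate_state(
    params: TaxonParameters,
    median_mafd: float,
    n_draws: int = 100_000,
    seed: int | None = 0,
    method: str = "mc",
) -> StateEstimate:
    """Full range-wide estimate using the ranges and presence fractions in ``params``."""
    central = extrapolate_state(
        median_mafd, params.plot_presence_fraction, params.range_area_km2
    )
    sd = propagate_uncertainty(params, central, n_draws=n_draws, seed=seed, method=method)
    return StateEstimate(
        taxon=params.taxon,
        central=central,
        sd=sd,
        range_area_km2=params.range_area_km2,
        plot_presence_fraction=params.plot_presence_fraction,
        median_mafd=median_mafd,
        method=method,
    )
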