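"""Censored biomarker panel processing.

Immunoassay panels report concentrations only inside a detection window:
values outside come back pinned at the lower/upper limit of detection
(LLOD/ULOD) with a censor flag.  This module fits a log-normal to each
marker by censored maximum likelihood, replaces censored readings with the
conditional expectation of the concentration given the censoring event
(E[X | X < LLOD] or E[X | X > ULOD]), and finally converts each marker to
within-cohort quantile ranks so downstream models see an outlier-robust,
comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

#: The 15-marker sepsis panel, in panel order.
MARKER_NAMES: tuple[str, ...] = (
    "TNF-a", "IL-1b", "G-CSF", "IL-6", "PCT", "sTREM-1", "IL-18", "MMP-9",
    "TNFR1", "TNFR2", "IP-10", "MCP-1", "IL-1ra", "NGAL", "nCD64",
)

OBSERVED = "observed"
BELOW_LLOD = "below_llod"
ABOVE_ULOD = "above_ulod"
CENSOR_STATES = (OBSERVED, BELOW_LLOD, ABOVE_ULOD)


@dataclass(frozen=True)
class BiomarkerMeasurement:
    """One marker reading.  Censored readings carry the limit value itself."""

    marker: str
    concentration: float
    censor: str = OBSERVED
    batch: int = 0

    def __post_init__(self) -> None:
        if self.censor not in CENSOR_STATES:
            raise ValueError(f"censor must be one of {CENSOR_STATES}, got {self.censor!r}")
        if not (np.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError(f"{self.marker}: concentration must be positive and finite")


@dataclass(frozen=True)
class CensoredFit:
    """Log-normal fit of one marker: ln X ~ N(mu, sigma^2)."""

    mu: float
    sigma: float
    n_observed: int
    n_censored_low: int = 0
    n_censored_high: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def fit_censored_lognormal(values: Sequence[BiomarkerMeasurement]) -> CensoredFit:
    """Censored maximum-likelihood log-normal fit for one marker.

    Uncensored readings contribute normal densities on the log scale;
    below-LLOD readings contribute ``Phi((ln LLOD - mu)/sigma)`` and
    above-ULOD readings the complementary survival term.  Requires at least
    3 observed values and non-degenerate spread; callers with fewer should
    fall back to imputing at the limit itself.
    """
    obs = np.log([m.concentration for m in values if m.censor == OBSERVED])
    left = np.log([m.concentration for m in values if m.censor == BELOW_LLOD])
    right = np.log([m.concentration for m in values if m.censor == ABOVE_ULOD])
    if obs.size < 3:
        raise ValueError(
            f"need >= 3 observed values to fit (got {obs.size}); "
            "fall back to imputing censored readings at the detection limit"
        )
    if np.ptp(obs) == 0.0:
        raise ValueError("all observed values identical: sigma is degenerate")

    mu0, s0 = float(np.mean(obs)), float(np.std(obs))
    s0 = max(s0, 1e-3)

    def negloglik(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        ll = np.sum(stats.norm.logpdf(obs, mu, sigma))
        if left.size:
            ll += np.sum(stats.norm.logcdf(left, mu, sigma))
        if right.size:
            ll += np.sum(stats.norm.logsf(right, mu, sigma))
        return -ll

    res = optimize.minimize(
        negloglik, x0=np.array([mu0, np.log(s0)]), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return CensoredFit(
        mu=mu, sigma=sigma, n_observed=int(obs.size),
        n_censored_low=int(left.size), n_censored_high=int(right.size),
    )


def conditional_expectation(fit: CensoredFit, bound: float, side: str) -> float:
    """Truncated log-normal mean E[X | X < bound] or E[X | X > bound].

    Closed form: with a = (ln b - mu)/sigma,
    E[X | X < b] = exp(mu + sigma^2/2) * Phi(a - sigma) / Phi(a), and the
    ``above`` side uses survival functions in place of Phi.  Evaluated in
    log space so bounds far into either tail stay finite; the result is
    clamped to the open interval (0, bound) resp. (bound, inf) against
    floating-point round-off at extreme bounds.
    """
    if not bound > 0:
        raise ValueError("bound must be positive")
    a = (np.log(bound) - fit.mu) / fit.sigma
    mean_log = fit.mu + 0.5 * fit.sigma**2
    if side == "below":
        log_ratio = stats.norm.logcdf(a - fit.sigma) - stats.norm.logcdf(a)
        value = float(np.exp(mean_log + log_ratio))
        return min(value, bound * (1.0 - 1e-15))
    if side == "above":
        log_ratio = stats.norm.logsf(a - fit.sigma) - stats.norm.logsf(a)
        value = float(np.exp(mean_log + log_ratio))
        return max(value, bound * (1.0 + 1e-15))
    raise ValueError(f"side must be 'below' or 'above', got {side!r}")


def impute_censored(
    panel: Sequence[BiomarkerMeasurement],
    fits: Mapping[str, CensoredFit],
) -> list[BiomarkerMeasurement]:
    """Replace censored concentrations by their conditional expectations.

    Observed readings pass through untouched; censor flags are preserved on
    the imputed readings for provenance.  Raises ``KeyError`` naming the
    marker if a censored reading has no fit.
    """
    out: list[BiomarkerMeasurement] = []
    for m in panel:
        if m.censor == OBSERVED:
            out.append(m)
            continue
        if m.marker not in fits:
            raise KeyError(f"no censored-distribution fit available for marker {m.marker!r}")
        side = "below" if m.censor == BELOW_LLOD else "above"
        value = conditional_expectation(fits[m.marker], m.concentration, side)
        out.append(replace(m, concentration=value))
    return out


def quantile_normalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map one marker's concentrations to quantile ranks rank/(n+1).

    Ties receive the mean of their tied ranks, so the output is invariant
    under any strictly monotone transform of the input and lies in (0, 1).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    return stats.rankdata(arr, method="average") / (arr.size + 1)
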