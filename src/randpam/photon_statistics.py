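"""Closed-form photon-hit statistics for a microvillus population.

A fly photoreceptor's rhabdomere is an array of ``N_u`` microvilli, each an
independent photon-sampling unit.  When ``N_ph`` photons arrive in one
time-bin and each lands on a uniformly chosen microvillus, the number of
hits ``x`` to any one microvillus is Binomial(N_ph, 1/N_u), which for
``N_ph << N_u**2`` is well approximated by Poisson with mean
``lambda_M = N_ph / N_u``.  Everything downstream of the sampling step —
the expected occupancy ``N_u * P(x)``, the multi-photon-hit percentage, and
the activated-microvilli-per-photon ratio — follows from these two pmfs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SamplingGeometry",
    "HitRate",
    "HitPMF",
    "binomial_hit_pmf",
    "poisson_hit_pmf",
    "poisson_approx_valid",
    "expected_microvilli_with_x_hits",
    "multi_photon_fraction",
    "activated_per_photon",
    "multi_photon_table",
]

#: Default validity rule for the Poisson approximation: N_ph / N_u**2 at or
#: below this ratio (two orders of margin under the worked fly regime
#: 5e6 photons vs N_u**2 = 9e8) and at least MIN_MICROVILLI units.
POISSON_VALIDITY_RATIO = 0.01
MIN_MICROVILLI = 100


@dataclass(frozen=True)
class SamplingGeometry:
    """Structural parameters of the photon-sampling array.

    Parameters
    ----------
    n_microvilli : int
        Number of microvilli in the rhabdomere (N_u).  30,000 for a
        Drosophila R1-R6 photoreceptor, 90,000 for the blowfly.
    bin_duration_ms : float
        Duration of one time-bin in milliseconds; 1 ms at the standard
        1 kHz input sampling.
    """

    n_microvilli: int
    bin_duration_ms: float = 1.0

    def __post_init__(self) -> None:
        if int(self.n_microvilli) != self.n_microvilli or self.n_microvilli < 1:
            raise ValueError(f"n_microvilli must be a positive integer, got {self.n_microvilli}")
        if not self.bin_duration_ms > 0:
            raise ValueError(f"bin_duration_ms must be positive, got {self.bin_duration_ms}")


@dataclass(frozen=True)
class HitRate:
    """Mean photon hits per microvillus per bin, lambda_M = N_ph / N_u.

    ``n_photons`` is optional metadata recording the per-bin photon count
    the rate was derived from.
    """

    lambda_m: float
    n_photons: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_m < 0:
            raise ValueError(f"lambda_m must be non-negative, got {self.lambda_m}")
        if self.n_photons is not None and self.n_photons < 0:
            raise ValueError(f"n_photons must be non-negative, got {self.n_photons}")

    @classmethod
    def from_counts(cls, n_photons: int, geometry: SamplingGeometry) -> "HitRate":
        if n_photons < 0:
            raise ValueError(f"n_photons must be non-negative, got {n_photons}")
        return cls(lambda_m=n_photons / geometry.n_microvilli, n_photons=n_photons)


@dataclass(frozen=True)
class HitPMF:
    """A hit-count pmf over x = 0, 1, 2, ... with its distributional family."""

    support: np.ndarray
    probabilities: np.ndarray
    family: str  # "binomial" | "poisson"

    def __post_init__(self) -> None:
        if np.any(self.probabilities < 0):
            raise ValueError("pmf probabilities must be non-negative")


def _as_rate(rate: HitRate | float) -> float:
    lam = rate.lambda_m if isinstance(rate, HitRate) else float(rate)
    if lam < 0:
        raise ValueError(f"lambda_m must be non-negative, got {lam}")
    return lam


def binomial_hit_pmf(n_photons: int, geometry: SamplingGeometry, x: int) -> float:
    """Exact probability that one microvillus absorbs ``x`` of ``n_photons``.

    x ~ Binomial(N_ph, 1/N_u): each of the N_ph photons independently picks
    this microvillus with probability 1/N_u.  Evaluated in log-space by
    scipy, so large N_ph does not overflow.
    """
    if n_photons < 0:
        raise ValueError(f"n_photons must be non-negative, got {n_photons}")
    if x < 0 or x > n_photons:
        raise ValueError(f"x must satisfy 0 <= x <= n_photons, got x={x}, n_photons={n_photons}")
    return float(stats.binom.pmf(x, n_photons, 1.0 / geometry.n_microvilli))


def poisson_hit_pmf(rate: HitRate | float, x: int) -> float:
    """Poisson(lambda_M) probability of ``x`` hits: lambda^x e^-lambda / x!."""
    lam = _as_rate(rate)
    if x < 0:
        raise ValueError(f"x must be non-negative, got {x}")
    return float(stats.poisson.pmf(x, lam))


def poisson_approx_valid(
    n_photons: int, geometry: SamplingGeometry
) -> tuple[bool, dict[str, float]]:
    """Whether Poisson may replace the exact binomial hit pmf.

    The approximation requires many microvilli and N_ph well below N_u**2.
    Returns the flag plus the diagnostic ratios so callers can apply their
    own cutoff.
    """
    if n_photons < 0:
        raise ValueError(f"n_photons must be non-negative, got {n_photons}")
    n_u = geometry.n_microvilli
    ratio = n_photons / n_u**2
    diagnostics = {
        "n_ph_over_n_u_squared": ratio,
        "lambda_m": n_photons / n_u,
        "n_microvilli": float(n_u),
    }
    valid = ratio <= POISSON_VALIDITY_RATIO and n_u >= MIN_MICROVILLI
    return valid, diagnostics


def hit_pmf(n_photons: int, geometry: SamplingGeometry, x_max: int | None = None) -> HitPMF:
    """Full hit-count pmf for one microvillus, binomial or Poisson as valid.

    ``x_max`` truncates the support (default: smallest of n_photons and the
    point where the upper Poisson tail falls below 1e-15).
    """
    valid, _ = poisson_approx_valid(n_photons, geometry)
    lam = n_photons / geometry.n_microvilli
    if x_max is None:
        if n_photons == 0:
            x_max = 0
        else:
            # cover the bulk plus a generous tail
            x_max = int(min(n_photons, math.ceil(lam + 12 * math.sqrt(lam + 1) + 20)))
    support = np.arange(x_max + 1)
    if valid:
        probs = stats.poisson.pmf(support, lam)
        family = "poisson"
    else:
        probs = stats.binom.pmf(support, n_photons, 1.0 / geometry.n_microvilli)
        family = "binomial"
    return HitPMF(support=support, probabilities=probs, family=family)


def expected_microvilli_with_x_hits(
    n_photons: int, geometry: SamplingGeometry, x: int
) -> float:
    """Expected number of microvilli absorbing exactly ``x`` photons, N_u * P(x).

    The occupancy of the x-hit class is Binomial(N_u, P(x)) — a compound
    binomial once x's own law is folded in — so its mean is N_u * P(x).
    Uses the Poisson P(x) when the approximation is valid, else the exact
    binomial.
    """
    if x < 0:
        raise ValueError(f"x must be non-negative, got {x}")
    valid, _ = poisson_approx_valid(n_photons, geometry)
    if valid:
        p = poisson_hit_pmf(n_photons / geometry.n_microvilli, x)
    else:
        p = binomial_hit_pmf(n_photons, geometry, x) if x <= n_photons else 0.0
    return geometry.n_microvilli * p


def multi_photon_fraction(rate: HitRate | float) -> float:
    """Fraction of hit microvilli receiving two or more photons (P_M).

    P_M = P(x > 1) / P(x >= 1) = 1 - lambda / (e^lambda - 1) under the
    Poisson law; 0 at lambda = 0 by continuous extension.  Strictly
    increasing in lambda, approaching 1 in bright light on few microvilli.
    """
    lam = _as_rate(rate)
    if lam == 0:
        return 0.0
    return 1.0 - lam / math.expm1(lam)


def activated_per_photon(rate: HitRate | float) -> float:
    """Activated microvilli per incoming photon, N_A / N_ph = (1 - e^-lambda)/lambda.

    The normalized-gain lower bound: the gain of a sampler in which any
    multi-photon hit collapses to a single unit event.  1 at lambda = 0 by
    continuous extension; strictly decreasing in lambda.
    """
    lam = _as_rate(rate)
    if lam == 0:
        return 1.0
    return -math.expm1(-lam) / lam


def multi_photon_table(
    photon_levels: list[int], microvilli_levels: list[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-photon-hit percentage matrix over (N_ph, N_u) grids.

    Rows are photons per bin, columns microvillus counts.  Returns
    ``(display, raw)``: the display frame holds percentages rounded to two
    decimals; the raw frame the unrounded values.
    """
    if not photon_levels or not microvilli_levels:
        raise ValueError("photon_levels and microvilli_levels must be non-empty")
    if any(n <= 0 for n in photon_levels) or any(n <= 0 for n in microvilli_levels):
        raise ValueError("all photon and microvillus levels must be positive")
    raw = pd.DataFrame(
        [
            [100.0 * multi_photon_fraction(n_ph / n_u) for n_u in microvilli_levels]
            for n_ph in photon_levels
        ],
        index=pd.Index(photon_levels, name="photons_per_bin"),
        columns=pd.Index(microvilli_levels, name="n_microvilli"),
    )
    return raw.round(2), raw
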