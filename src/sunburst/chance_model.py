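"""Resampling-based chance reference for single-trial path-choice percentages.

In a Sunburst-style test each of N subjects commits to one of K available
paths exactly once, so "chance" for any given path is the distribution of
per-path percentages when N choices are thrown uniformly at random across
the K paths.  The reference distribution is built by Monte-Carlo
reallocation: R resamples of N uniform choices (a multinomial draw), each
converted to percentages, with the mean ``mu_r`` and standard deviation
``sigma_r`` pooled over all K x R per-path percentages.  Paths are
exchangeable under this null, so pooling across paths yields a single
chance band per experiment rather than K noisy per-path ones.

Two one-sided thresholds come straight off the reference distribution,

    thr_05 = mu_r + 1.650 * sigma_r       (p = 0.05)
    thr_01 = mu_r + 2.326 * sigma_r       (p = 0.01)

and observed percentages are normalized as z = (observed - mu_r) / sigma_r,
which puts experiments with different K and N on one scale.

Because each per-path count is Binomial(N, 1/K), the null also has a closed
form, mu = 100/K and sigma = 100 * sqrt((1/K)(1 - 1/K)/N), exposed as
:func:`closed_form_null` both as a fast analytic policy and as an
independent oracle for the resampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateNullError

__all__ = [
    "NullDistribution",
    "NormalizedValue",
    "resample_null",
    "analytic_null",
    "closed_form_null",
    "normalize",
    "above_chance",
    "Z_05",
    "Z_01",
]

#: One-sided normal z-scores behind the p = 0.05 and p = 0.01 thresholds.
Z_05 = 1.650
Z_01 = 2.326


@dataclass(frozen=True)
class NullDistribution:
    """Chance reference for one experiment's (N, K) geometry.

    ``shuffle_z_mean`` / ``shuffle_z_var`` are the mean and variance of the
    resampled percentages after normalization — close to (0, 1) by
    construction but computed, not assumed; they feed the z-difference test.
    ``method`` is ``"resample"`` or ``"analytic"``; for the analytic null R
    and seed are ``None``.
    """

    K: int
    N: int
    R: int | None
    seed: int | None
    mu_r: float
    sigma_r: float
    thr_05: float
    thr_01: float
    shuffle_z_mean: float
    shuffle_z_var: float
    method: str = "resample"

    @property
    def label(self) -> str:
        return (f"{self.method}(N={self.N}, K={self.K}, R={self.R}, "
                f"seed={self.seed})")


@dataclass(frozen=True)
class NormalizedValue:
    """A chance-normalized percentage: z = (observed - mu_r) / sigma_r."""

    z: float
    observed: float
    null_ref: str


def _check_nk(N: int, K: int) -> None:
    if K < 2:
        raise DegenerateNullError(f"chance undefined for K={K} < 2 paths")
    if N < 1:
        raise DegenerateNullError("chance undefined for N=0 scored choices")


def resample_null(N: int, K: int, R: int = 1000, seed: int = 0,
                  ) -> NullDistribution:
    """Monte-Carlo chance distribution for N choices over K paths.

    Each of the R resamples assigns N choices uniformly at random across the
    K paths (with replacement) and is converted to percentages; ``mu_r`` and
    ``sigma_r`` are the mean/SD pooled over all K*R per-path percentages.
    Identical (N, K, R, seed) produce a bit-identical result.
    """
    _check_nk(N, K)
    if R < 1:
        raise DegenerateNullError(f"need at least one resample, got R={R}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(N, np.full(K, 1.0 / K), size=R)
    pct = counts.ravel() * (100.0 / N)
    mu = float(pct.mean())
    sigma = float(pct.std(ddof=1))
    if sigma <= 0.0:
        # All resamples identical: only possible at tiny R; keep the caller
        # honest instead of emitting unusable thresholds.
        raise DegenerateNullError(
            f"degenerate resampled null (sigma=0) for N={N}, K={K}, R={R}")
    zvals = (pct - mu) / sigma
    return NullDistribution(
        K=K, N=N, R=R, seed=seed, mu_r=mu, sigma_r=sigma,
        thr_05=mu + Z_05 * sigma, thr_01=mu + Z_01 * sigma,
        shuffle_z_mean=float(zvals.mean()),
        shuffle_z_var=float(zvals.var(ddof=1)),
        method="resample")


def closed_form_null(N: int, K: int) -> tuple[float, float]:
    """Analytic (mu, sigma) of the uniform-choice null, in percent units.

    Each per-path count is Binomial(N, 1/K), hence mu = 100/K and
    sigma = 100 * sqrt((1/K)(1 - 1/K)/N).
    """
    _check_nk(N, K)
    p = 1.0 / K
    return 100.0 * p, 100.0 * float(np.sqrt(p * (1.0 - p) / N))


def analytic_null(N: int, K: int) -> NullDistribution:
    """Closed-form counterpart of :func:`resample_null` (exact moments)."""
    mu, sigma = closed_form_null(N, K)
    return NullDistribution(
        K=K, N=N, R=None, seed=None, mu_r=mu, sigma_r=sigma,
        thr_05=mu + Z_05 * sigma, thr_01=mu + Z_01 * sigma,
        shuffle_z_mean=0.0, shuffle_z_var=1.0, method="analytic")


def normalize(observed: float, null: NullDistribution) -> NormalizedValue:
    """Chance-normalize an observed per-path percentage against ``null``."""
    if null.sigma_r <= 0.0:
        raise DegenerateNullError("normalization undefined for sigma_r = 0")
    return NormalizedValue(z=(observed - null.mu_r) / null.sigma_r,
                           observed=observed, null_ref=null.label)


def above_chance(observed: float, null: NullDistribution,
                 level: float | str = "p05",
                 z_cut: float | None = None) -> bool:
    """Is ``observed`` strictly above the chance threshold?

    ``level`` selects the 0.05 or 0.01 percentage threshold (``"p05"``/0.05,
    ``"p01"``/0.01); passing ``z_cut`` instead compares the normalized score
    against an arbitrary z cutoff (e.g. the 1.96-SD categorization
    criterion).  Exceedance is strict: a value exactly at threshold is not
    above chance.
    """
    if z_cut is not None:
        return normalize(observed, null).z > z_cut
    if level in ("p05", 0.05):
        return observed > null.thr_05
    if level in ("p01", 0.01):
        return observed > null.thr_01
    raise ValueError(f"unknown significance level {level!r}; "
                     "use 'p05', 'p01' or a z_cut")
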