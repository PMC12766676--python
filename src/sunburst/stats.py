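"""Auxiliary tests: chi-square against expected proportions with
Benjamini-Hochberg correction, the between-experiment z-difference test,
and Gaussian density summaries for sources reporting only mean +/- SD.

These are the standard statistical steps wrapped behind one surface so the
report layer and tests exercise a single code path; scipy and statsmodels
do the distributional work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .chance_model import NormalizedValue, NullDistribution
from .errors import AnalysisError, ValidationError

__all__ = [
    "TestResult",
    "chi_square_expected",
    "benjamini_hochberg",
    "z_difference_test",
    "gaussian_density_summary",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    df: int | None = None
    p_adjusted: float | None = None


def chi_square_expected(observed, expected_proportions) -> TestResult:
    """Pearson chi-square test of observed counts against expected proportions.

    ``E_i = total * p_i``; statistic = sum (O_i - E_i)^2 / E_i with
    ``cells - 1`` degrees of freedom and an asymptotic upper-tail p-value
    (no continuity correction).  A warning is emitted when any expected
    count falls below 5, where the asymptotic approximation weakens.
    """
    observed = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if observed.size < 2 or props.size != observed.size:
        raise ValidationError("need >= 2 cells with matching expected "
                              "proportions")
    if np.any(observed < 0):
        raise ValidationError("negative observed counts")
    if not np.isclose(props.sum(), 1.0, atol=1e-9):
        raise ValidationError("expected proportions must sum to 1")
    total = observed.sum()
    if total < 1:
        raise ValidationError("total observed count must be >= 1")
    expected = total * props
    if np.any(expected == 0):
        raise ValidationError("expected count of zero in some cell")
    if np.any(expected < 5):
        warnings.warn("expected count below 5 in some cell; asymptotic "
                      "chi-square p-value may be unreliable", stacklevel=2)
    stat, p = sps.chisquare(observed, f_exp=expected)
    return TestResult(statistic=float(stat), p_raw=float(p),
                      df=observed.size - 1)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up false-discovery-rate adjustment of a family of p-values.

    Order-preserving; adjusted values are capped at 1 and monotone
    non-decreasing in the sorted order after step-up enforcement.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_z(value: float | NormalizedValue) -> float:
    return value.z if isinstance(value, NormalizedValue) else float(value)


def z_difference_test(z_a: float | NormalizedValue,
                      z_b: float | NormalizedValue,
                      null_a: NullDistribution,
                      null_b: NullDistribution) -> TestResult:
    """Compare two chance-normalized preferences from different experiments.

    statistic = ((z_a - z_b) - (m_a - m_b)) / sqrt(s_a^2 + s_b^2), where m
    and s^2 are the mean and variance of each experiment's shuffle
    distribution pushed through the same normalization.  Those moments are
    ~(0, 1) by construction but are taken from the null objects as
    computed, not assumed, so a resampled null contributes its actual
    finite-R moments.  Two-sided normal p-value.
    """
    va, vb = null_a.shuffle_z_var, null_b.shuffle_z_var
    denom = float(np.sqrt(va + vb))
    if denom <= 0.0:
        raise AnalysisError("z-difference test undefined: zero summed "
                            "shuffle variance")
    stat = ((_as_z(z_a) - _as_z(z_b))
            - (null_a.shuffle_z_mean - null_b.shuffle_z_mean)) / denom
    p = 2.0 * float(sps.norm.sf(abs(stat)))
    return TestResult(statistic=float(stat), p_raw=min(p, 1.0), df=None)


def gaussian_density_summary(mean: float, sd: float, grid) -> np.ndarray:
    """Gaussian probability density over a grid of alley positions.

    For sources that report path choices only as mean +/- SD (in alley-number
    units), the continuous normal density is the plotted summary; values are
    not renormalized over the discrete grid.
    """
    if sd <= 0:
        raise ValidationError("sd must be positive")
    return sps.norm.pdf(np.asarray(grid, dtype=float), loc=mean, scale=sd)
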