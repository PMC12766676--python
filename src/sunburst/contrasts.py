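"""Cross-experiment paired path contrasts and distributional summaries.

The categorization stage asks *which* role wins within an experiment; the
contrasts here ask finer questions across experiments, e.g. whether the
adjacent path that is more likely to intersect the blocked training route
is preferred over the other adjacent path, or whether the outer arm on the
rewarded side beats its counterpart.  Each eligible experiment contributes
one pair of chance-normalized scores (z_primary, z_alternative) and their
difference; the group-level question is answered with a paired two-sided
sign-flip permutation test on the per-experiment differences, exact when
the number of experiments is small and seeded Monte-Carlo otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .categorization import NullPolicy
from .chance_model import normalize
from .errors import AnalysisError
from .experiment_data import Dataset, ExperimentRecord, to_percentages

__all__ = [
    "PairedContrast",
    "ContrastSummary",
    "ContrastResult",
    "adjacent_contrast",
    "outer_contrast",
    "sign_flip_permutation_test",
    "experiment_distribution_ci",
    "shortcut_adjacent_delta",
]

#: At or below this many pairs the sign-flip null is enumerated exactly.
EXACT_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class PairedContrast:
    """One experiment's focal-vs-counterpart normalized pair."""

    study_id: str
    experiment_id: str
    z_primary: float
    z_alternative: float

    @property
    def delta(self) -> float:
        return self.z_primary - self.z_alternative


@dataclass(frozen=True)
class ContrastSummary:
    """Group-level summary over the eligible experiments."""

    n_experiments: int
    pct_primary_above: float
    pct_alternative_above: float
    mean_delta: float
    p_value: float
    exact: bool
    empty: bool = False


@dataclass(frozen=True)
class ContrastResult:
    mode: str
    table: pd.DataFrame
    summary: ContrastSummary


def sign_flip_permutation_test(deltas: np.ndarray, n_perm: int = 10000,
                               seed: int = 0) -> tuple[float, bool]:
    """Two-sided paired sign-flip permutation p-value for mean(delta) = 0.

    Under the null each pair's difference is symmetric about zero, so the
    reference distribution flips the sign of every delta independently.
    With at most :data:`EXACT_ENUMERATION_LIMIT` pairs all 2^n sign
    patterns are enumerated; beyond that ``n_perm`` seeded random flips are
    drawn and the observed pattern is counted into the null (add-one rule).
    Returns ``(p, exact)``.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    if n == 0:
        raise AnalysisError("permutation test needs at least one pair")
    observed = abs(deltas.mean())
    if n <= EXACT_ENUMERATION_LIMIT:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        stats = np.abs(signs @ deltas) / n
        # >= with a float-safe margin: sign patterns reproducing the
        # observed magnitude count toward p.
        p = float(np.mean(stats >= observed - 1e-12))
        return p, True
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    stats = np.abs(signs @ deltas) / n
    hits = int(np.sum(stats >= observed - 1e-12))
    return float((hits + 1) / (n_perm + 1)), False


def _paired_contrast(dataset: Dataset, flag: str, primary_flag: str,
                     mode: str, z_cut: float, null_policy: NullPolicy,
                     n_perm: int, seed: int) -> ContrastResult:
    rows: list[dict] = []
    pairs: list[PairedContrast] = []
    for rec in dataset:
        selected = [p for p in rec.scorable_paths if getattr(p, flag)]
        if len(selected) != 2:
            continue
        primary = [p for p in selected if getattr(p, primary_flag)]
        if len(primary) != 1:
            continue  # the mode flag must single out one side
        alt = selected[0] if selected[1] is primary[0] else selected[1]
        pct = to_percentages(rec)
        null = null_policy.make_null(rec)
        z_p = normalize(pct[primary[0].index], null).z
        z_a = normalize(pct[alt.index], null).z
        if max(z_p, z_a) <= z_cut:
            continue  # neither side above chance: not informative
        pair = PairedContrast(rec.study_id, rec.experiment_id, z_p, z_a)
        pairs.append(pair)
        rows.append({
            "study_id": rec.study_id, "experiment_id": rec.experiment_id,
            "mode": mode, "z_primary": z_p, "z_alternative": z_a,
            "delta": pair.delta,
            "primary_above": z_p > z_cut, "alternative_above": z_a > z_cut,
        })
    table = pd.DataFrame(rows, columns=[
        "study_id", "experiment_id", "mode", "z_primary", "z_alternative",
        "delta", "primary_above", "alternative_above"])
    if not pairs:
        summary = ContrastSummary(
            n_experiments=0, pct_primary_above=float("nan"),
            pct_alternative_above=float("nan"), mean_delta=float("nan"),
            p_value=float("nan"), exact=False, empty=True)
        return ContrastResult(mode=mode, table=table, summary=summary)
    deltas = np.array([p.delta for p in pairs])
    p_value, exact = sign_flip_permutation_test(deltas, n_perm=n_perm,
                                                seed=seed)
    summary = ContrastSummary(
        n_experiments=len(pairs),
        pct_primary_above=100.0 * float(table["primary_above"].mean()),
        pct_alternative_above=100.0 * float(table["alternative_above"].mean()),
        mean_delta=float(deltas.mean()), p_value=p_value, exact=exact)
    return ContrastResult(mode=mode, table=table, summary=summary)


def adjacent_contrast(dataset: Dataset, mode: str = "intersect",
                      z_cut: float = 1.96,
                      null_policy: NullPolicy = NullPolicy(),
                      n_perm: int = 10000, seed: int = 0) -> ContrastResult:
    """Intersecting (or first-turn) adjacent path vs. the other adjacent path.

    ``mode="intersect"`` takes as focal path the adjacent arm more likely to
    intersect the training route; ``mode="first_turn"`` the one heading in
    the direction of the first training turn.  Only experiments with both
    adjacent arms flagged and at least one of them above chance are
    included; with no eligible experiment the result carries an explicit
    ``empty`` flag instead of a p-value.
    """
    primary = {"intersect": "intersects_training",
               "first_turn": "matches_first_turn"}.get(mode)
    if primary is None:
        raise ValueError(f"unknown adjacent contrast mode {mode!r}")
    return _paired_contrast(dataset, "is_adjacent", primary, mode, z_cut,
                            null_policy, n_perm, seed)


def outer_contrast(dataset: Dataset, mode: str = "reward_side",
                   z_cut: float = 1.96,
                   null_policy: NullPolicy = NullPolicy(),
                   n_perm: int = 10000, seed: int = 0) -> ContrastResult:
    """Reward-side (or first-turn) outer arm vs. the other outer arm."""
    primary = {"reward_side": "reward_side",
               "first_turn": "matches_first_turn"}.get(mode)
    if primary is None:
        raise ValueError(f"unknown outer contrast mode {mode!r}")
    return _paired_contrast(dataset, "is_outer", primary, mode, z_cut,
                            null_policy, n_perm, seed)


def shortcut_adjacent_delta(record: ExperimentRecord,
                            null_policy: NullPolicy = NullPolicy()) -> float:
    """Per-experiment z(shortcut) - z(adjacent) statistic."""
    from .categorization import role_z
    zs = role_z(record, null_policy.make_null(record))
    if "shortcut" not in zs or "adjacent" not in zs:
        raise AnalysisError(
            f"{record.study_id}/{record.experiment_id}: record lacks "
            "shortcut or adjacent roles")
    return zs["shortcut"] - zs["adjacent"]


def experiment_distribution_ci(values: np.ndarray | list[float],
                               levels: tuple[float, ...] = (90.0, 95.0, 99.0),
                               ) -> dict[float, tuple[float, float]]:
    """Empirical percentile intervals of a per-experiment statistic.

    Central intervals at each confidence level, computed with
    linear-interpolation percentiles over the distribution of experiments;
    the returned intervals are nested (99 contains 95 contains 90).
    Requires at least two experiments.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise AnalysisError("need at least 2 experiments for an "
                            "experiment-distribution interval")
    out: dict[float, tuple[float, float]] = {}
    for level in levels:
        alpha = (100.0 - level) / 2.0
        lo, hi = np.percentile(values, [alpha, 100.0 - alpha])
        out[level] = (float(lo), float(hi))
    return out
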