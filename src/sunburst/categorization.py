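"""Assign experiments to path-preference categories and tally prevalence.

Each experiment is summarized by the percentage of scored choices landing
on each path *role*:

* ``shortcut`` — the path pointing most directly at the former reward
  location (the classic cognitive-map claim);
* ``adjacent`` — the two paths flanking the blocked training route
  (stimulus-triggered response); multi-path roles are averaged;
* ``outer`` — the outermost arms (thigmotaxis / route repetition), averaged;
* ``cued`` — the path heading toward a salient stimulus (beaconing);
* ``other`` — the best single unlabelled path (an experiment can be "won"
  by a path with no remarkable features, so this role is a maximum, not an
  average).

A role is a candidate only if its (averaged) percentage is above chance —
by default exceeding the chance distribution by more than 1.96 standard
deviations.  Among candidates the highest percentage wins; exact ties are
broken by the fixed priority Shortcut > Adjacent > Outer > Cued > Other,
which deliberately biases outcomes toward positive shortcutting.  If no
role is above chance the experiment is categorized ``no_pref``.

Inclusion rules for cross-study comparison (first-choice scoring only,
intact animals only, trained animals only, designated pre-op groups pooled)
are provided as pure, composable dataset filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chance_model import (NullDistribution, analytic_null, normalize,
                           resample_null)
from .errors import AnalysisError, ValidationError
from .experiment_data import Dataset, ExperimentRecord, to_percentages

__all__ = [
    "ROLE_PRIORITY",
    "CategoryResult",
    "NullPolicy",
    "role_percentages",
    "categorize",
    "categorize_dataset",
    "prevalence",
    "filter_scoring",
    "filter_out_flagged",
    "combine_groups",
    "default_inclusion",
]

#: Tie-break priority, highest first.
ROLE_PRIORITY = ("shortcut", "adjacent", "outer", "cued", "other")

CATEGORIES = ROLE_PRIORITY + ("no_pref",)


@dataclass(frozen=True)
class CategoryResult:
    """Outcome of categorizing one experiment."""

    study_id: str
    experiment_id: str
    category: str
    winning_role: str | None
    role_percentages: dict[str, float]
    role_z: dict[str, float]
    null_used: str


@dataclass(frozen=True)
class NullPolicy:
    """How to build each experiment's chance reference.

    ``method="resample"`` draws R Monte-Carlo reallocations with a
    per-record seed derived deterministically from ``seed`` and the record
    identity; ``method="analytic"`` uses the exact binomial moments.
    """

    method: str = "resample"
    R: int = 1000
    seed: int = 0

    def make_null(self, record: ExperimentRecord) -> NullDistribution:
        n, k = record.n_scored, record.k_scorable
        if self.method == "analytic":
            return analytic_null(n, k)
        if self.method == "resample":
            return resample_null(n, k, R=self.R,
                                 seed=self.record_seed(record))
        raise ValueError(f"unknown null policy method {self.method!r}")

    def record_seed(self, record: ExperimentRecord) -> int:
        import zlib
        tag = zlib.crc32(
            f"{record.study_id}/{record.experiment_id}".encode())
        return int(np.random.SeedSequence([self.seed, tag])
                   .generate_state(1)[0] % (2 ** 31))


def role_percentages(record: ExperimentRecord) -> dict[str, float]:
    """Per-role percentages for one experiment.

    Single-path roles report that path's percentage; the multi-path adjacent
    and outer roles report the arithmetic mean over their member paths; a
    path carrying several role flags contributes to each of them.  ``other``
    is the maximum percentage among unlabelled, non-training paths.  Roles
    with no member path are absent from the result.
    """
    pct = to_percentages(record)
    scorable = record.scorable_paths
    out: dict[str, float] = {}
    for role, flag in (("shortcut", "is_shortcut"), ("adjacent", "is_adjacent"),
                       ("outer", "is_outer"), ("cued", "is_cued")):
        members = [pct[p.index] for p in scorable if getattr(p, flag)]
        if members:
            out[role] = float(np.mean(members))
    unlabelled = [pct[p.index] for p in scorable
                  if not (p.is_shortcut or p.is_adjacent or p.is_outer
                          or p.is_cued or p.is_training)]
    if unlabelled:
        out["other"] = float(max(unlabelled))
    return out


def role_z(record: ExperimentRecord, null: NullDistribution,
           average_percentages_first: bool = True) -> dict[str, float]:
    """Chance-normalized score for every role present in the record.

    Multi-path roles can be normalized after averaging percentages
    (default) or by averaging per-path z-scores; under the pooled null the
    two orders are algebraically identical, and both are exposed so the
    equivalence can be asserted rather than assumed.
    """
    if average_percentages_first:
        return {role: normalize(p, null).z
                for role, p in role_percentages(record).items()}
    pct = to_percentages(record)
    scorable = record.scorable_paths
    out: dict[str, float] = {}
    for role, flag in (("shortcut", "is_shortcut"), ("adjacent", "is_adjacent"),
                       ("outer", "is_outer"), ("cued", "is_cued")):
        zs = [normalize(pct[p.index], null).z
              for p in scorable if getattr(p, flag)]
        if zs:
            out[role] = float(np.mean(zs))
    unlabelled = [normalize(pct[p.index], null).z for p in scorable
                  if not (p.is_shortcut or p.is_adjacent or p.is_outer
                          or p.is_cued or p.is_training)]
    if unlabelled:
        out["other"] = float(max(unlabelled))
    return out


def categorize(record: ExperimentRecord, null: NullDistribution,
               z_cut: float = 1.96) -> CategoryResult:
    """Assign one experiment to a path-preference category.

    Among roles whose averaged percentage exceeds chance by more than
    ``z_cut`` standard deviations, the role with the highest percentage
    wins; exact ties follow :data:`ROLE_PRIORITY`.  With no above-chance
    role the category is ``no_pref``.
    """
    percs = role_percentages(record)
    if not percs:
        raise AnalysisError(
            f"{record.study_id}/{record.experiment_id}: no scorable paths")
    zs = {role: normalize(p, null).z for role, p in percs.items()}
    candidates = [role for role in ROLE_PRIORITY
                  if role in zs and zs[role] > z_cut]
    if not candidates:
        winner = None
        category = "no_pref"
    else:
        best = max(percs[r] for r in candidates)
        # ROLE_PRIORITY order makes the first maximal candidate the winner.
        winner = next(r for r in candidates if percs[r] == best)
        category = winner
    return CategoryResult(
        study_id=record.study_id, experiment_id=record.experiment_id,
        category=category, winning_role=winner,
        role_percentages=percs, role_z=zs, null_used=null.label)


def categorize_dataset(dataset: Dataset,
                       null_policy: NullPolicy = NullPolicy(),
                       z_cut: float = 1.96) -> list[CategoryResult]:
    """Categorize every record with its own (N, K) chance reference."""
    return [categorize(rec, null_policy.make_null(rec), z_cut=z_cut)
            for rec in dataset]


def prevalence(dataset: Dataset, null_policy: NullPolicy = NullPolicy(),
               z_cut: float = 1.96) -> dict[str, float]:
    """Percent of experiments per category, over all records in ``dataset``.

    Inclusion filtering is the caller's responsibility (see
    :func:`default_inclusion`); every category label appears in the result,
    with 0.0 where no experiment falls in it, and values sum to 100.
    """
    if len(dataset) == 0:
        raise AnalysisError("prevalence undefined for an empty dataset")
    results = categorize_dataset(dataset, null_policy, z_cut=z_cut)
    out = {cat: 0.0 for cat in CATEGORIES}
    for res in results:
        out[res.category] += 1.0
    total = float(len(results))
    return {cat: 100.0 * v / total for cat, v in out.items()}


# ---------------------------------------------------------------------------
# Inclusion filters — pure and idempotent


def filter_scoring(dataset: Dataset,
                   whitelist: Sequence[tuple[str, str]] = (),
                   ) -> Dataset:
    """Keep first-choice-scored records (plus explicitly whitelisted ones).

    Cross-study comparison uses first-choice distributions; records scored
    with mixed-order choices are dropped unless their
    (study_id, experiment_id) is whitelisted — the escape hatch for sources
    that reported only mixed-order choices.
    """
    allowed = set(whitelist)
    return Dataset(records=tuple(
        r for r in dataset
        if r.scoring == "first_choice"
        or (r.study_id, r.experiment_id) in allowed))


def filter_out_flagged(dataset: Dataset, key: str) -> Dataset:
    """Drop records whose ``extra[key]`` is truthy (e.g. ``lesioned``,
    ``untrained``)."""
    def truthy(v: object) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in {"1", "true", "yes", "y"}
        return bool(v)

    return Dataset(records=tuple(
        r for r in dataset if not truthy(r.extra.get(key, False))))


def combine_groups(dataset: Dataset, ids: Iterable[tuple[str, str]],
                   new_experiment_id: str,
                   new_group_label: str = "combined") -> Dataset:
    """Pool designated groups into one record by summing per-path counts.

    Used e.g. to merge pre-op groups that each represent a first test on
    intact animals.  All pooled records must share one study and an
    identical path layout.
    """
    ids = list(ids)
    members = [r for r in dataset if (r.study_id, r.experiment_id) in ids]
    if len(members) != len(ids):
        missing = set(ids) - {(r.study_id, r.experiment_id) for r in members}
        raise AnalysisError(f"combine_groups: records not found: {missing}")
    first = members[0]
    for r in members[1:]:
        if r.paths != first.paths:
            raise ValidationError(
                "combine_groups: path layouts differ between pooled records")
        if r.study_id != first.study_id:
            raise ValidationError(
                "combine_groups: cannot pool records across studies")
    counts = tuple(int(s) for s in np.sum([r.counts for r in members], axis=0))
    pooled = replace(first, experiment_id=new_experiment_id,
                     group_label=new_group_label, counts=counts,
                     n_no_choice=sum(r.n_no_choice for r in members))
    rest = tuple(r for r in dataset
                 if (r.study_id, r.experiment_id) not in ids)
    return Dataset(records=rest + (pooled,))


@dataclass(frozen=True)
class InclusionConfig:
    """Declarative bundle of the default cross-study inclusion rules."""

    mixed_order_whitelist: tuple[tuple[str, str], ...] = ()
    drop_lesioned: bool = True
    drop_untrained: bool = True
    combine: tuple[tuple[tuple[tuple[str, str], ...], str], ...] = field(
        default_factory=tuple)


def default_inclusion(dataset: Dataset,
                      config: InclusionConfig = InclusionConfig()) -> Dataset:
    """Apply the standard inclusion rules, in a fixed order.

    Pooling happens first (so pooled members are judged post-merge), then
    scoring, lesion and training filters.  The composition is idempotent.
    """
    out = dataset
    for ids, new_id in config.combine:
        out = combine_groups(out, ids, new_id)
    out = filter_scoring(out, whitelist=config.mixed_order_whitelist)
    if config.drop_lesioned:
        out = filter_out_flagged(out, "lesioned")
    if config.drop_untrained:
        out = filter_out_flagged(out, "untrained")
    return out
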