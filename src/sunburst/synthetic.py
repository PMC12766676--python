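"""Generator for Sunburst-style experiments under known navigation strategies.

Every subject makes exactly one categorical choice among K radial paths.
The generator draws each subject's *strategy* from a mixture and maps it to
a path role:

* ``shortcut`` — map-based choice of the shortcut path (optionally "smeared"
  geometrically onto neighbouring arms to emulate noisy vector navigation);
* ``adjacent`` — stimulus-triggered response next to the blocked training
  route: one of the two adjacent arms, with a configurable split between
  the intersecting arm and its counterpart;
* ``beacon`` — approach the cued path (uniform fallback when no cue);
* ``outer`` — thigmotaxis / route repetition toward the outermost arms,
  with a configurable reward-side weighting;
* ``other`` — apparatus-driven bias toward one designated unlabelled path
  (shadowed or walled arms that win in some studies without carrying any
  nominal role);
* ``uniform`` — exploration without preference over all scorable arms.

Strategies are modeled as path-role targets, not spatial trajectories;
layouts are preset role assignments over 1-based path indices.  Everything
is deterministic under the config seed with no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .experiment_data import Dataset, ExperimentRecord, PathSpec

__all__ = [
    "StrategyMix",
    "SimConfig",
    "make_layout",
    "simulate_experiment",
    "simulate_dataset",
    "load_sim_configs",
]

STRATEGIES = ("shortcut", "adjacent", "beacon", "outer", "other", "uniform")

#: Preset name -> required path count.
PRESET_K = {"tolman": 18, "enclosed": 8, "harley": 6, "tmaze": 5}


@dataclass(frozen=True)
class StrategyMix:
    """Mixture over single-subject choice strategies; must sum to 1."""

    p_shortcut: float = 0.0
    p_adjacent: float = 0.0
    p_beacon: float = 0.0
    p_outer: float = 0.0
    p_other: float = 0.0
    p_uniform: float = 1.0

    def __post_init__(self) -> None:
        probs = self.as_array()
        if np.any(probs < 0):
            raise ValidationError("strategy probabilities must be >= 0")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"strategy probabilities must sum to 1, got {probs.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_shortcut, self.p_adjacent, self.p_beacon,
                         self.p_outer, self.p_other, self.p_uniform])

    @classmethod
    def pure(cls, strategy: str) -> "StrategyMix":
        if strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {strategy!r}")
        kwargs = {f"p_{s}": (1.0 if s == strategy else 0.0)
                  for s in STRATEGIES}
        return cls(**kwargs)

    @classmethod
    def dominant(cls, strategy: str, weight: float = 0.7) -> "StrategyMix":
        """``weight`` on one strategy, the remainder on uniform exploration."""
        if not 0.0 <= weight <= 1.0:
            raise ValidationError("weight must be in [0, 1]")
        kwargs = {f"p_{s}": 0.0 for s in STRATEGIES}
        kwargs[f"p_{strategy}"] = weight
        kwargs["p_uniform"] = kwargs.get("p_uniform", 0.0) + (1.0 - weight)
        return cls(**kwargs)


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to simulate one experiment, reproducibly."""

    experiment_id: str
    layout: tuple[PathSpec, ...]
    N: int
    seed: int
    mix: StrategyMix
    study_id: str = "synthetic"
    species: str = "rat"
    group_label: str = ""
    scoring: str = "first_choice"
    p_no_choice: float = 0.0
    #: P(adjacent-strategy subject picks the intersecting adjacent arm).
    adjacent_intersect_weight: float = 0.5
    #: P(outer-strategy subject picks the reward-side outer arm).
    outer_reward_weight: float = 0.5
    #: Geometric decay per arm for the smeared-shortcut variant; None = the
    #: shortcut arm exactly.
    shortcut_smear: float | None = None
    #: Target path index for the "other" strategy; default: first unlabelled
    #: scorable path.
    other_index: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "layout", tuple(self.layout))
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if not 0.0 <= self.p_no_choice < 1.0:
            raise ValidationError("p_no_choice must be in [0, 1)")
        # Mutual consistency: build a throwaway record to run the PathSpec
        # invariants over the layout.
        ExperimentRecord(
            study_id="_check", experiment_id="_check", species=self.species,
            group_label="", scoring=self.scoring, paths=self.layout,
            counts=tuple(1 for _ in self.layout))


def make_layout(preset: str, K: int | None = None) -> tuple[PathSpec, ...]:
    """Build a preset role layout over 1-based path indices.

    ``tolman``   — 18 arms, arms 13-18 excluded (12 scorable), shortcut #6,
                   adjacent #9/#10 flanking the training direction (#9
                   intersects the training route's long segment, #10 heads
                   with the first training turn), outer #1 (reward side) and
                   #12 (#12 matches the first turn).
    ``circular`` — full ring of K arms (default 18, min 5), no excluded
                   arms; adjacent #1 (intersecting) and #K, shortcut
                   opposite the training direction, and the cued arm next to
                   it (the lamp sits beside/above the reward, so the arm
                   heading straight at the light is the shortcut's
                   neighbour, not the shortcut itself).
    ``tmaze``    — 5-arm simplified fan: outer #1/#5 (reward side #5,
                   first-turn side #1), adjacent #2/#4; the shortcut
                   coincides with adjacent #4 on the reward side.
    ``enclosed`` — 8 arms, fully enclosed (no outer arms, no cue), adjacent
                   #4/#5, shortcut #2.
    ``harley``   — 6 arms, adjacent #3/#4 with the shortcut overlapping
                   adjacent #4, outer #1/#6 (reward side #6).

    In all presets the blocked training route is a stub that is not itself a
    choosable arm, so no path carries ``is_training``; its geometry is
    encoded by the adjacency / first-turn / reward-side flags.
    """
    if preset == "tolman":
        if K not in (None, 18):
            raise ValidationError("tolman preset requires K=18")
        paths = []
        for i in range(1, 19):
            paths.append(PathSpec(
                index=i,
                is_shortcut=(i == 6),
                is_adjacent=i in (9, 10),
                is_outer=i in (1, 12),
                is_excluded=i >= 13,
                intersects_training=(i == 9),
                matches_first_turn=i in (10, 12),
                reward_side=(i == 1),
            ))
        return tuple(paths)
    if preset == "circular":
        K = 18 if K is None else K
        if K < 5:
            raise ValidationError("circular preset requires K >= 5")
        shortcut = 1 + K // 2
        return tuple(
            PathSpec(index=i,
                     is_shortcut=(i == shortcut),
                     is_cued=(i == shortcut + 1),
                     is_adjacent=i in (1, K),
                     intersects_training=(i == 1),
                     matches_first_turn=(i == K))
            for i in range(1, K + 1))
    if preset == "tmaze":
        if K not in (None, 5):
            raise ValidationError("tmaze preset requires K=5")
        return (
            PathSpec(index=1, is_outer=True, matches_first_turn=True),
            PathSpec(index=2, is_adjacent=True, intersects_training=True),
            PathSpec(index=3),
            PathSpec(index=4, is_adjacent=True, is_shortcut=True,
                     matches_first_turn=False),
            PathSpec(index=5, is_outer=True, reward_side=True),
        )
    if preset == "enclosed":
        if K not in (None, 8):
            raise ValidationError("enclosed preset requires K=8")
        return tuple(
            PathSpec(index=i,
                     is_shortcut=(i == 2),
                     is_adjacent=i in (4, 5),
                     intersects_training=(i == 4),
                     matches_first_turn=(i == 5))
            for i in range(1, 9))
    if preset == "harley":
        if K not in (None, 6):
            raise ValidationError("harley preset requires K=6")
        return (
            PathSpec(index=1, is_outer=True, matches_first_turn=True),
            PathSpec(index=2),
            PathSpec(index=3, is_adjacent=True, intersects_training=True),
            PathSpec(index=4, is_adjacent=True, is_shortcut=True),
            PathSpec(index=5),
            PathSpec(index=6, is_outer=True, reward_side=True),
        )
    raise ValidationError(f"unknown layout preset {preset!r}")


def _strategy_targets(config: SimConfig) -> dict[str, tuple[np.ndarray,
                                                            np.ndarray]]:
    """Per-strategy (path indices, probabilities) over the scorable arms."""
    scorable = [p for p in config.layout if not p.is_excluded]
    idx = np.array([p.index for p in scorable])
    targets: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    uniform = np.full(len(scorable), 1.0 / len(scorable))
    targets["uniform"] = (idx, uniform)

    shortcuts = [p for p in scorable if p.is_shortcut]
    if shortcuts:
        if config.shortcut_smear is None:
            targets["shortcut"] = (np.array([shortcuts[0].index]),
                                   np.array([1.0]))
        else:
            lam = config.shortcut_smear
            w = np.array([lam ** abs(p.index - shortcuts[0].index)
                          for p in scorable])
            targets["shortcut"] = (idx, w / w.sum())

    adjacent = [p for p in scorable if p.is_adjacent]
    if adjacent:
        if len(adjacent) == 2:
            inter = [p for p in adjacent if p.intersects_training]
            if len(inter) == 1:
                other = adjacent[0] if adjacent[1] is inter[0] else adjacent[1]
                w = config.adjacent_intersect_weight
                targets["adjacent"] = (
                    np.array([inter[0].index, other.index]),
                    np.array([w, 1.0 - w]))
            else:
                targets["adjacent"] = (
                    np.array([p.index for p in adjacent]),
                    np.full(2, 0.5))
        else:
            targets["adjacent"] = (np.array([adjacent[0].index]),
                                   np.array([1.0]))

    outer = [p for p in scorable if p.is_outer]
    if outer:
        if len(outer) == 2:
            reward = [p for p in outer if p.reward_side]
            if len(reward) == 1:
                other = outer[0] if outer[1] is reward[0] else outer[1]
                w = config.outer_reward_weight
                targets["outer"] = (
                    np.array([reward[0].index, other.index]),
                    np.array([w, 1.0 - w]))
            else:
                targets["outer"] = (np.array([p.index for p in outer]),
                                    np.full(2, 0.5))
        else:
            targets["outer"] = (np.array([outer[0].index]), np.array([1.0]))

    cued = [p for p in scorable if p.is_cued]
    if cued:
        targets["beacon"] = (np.array([p.index for p in cued]),
                             np.full(len(cued), 1.0 / len(cued)))
    else:
        targets["beacon"] = (idx, uniform)  # no cue: nothing to approach

    unlabelled = [p for p in scorable
                  if not (p.is_shortcut or p.is_adjacent or p.is_outer
                          or p.is_cued or p.is_training)]
    if config.other_index is not None:
        chosen = [p for p in scorable if p.index == config.other_index]
        if not chosen or chosen[0] not in unlabelled:
            raise ValidationError(
                f"other_index {config.other_index} is not an unlabelled "
                "scorable path")
        targets["other"] = (np.array([config.other_index]), np.array([1.0]))
    elif unlabelled:
        targets["other"] = (np.array([unlabelled[0].index]), np.array([1.0]))

    return targets


def simulate_experiment(config: SimConfig) -> ExperimentRecord:
    """Simulate one experiment: N subjects, one scored choice each.

    Each subject independently (optionally) abstains with ``p_no_choice``,
    otherwise draws a strategy from the mixture and a path from that
    strategy's target distribution.  A strategy with positive probability
    but no matching path (and no defined fallback) raises
    :class:`ValidationError`.  Same seed, same record.
    """
    rng = np.random.default_rng(config.seed)
    targets = _strategy_targets(config)
    probs = config.mix.as_array()
    for s, p in zip(STRATEGIES, probs):
        if p > 0 and s not in targets:
            raise ValidationError(
                f"strategy {s!r} has probability {p} but no matching path "
                "in the layout")

    n_no_choice = int(rng.binomial(config.N, config.p_no_choice)) \
        if config.p_no_choice > 0 else 0
    n_choosers = config.N - n_no_choice

    strategy_counts = rng.multinomial(n_choosers, probs)
    counts = {p.index: 0 for p in config.layout}
    for s, k in zip(STRATEGIES, strategy_counts):
        if k == 0:
            continue
        indices, weights = targets[s]
        drawn = rng.multinomial(k, weights)
        for pidx, c in zip(indices, drawn):
            counts[int(pidx)] += int(c)
    return ExperimentRecord(
        study_id=config.study_id, experiment_id=config.experiment_id,
        species=config.species, group_label=config.group_label,
        scoring=config.scoring, paths=config.layout,
        counts=tuple(counts[p.index] for p in config.layout),
        n_no_choice=n_no_choice,
        provenance=f"simulated(seed={config.seed})")


def simulate_dataset(configs) -> Dataset:
    """Simulate one record per config; errors on duplicate experiment ids."""
    configs = list(configs)
    if not configs:
        raise ValidationError("simulate_dataset needs at least one config")
    return Dataset(records=tuple(simulate_experiment(c) for c in configs))


# ---------------------------------------------------------------------------
# YAML/JSON generator configs


def load_sim_configs(path: str | Path) -> list[SimConfig]:
    """Load a list of SimConfigs from a YAML (or JSON) file.

    Schema: a mapping with key ``experiments``: a list of entries, each with
    ``experiment_id``, ``preset`` (or an explicit ``layout`` list of path
    objects), ``N``, ``seed`` and a ``mix`` mapping of strategy
    probabilities; remaining SimConfig fields are optional.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"generator config not found: {path}")
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict) or "experiments" not in payload:
        raise ValidationError(f"{path}: expected a mapping with key "
                              "'experiments'")
    configs = []
    for i, entry in enumerate(payload["experiments"]):
        try:
            if "layout" in entry:
                layout = tuple(
                    PathSpec(index=int(p["index"]),
                             **{k: bool(v) for k, v in p.items()
                                if k != "index"})
                    for p in entry["layout"])
            else:
                layout = make_layout(entry["preset"], entry.get("K"))
            mix = StrategyMix(**{f"p_{k.removeprefix('p_')}": float(v)
                                 for k, v in entry["mix"].items()})
            known = {"experiment_id", "preset", "K", "layout", "N", "seed",
                     "mix", "study_id", "species", "group_label", "scoring",
                     "p_no_choice", "adjacent_intersect_weight",
                     "outer_reward_weight", "shortcut_smear", "other_index"}
            unknown = set(entry) - known
            if unknown:
                raise ValidationError(f"unknown keys {sorted(unknown)}")
            extra = {k: entry[k] for k in
                     ("study_id", "species", "group_label", "scoring",
                      "p_no_choice", "adjacent_intersect_weight",
                      "outer_reward_weight", "shortcut_smear", "other_index")
                     if k in entry}
            configs.append(SimConfig(
                experiment_id=str(entry["experiment_id"]), layout=layout,
                N=int(entry["N"]), seed=int(entry["seed"]), mix=mix,
                **extra))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: experiment entry #{i}: {exc}") from exc
    return configs
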