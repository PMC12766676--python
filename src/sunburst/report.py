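"""Report assembly: run the full analysis over a dataset file and write a
reproducible bundle of tables plus a machine-readable manifest.

The bundle contains ``categories.csv`` (one row per experiment with its
category, role percentages, role z-values and null parameters),
``prevalence.csv``, ``contrasts.csv`` (all four paired-contrast modes),
``tests.json`` (group summaries, permutation p-values, and the
experiment-distribution confidence intervals of the shortcut-vs-adjacent
statistic) and ``manifest.json`` (inputs, parameters, seed, library
versions).  Reruns with an identical config produce byte-identical JSON
and CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .categorization import (InclusionConfig, NullPolicy, categorize_dataset,
                             default_inclusion, prevalence)
from .contrasts import (adjacent_contrast, experiment_distribution_ci,
                        outer_contrast, shortcut_adjacent_delta)
from .errors import AnalysisError, SunburstError, ValidationError
from .experiment_data import Dataset, read_dataset

__all__ = ["RunConfig", "run_analysis", "load_run_config"]

log = logging.getLogger("sunburst")

ARTIFACTS = ("categories.csv", "prevalence.csv", "contrasts.csv",
             "tests.json", "manifest.json")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one analysis run; unknown config-file keys rejected."""

    dataset: str
    out_dir: str = "sunburst_report"
    resamples: int = 1000
    seed: int = 0
    z_cut: float = 1.96
    threshold_mode: str = "z196"  # z196 | p05 | p01
    null_method: str = "resample"  # resample | analytic
    n_perm: int = 10000
    apply_inclusion: bool = True
    mixed_order_whitelist: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.resamples < 1 or self.n_perm < 1:
            raise ValidationError("resamples and n_perm must be positive")
        if self.threshold_mode not in ("z196", "p05", "p01"):
            raise ValidationError(
                f"unknown threshold mode {self.threshold_mode!r}")

    @property
    def effective_z_cut(self) -> float:
        from .chance_model import Z_01, Z_05
        return {"z196": self.z_cut, "p05": Z_05, "p01": Z_01}[
            self.threshold_mode]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValidationError(f"{path}: expected a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys "
                              f"{sorted(unknown)}")
    if "mixed_order_whitelist" in payload:
        payload["mixed_order_whitelist"] = tuple(
            tuple(x) for x in payload["mixed_order_whitelist"])
    return RunConfig(**payload)


def _categories_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {"study_id": res.study_id, "experiment_id": res.experiment_id,
               "category": res.category,
               "winning_role": res.winning_role or "",
               "null_used": res.null_used}
        for role, pct in sorted(res.role_percentages.items()):
            row[f"pct_{role}"] = round(pct, 6)
        for role, z in sorted(res.role_z.items()):
            row[f"z_{role}"] = round(z, 6)
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Run the whole pipeline and write the report bundle.

    Returns a dict with the in-memory results (categories, prevalence,
    contrast summaries).  Any stage failure aborts with a stage-labelled
    message and removes partial outputs written by this run.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        target = out_dir / name
        writer(target)
        written.append(target)
        log.info("wrote %s", target)

    stage = "read"
    try:
        if dataset is None:
            dataset = read_dataset(config.dataset)
        log.info("dataset: %d experiments", len(dataset))

        stage = "inclusion"
        if config.apply_inclusion:
            included = default_inclusion(dataset, InclusionConfig(
                mixed_order_whitelist=config.mixed_order_whitelist))
        else:
            included = dataset
        if len(included) == 0:
            raise AnalysisError("no experiments left after inclusion "
                                "filtering")

        stage = "categorization"
        policy = NullPolicy(method=config.null_method, R=config.resamples,
                            seed=config.seed)
        z_cut = config.effective_z_cut
        results = categorize_dataset(included, policy, z_cut=z_cut)
        prev = prevalence(included, policy, z_cut=z_cut)
        emit("categories.csv",
             lambda p: _categories_frame(results).to_csv(p, index=False))
        emit("prevalence.csv", lambda p: pd.DataFrame(
            [{"category": k, "percent": round(v, 6)}
             for k, v in prev.items()]).to_csv(p, index=False))

        stage = "contrasts"
        contrast_results = [
            adjacent_contrast(included, mode, z_cut=z_cut, null_policy=policy,
                              n_perm=config.n_perm, seed=config.seed)
            for mode in ("intersect", "first_turn")
        ] + [
            outer_contrast(included, mode, z_cut=z_cut, null_policy=policy,
                           n_perm=config.n_perm, seed=config.seed)
            for mode in ("reward_side", "first_turn")
        ]
        frames = [c.table.assign(contrast=kind)
                  for c, kind in zip(contrast_results,
                                     ("adjacent", "adjacent",
                                      "outer", "outer"))]
        filled = [f for f in frames if not f.empty]
        table = (pd.concat(filled, ignore_index=True)
                 if filled else frames[0])
        emit("contrasts.csv", lambda p: table.to_csv(p, index=False))

        stage = "distribution"
        deltas = []
        for rec in included:
            try:
                deltas.append(shortcut_adjacent_delta(rec, policy))
            except AnalysisError:
                continue
        cis = (experiment_distribution_ci(deltas)
               if len(deltas) >= 2 else None)

        stage = "tests"
        tests_payload = {
            "contrasts": [
                {"contrast": kind, "mode": c.mode, **asdict(c.summary)}
                for c, kind in zip(contrast_results,
                                   ("adjacent", "adjacent", "outer", "outer"))
            ],
            "shortcut_adjacent_delta_ci": (
                {str(level): list(bounds) for level, bounds in cis.items()}
                if cis else None),
            "n_delta_experiments": len(deltas),
        }
        emit("tests.json", lambda p: p.write_text(
            json.dumps(tests_payload, indent=2, sort_keys=True,
                       allow_nan=True)))

        stage = "manifest"
        dataset_path = Path(config.dataset)
        manifest = {
            "package_version": __version__,
            "config": {**asdict(config)},
            "dataset_sha256": hashlib.sha256(
                dataset_path.read_bytes()).hexdigest()
            if dataset_path.exists() else None,
            "n_experiments_input": len(dataset),
            "n_experiments_included": len(included),
            "versions": _library_versions(),
        }
        emit("manifest.json", lambda p: p.write_text(
            json.dumps(manifest, indent=2, sort_keys=True)))
    except SunburstError as exc:
        for target in written:
            target.unlink(missing_ok=True)
        raise AnalysisError(f"analysis failed at stage '{stage}': {exc}"
                            ) from exc
    return {"categories": results, "prevalence": prev,
            "contrasts": contrast_results, "delta_ci": cis,
            "out_dir": str(out_dir)}


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy
    return {"numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__}
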