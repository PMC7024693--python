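"""End-to-end orchestration: cohort -> classification -> rates -> models -> trees.

One :class:`RunConfig` drives a reproducible run that emits the analysis
artifacts (classified cohort, rate table, above-threshold decomposition,
model tables for the full/above/below samples, staged AIC/LR comparison,
tree renderings) plus a manifest recording the config hash and seed.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cohort import (
    SUBSCALE_RANGES,
    StudentRecord,
    ThresholdConfig,
    analysable_subset,
    read_cohort,
    records_to_frame,
)
from .multinomial import (
    ModelError,
    ModelSpec,
    fit_multinomial,
    significance_policy,
    staged_comparison,
)
from .reliable import (
    RCIConfig,
    above_threshold_decomposition,
    classify_cohort,
    rate_table,
    split_by_threshold,
)
from .synthetic import AttritionConfig, CohortConfig, apply_attrition, generate
from .tree import TreeConfig, grow_tree, render_tree, tree_to_dict

logger = logging.getLogger("sdqchange")

SAMPLE_LABELS = ("full", "above", "below")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run: exactly one of ``cohort`` / ``input_path``."""

    cohort: Optional[CohortConfig] = None
    input_path: Optional[str] = None
    rci: RCIConfig = field(default_factory=RCIConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    out_dir: str = "sdqchange_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_path is None):
            raise PipelineError(
                "config must carry exactly one of a cohort config or an "
                "input CSV path"
            )


def _stage_seed(seed: int, stage: int) -> int:
    """Fixed fan-out of the global seed into per-stage sub-seeds."""
    h = hashlib.sha256(f"sdqchange:{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _config_dict(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(config)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def attrition_report(
    full_t1: Sequence[StudentRecord], followed: Sequence[StudentRecord]
) -> pd.DataFrame:
    """Welch t comparison of T1 scores, followed-up versus dropped.

    ``followed`` must be a subset (by id) of ``full_t1``; each group needs
    at least two records.
    """
    followed_ids = {r.id for r in followed}
    unknown = followed_ids - {r.id for r in full_t1}
    if unknown:
        raise PipelineError(
            f"followed records not present in the full cohort: {sorted(unknown)[:5]}"
        )
    dropped = [r for r in full_t1 if r.id not in followed_ids]
    if len(followed) < 2 or len(dropped) < 2:
        raise PipelineError(
            "attrition report needs at least two records in each group "
            f"(followed {len(followed)}, dropped {len(dropped)})"
        )
    rows = []
    for name in SUBSCALE_RANGES:
        a = np.array([getattr(r.t1, name) for r in followed], float)
        b = np.array([getattr(r.t1, name) for r in dropped], float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(t) and a.var() == 0.0 and b.var() == 0.0:
            # both groups constant: no evidence of a difference
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        rows.append(
            {
                "subscale": name,
                "mean_followed": a.mean(),
                "mean_dropped": b.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["follow_up_proportion"] = len(followed) / len(full_t1)
    return out


def _write_classified(records, results, rci: RCIConfig, path: Path) -> None:
    frame = records_to_frame(records)
    for name in ("emotional", "conduct", "hyperactivity"):
        frame[f"delta_{name}"] = [r.deltas[name] for r in results]
        frame[f"rci_{name}"] = [round(r.rci[name], 6) for r in results]
        frame[f"status_{name}"] = [r.subscale_status[name] for r in results]
    frame["overall"] = [r.overall for r in results]
    frame.to_csv(path, index=False, encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, list] = {}

    stage = "cohort"
    try:
        if config.cohort is not None:
            cohort_cfg = replace(config.cohort, seed=_stage_seed(config.seed, 0))
            full_t1 = generate(cohort_cfg)
            if cohort_cfg.attrition.enabled:
                after = apply_attrition(full_t1, cohort_cfg)
                followed = analysable_subset(after)
                report = attrition_report(full_t1, followed)
                report.to_csv(out / "attrition.csv", index=False)
                artifacts["attrition_report"] = ["attrition.csv"]
                records = followed
            else:
                records = analysable_subset(full_t1)
        else:
            records = analysable_subset(read_cohort(config.input_path))
        if not records:
            raise PipelineError("no analysable records")
        logger.info("cohort: %d analysable records", len(records))

        stage = "classify"
        results = classify_cohort(records, config.rci)
        _write_classified(records, results, config.rci, out / "classified.csv")
        artifacts["classified_cohort"] = ["classified.csv"]

        stage = "split"
        halves = split_by_threshold(records, config.thresholds)
        index = {id(r): res for r, res in zip(records, results)}
        samples = {
            "full": (records, results),
            "above": (halves["above"], [index[id(r)] for r in halves["above"]]),
            "below": (halves["below"], [index[id(r)] for r in halves["below"]]),
        }

        stage = "rates"
        table = rate_table(
            samples["full"][1], samples["above"][1], samples["below"][1]
        )
        table.to_frame().to_csv(out / "rates.csv", index=False)
        (out / "rates.txt").write_text(table.to_text() + "\n", encoding="utf-8")
        artifacts["rate_table"] = ["rates.csv", "rates.txt"]

        stage = "decomposition"
        decomp = above_threshold_decomposition(
            samples["above"][0], samples["above"][1], config.thresholds, config.rci
        )
        drow = {
            "improved_on_elevated": decomp.improved_on_elevated,
            "improved_on_other": decomp.improved_on_other,
            "deteriorated_on_elevated": decomp.deteriorated_on_elevated,
            "deteriorated_on_other": decomp.deteriorated_on_other,
            "n_above": decomp.n_above,
            **{k: v for k, v in decomp.percentages().items()},
        }
        pd.DataFrame([drow]).to_csv(out / "decomposition.csv", index=False)
        artifacts["decomposition"] = ["decomposition.csv"]

        stage = "models"
        model_files, stage_files, warnings_log = [], [], {}
        for label in SAMPLE_LABELS:
            recs, ress = samples[label]
            alpha = significance_policy(label)
            fname, sname = f"model_{label}.csv", f"stages_{label}.csv"
            try:
                fit = fit_multinomial(ModelSpec.for_stage("full"), recs, ress)
                summary = fit.summary_frame(alpha=alpha)
                summary.insert(0, "sample", label)
                summary.to_csv(out / fname, index=False)
                staged = staged_comparison(recs, ress, label)
                staged.to_csv(out / sname, index=False)
            except ModelError as exc:
                # small or degenerate sub-samples (separation, empty
                # cells) are flagged, not fatal: the run stays usable
                note = pd.DataFrame([{"sample": label, "error": str(exc)}])
                note.to_csv(out / fname, index=False)
                note.to_csv(out / sname, index=False)
                warnings_log[label] = str(exc)
                logger.warning("model stage (%s sample): %s", label, exc)
            model_files.append(fname)
            stage_files.append(sname)
        artifacts["model_tables"] = model_files
        artifacts["staged_comparison"] = stage_files

        stage = "trees"
        tree_files = []
        for label in SAMPLE_LABELS:
            recs, ress = samples[label]
            tree_cfg = replace(config.tree, seed=_stage_seed(config.seed, 5))
            tree = grow_tree(recs, ress, config=tree_cfg)
            (out / f"tree_{label}.txt").write_text(
                render_tree(tree) + "\n", encoding="utf-8"
            )
            (out / f"tree_{label}.json").write_text(
                json.dumps(tree_to_dict(tree), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            tree_files += [f"tree_{label}.txt", f"tree_{label}.json"]
        artifacts["tree_renderings"] = tree_files

        stage = "manifest"
        artifacts["manifest"] = ["manifest.json"]
        manifest = {
            "model_warnings": warnings_log,
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config),
            "n_analysable": len(records),
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


# --------------------------------------------------------------------------
# Structured-text (YAML) run configuration
# --------------------------------------------------------------------------

def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Build a RunConfig from a nested key/value YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)


def run_config_from_dict(data: dict) -> RunConfig:
    kwargs: dict = {}
    if "cohort" in data:
        cohort = dict(data["cohort"])
        if "attrition" in cohort:
            cohort["attrition"] = AttritionConfig(**cohort["attrition"])
        if "effect_log_odds" in cohort:
            cohort["effect_log_odds"] = {
                k: tuple(v) for k, v in cohort["effect_log_odds"].items()
            }
        kwargs["cohort"] = CohortConfig(**cohort)
    if "input_path" in data:
        kwargs["input_path"] = data["input_path"]
    if "rci" in data:
        kwargs["rci"] = RCIConfig(**data["rci"])
    if "thresholds" in data:
        kwargs["thresholds"] = ThresholdConfig(**data["thresholds"])
    if "tree" in data:
        kwargs["tree"] = TreeConfig(**data["tree"])
    for key in ("out_dir", "seed", "log_level"):
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)
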