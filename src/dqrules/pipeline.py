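"""End-to-end orchestration: simulate/read -> split -> mine -> clean -> assess.

One call produces, per digit level and mined age group, a cleaned rule
set plus filter report, and optionally a bias/variance assessment of the
records against the surviving rules.  All outputs are accumulated in
memory and flushed together at the end, so a failing stage leaves no
partial files; a run manifest records the seed, thresholds, stage
counts, and a hash of the configuration.  Reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .assessment import (DEFAULT_CI_LEVEL, DEFAULT_MIN_LHS_COUNT,
                         DEFAULT_TOP_K, DEFAULT_VOLUME_FLOOR, assess,
                         rank_rules)
from .filtering import (DEFAULT_ALPHA, DEFAULT_NESTED_DELTA,
                        DEFAULT_STABILITY_MAX_DIFF, DEFAULT_TRAIN_FRACTION,
                        run_cascade, split_records)
from .icd import AsteriskRegistry
from .io import RuleSetFile, read_records, ruleset_to_json, write_records
from .mining import (DEFAULT_MAX_ITEMSET_SIZE, DEFAULT_MIN_CONFIDENCE,
                     DEFAULT_MIN_SUPPORT_COUNT, build_transactions,
                     derive_rules, mine_frequent_itemsets)
from .records import MINED_AGE_GROUPS
from .synthetic import SimulationConfig, generate_records


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults are the study parameterization.

    Exactly one of ``simulation`` / ``records_path`` supplies the input
    records.
    """

    simulation: Optional[SimulationConfig] = None
    records_path: Optional[str] = None
    records_dialect: str = "long"
    levels: tuple[int, ...] = (3, 4)
    age_groups: tuple[str, ...] = MINED_AGE_GROUPS
    min_confidence: float = DEFAULT_MIN_CONFIDENCE
    min_support_count: int = DEFAULT_MIN_SUPPORT_COUNT
    max_itemset_size: int = DEFAULT_MAX_ITEMSET_SIZE
    nested_delta: float = DEFAULT_NESTED_DELTA
    alpha: float = DEFAULT_ALPHA
    stability_max_diff: float = DEFAULT_STABILITY_MAX_DIFF
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    registry: AsteriskRegistry = field(default_factory=AsteriskRegistry)
    strict_asterisk: bool = False
    run_assessment: bool = True
    #: hospital id -> group label; defaults to the simulation's profiles.
    hospital_groups: Optional[dict[str, str]] = None
    volume_floor: int = DEFAULT_VOLUME_FLOOR
    min_lhs_count: int = DEFAULT_MIN_LHS_COUNT
    ci_level: float = DEFAULT_CI_LEVEL
    top_k: int = DEFAULT_TOP_K
    seed: int = 0
    write_records_csv: bool = False

    def validate(self) -> None:
        if (self.simulation is None) == (self.records_path is None):
            raise ValueError(
                "exactly one of simulation / records_path must be set")
        for level in self.levels:
            if level not in (3, 4):
                raise ValueError(f"bad digit level {level}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must be in (0, 1)")

    def config_hash(self) -> str:
        blob = {
            k: v for k, v in {
                "simulation": (self.simulation.to_dict()
                               if self.simulation else None),
                "records_path": self.records_path,
                "levels": list(self.levels),
                "age_groups": list(self.age_groups),
                "min_confidence": self.min_confidence,
                "min_support_count": self.min_support_count,
                "max_itemset_size": self.max_itemset_size,
                "nested_delta": self.nested_delta,
                "alpha": self.alpha,
                "stability_max_diff": self.stability_max_diff,
                "train_fraction": self.train_fraction,
                "registry": [sorted(self.registry.asterisk_codes),
                             sorted(self.registry.pairings)],
                "strict_asterisk": self.strict_asterisk,
                "volume_floor": self.volume_floor,
                "min_lhs_count": self.min_lhs_count,
                "ci_level": self.ci_level,
                "top_k": self.top_k,
                "seed": self.seed,
            }.items()
        }
        payload = json.dumps(blob, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    manifest: dict
    rulesets: dict[tuple[str, int], list]  # (age group, level) -> rules
    out_dir: Path


def _safe_label(age_group: str) -> str:
    return age_group.replace("+", "plus").replace("-", "_")


def run_pipeline(config: PipelineConfig,
                 out_dir: Union[str, Path]) -> PipelineResult:
    """Execute the full rule-development (and assessment) pipeline."""
    config.validate()
    out_dir = Path(out_dir)
    outputs: dict[str, str] = {}  # relative path -> text content
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "thresholds": {
            "min_confidence": config.min_confidence,
            "min_support_count": config.min_support_count,
            "max_itemset_size": config.max_itemset_size,
            "nested_delta": config.nested_delta,
            "alpha": config.alpha,
            "stability_max_diff": config.stability_max_diff,
            "train_fraction": config.train_fraction,
            "volume_floor": config.volume_floor,
            "min_lhs_count": config.min_lhs_count,
            "ci_level": config.ci_level,
            "top_k": config.top_k,
        },
        "stages": {},
    }

    stage = "input"
    try:
        if config.simulation is not None:
            records = generate_records(config.simulation, seed=config.seed)
            manifest["stages"]["input"] = {"source": "simulation",
                                           "n_records": len(records)}
        else:
            records, report = read_records(config.records_path,
                                           config.records_dialect)
            manifest["stages"]["input"] = {
                "source": config.records_path,
                "n_records": len(records),
                "n_malformed_rows": len(report.errors),
                "n_dropped_empty": report.n_dropped_empty,
            }

        stage = "split"
        train, validation = split_records(records, config.train_fraction,
                                          seed=config.seed)
        manifest["stages"]["split"] = {"n_train": len(train),
                                       "n_validation": len(validation)}

        rulesets: dict[tuple[str, int], list] = {}
        for level in config.levels:
            for age_group in config.age_groups:
                stage = f"mine[{age_group}/L{level}]"
                train_db = build_transactions(train, level, age_group)
                val_db = build_transactions(validation, level, age_group)
                itemsets = mine_frequent_itemsets(
                    train_db, config.min_support_count,
                    config.max_itemset_size)
                mined = derive_rules(itemsets, train_db,
                                     config.min_confidence,
                                     config.min_support_count)

                stage = f"filter[{age_group}/L{level}]"
                kept, report = run_cascade(
                    mined, train_db, val_db, config.registry,
                    nested_delta=config.nested_delta, alpha=config.alpha,
                    stability_max_diff=config.stability_max_diff,
                    strict_asterisk=config.strict_asterisk)
                rulesets[(age_group, level)] = kept

                tag = f"{_safe_label(age_group)}_L{level}"
                provenance = {
                    "age_group": age_group, "level": level,
                    "seed": config.seed,
                    "config_hash": manifest["config_hash"],
                    "thresholds": manifest["thresholds"],
                    "source": "training split",
                }
                outputs[f"rules_{tag}.json"] = ruleset_to_json(
                    RuleSetFile(rules=kept, provenance=provenance))
                outputs[f"review_{tag}.csv"] = _review_csv_text(kept)
                outputs[f"filter_report_{tag}.tsv"] = _tsv_text(
                    [("stage", "rule_id", "reason")] + report.to_rows())
                manifest["stages"][f"{age_group}/L{level}"] = {
                    "n_train_transactions": train_db.n,
                    "n_validation_transactions": val_db.n,
                    "n_mined": len(mined),
                    "cascade": [
                        {"stage": s.stage, "input": s.n_input,
                         "removed": s.n_removed, "retained": s.n_retained}
                        for s in report.stages
                    ],
                    "n_final": len(kept),
                }

        if config.run_assessment:
            stage = "assess"
            groups = config.hospital_groups
            if groups is None and config.simulation is not None:
                groups = {h.hospital_id: h.group
                          for h in config.simulation.hospitals}
            if groups is None:
                raise ValueError("assessment needs hospital_groups")
            all_rules = [r for rules in rulesets.values() for r in rules]
            result = assess(all_rules, records, groups,
                            min_volume=config.volume_floor,
                            min_lhs_count=config.min_lhs_count,
                            level=config.ci_level)
            for metric in ("bias", "variance"):
                ranked = rank_rules(result, metric, config.top_k)
                outputs[f"top_{metric}.tsv"] = _ranking_tsv(ranked, metric)
            outputs["assessment.tsv"] = _assessment_tsv(result)
            manifest["stages"]["assess"] = {
                "n_rules": len(all_rules),
                "n_bias_results": len(result.biases),
                "n_variance_results": len(result.variances),
            }

        if config.write_records_csv:
            stage = "write-records"
            out_dir.mkdir(parents=True, exist_ok=True)
            write_records(records, out_dir / "records.csv",
                          config.records_dialect)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs["manifest.json"] = json.dumps(manifest, indent=2,
                                          sort_keys=True) + "\n"
    out_dir.mkdir(parents=True, exist_ok=True)
    for rel, text in sorted(outputs.items()):
        (out_dir / rel).write_text(text)
    return PipelineResult(manifest=manifest, rulesets=rulesets,
                          out_dir=out_dir)


def _tsv_text(rows) -> str:
    return "".join("\t".join(str(c) for c in row) + "\n" for row in rows)


def _review_csv_text(rules) -> str:
    from .io import rule_display
    lines = ["rule,lhs,rhs,confidence,support,support_count,age_group,level"]
    for r in rules:
        lines.append(",".join([
            rule_display(r), "+".join(sorted(r.lhs)), r.rhs,
            f"{r.confidence:.6f}", f"{r.support:.6f}",
            str(r.joint_count), r.age_group, str(r.level)]))
    return "\n".join(lines) + "\n"


def _assessment_tsv(result) -> str:
    rows = [("group", "rule_id", "metric", "value", "breakdown")]
    for b in result.biases:
        if not b.defined:
            continue
        breakdown = ";".join(f"{h}:{c:.6f}" for h, c in b.contributions)
        rows.append((b.group, b.rule_id, "bias", f"{b.bias:.6f}",
                     breakdown))
    for v in result.variances:
        if not v.defined:
            continue
        breakdown = ";".join(
            f"{p.hospital_pair[0]}|{p.hospital_pair[1]}:"
            f"{p.contribution:.6f}" for p in v.pairs)
        rows.append((v.group, v.rule_id, "variance", f"{v.variance:.6f}",
                     breakdown))
    return _tsv_text(rows)


def _ranking_tsv(ranked, metric) -> str:
    rows = [("group", "rank", "rule_id", metric)]
    for group, items in ranked.items():
        for rank, res in enumerate(items, 1):
            value = res.bias if metric == "bias" else res.variance
            rows.append((group, rank, res.rule_id, f"{value:.6f}"))
    return _tsv_text(rows)
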