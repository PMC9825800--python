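"""End-to-end analysis pipeline: QC -> weights -> estimates -> contrasts.

Each stage writes its artifact (CSV/JSON) to the output directory so any
downstream stage can be rerun from saved intermediates; the whole run is
deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .bootstrap import bootstrap_estimates, difference_test
from .design import RRTDesign, STUDY_DESIGN
from .estimator import prevalence_bounds
from .records import CategoryMap, QCConfig, SPORT_CATEGORIES, doper_records, doping_records, quality_filter
from .weighting import PopulationMargins, compute_weights

__all__ = ["PipelineConfig", "run_pipeline", "summarize"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    input_csv: str
    output_dir: str = "rrtprev_out"
    category_map_csv: Optional[str] = None
    margins_csv: Optional[str] = None
    design: RRTDesign = STUDY_DESIGN
    qc: QCConfig = field(default_factory=QCConfig)
    questions: tuple[str, ...] = ("otc", "medication", "image")
    B: int = 2000
    alpha: float = 0.05
    level: float = 0.95
    seed: int = 0
    #: groups with fewer answered records are reported "not estimable"
    min_records: int = 200
    #: compare each category against the pool including (True) or excluding it
    include_group_in_reference: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "design" in kwargs:
            kwargs["design"] = RRTDesign.from_dict(kwargs["design"])
        if "qc" in kwargs:
            kwargs["qc"] = QCConfig(**kwargs["qc"])
        if "questions" in kwargs:
            kwargs["questions"] = tuple(kwargs["questions"])
        return cls(**kwargs)


def _question_entry(records, question, design, cfg, weight_col=None) -> dict:
    res = bootstrap_estimates(
        records, question, design, B=cfg.B, level=cfg.level, seed=cfg.seed,
        weight_col=weight_col,
    )
    lo, hi = prevalence_bounds(res.point)
    answered = records[records[f"{question}_answer"].isin(["yes", "no"])]
    return {
        "question": question,
        "n": int(len(answered)),
        "weighted_n": _wsum(answered, weight_col, question),
        "estimate": res.to_dict()["estimate"],
        "boundary_case": res.to_dict()["boundary_case"],
        "ci": res.to_dict()["ci"],
        "bounds": {"lower": lo, "upper": hi},
        "estimable": True,
    }


def _wsum(answered, weight_col, question) -> float:
    for cand in (weight_col, f"weight_{question}", "weight"):
        if cand and cand in answered.columns:
            return float(answered[cand].sum())
    return float(len(answered))


def _attach_weights(frame, question, margins) -> pd.DataFrame:
    if margins is None:
        return frame
    wt = compute_weights(frame, question, margins)
    out = frame.loc[wt.index].copy()
    out["weight"] = wt["weight"].to_numpy()
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute QC, weighting, per-question estimation and category
    contrasts; write artifacts under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    try:
        records = pd.read_csv(config.input_csv)
    except FileNotFoundError as e:
        raise PipelineError("load", f"input file not found: {config.input_csv}") from e
    margins = None
    if config.margins_csv:
        try:
            margins = PopulationMargins.from_csv(config.margins_csv)
        except FileNotFoundError as e:
            raise PipelineError("load", f"margins file not found: {config.margins_csv}") from e
    cmap = (
        CategoryMap.from_csv(config.category_map_csv)
        if config.category_map_csv
        else CategoryMap()
    )

    kept, audit = quality_filter(records, config.qc)
    log.append(f"qc: {len(records)} in, {len(kept)} kept, {len(audit)} dropped")
    kept.to_csv(outdir / "records_qc.csv", index=False)
    with open(outdir / "qc_audit.jsonl", "w") as fh:
        for entry in audit:
            fh.write(json.dumps(entry, default=str) + "\n")

    report: dict = {"config": {"seed": config.seed, "B": config.B, "alpha": config.alpha}, "questions": [], "log": log}

    for q in config.questions:
        frame = _attach_weights(kept, q, margins)
        try:
            report["questions"].append(
                _question_entry(frame, q, config.design, config, weight_col="weight" if margins is not None else None)
            )
        except (KeyError, ValueError) as e:
            raise PipelineError("estimate", f"question {q!r}: {e}") from e

    # doping behaviour: per sport record, overall and by category
    long = doping_records(kept, cmap)
    long.to_csv(outdir / "doping_records.csv", index=False)
    doping_block: dict = {"mode": "doping", "overall": None, "by_category": {}, "contrasts": {}}
    if len(long):
        frame = _attach_weights(long, "doping", margins)
        doping_block["overall"] = _question_entry(frame, "doping", config.design, config,
                                                  weight_col="weight" if margins is not None else None)
        for cat in SPORT_CATEGORIES:
            grp = frame[frame["category"] == cat]
            n_ans = int(grp["doping_answer"].isin(["yes", "no"]).sum())
            if n_ans < config.min_records:
                doping_block["by_category"][cat] = {
                    "category": cat, "n": n_ans, "estimable": False, "reason": "too few records",
                }
                log.append(f"category {cat}: {n_ans} records < {config.min_records}, not estimable")
                continue
            doping_block["by_category"][cat] = dict(
                _question_entry(grp, "doping", config.design, config,
                                weight_col="weight" if margins is not None else None),
                category=cat,
            )
            ref = frame if config.include_group_in_reference else frame[frame["category"] != cat]
            test = difference_test(
                grp, ref, "doping", config.design, B=config.B,
                alpha=config.alpha, seed=config.seed,
                weight_col="weight" if margins is not None else None,
            )
            doping_block["contrasts"][cat] = test.to_dict()
    report["doping"] = doping_block

    # dopers: one record per individual, yes-preferred
    dop, excluded = doper_records(kept, cmap, seed=config.seed)
    dop.to_csv(outdir / "doper_records.csv", index=False)
    doper_block: dict = {"mode": "doper", "overall": None, "by_gender": {}, "excluded": len(excluded)}
    if len(dop):
        frame = _attach_weights(dop, "doper", margins)
        doper_block["overall"] = _question_entry(frame, "doper", config.design, config,
                                                 weight_col="weight" if margins is not None else None)
        for gender, grp in frame.groupby("gender"):
            n_ans = int(grp["doper_answer"].isin(["yes", "no"]).sum())
            if n_ans < config.min_records:
                doper_block["by_gender"][gender] = {"n": n_ans, "estimable": False, "reason": "too few records"}
                continue
            doper_block["by_gender"][gender] = _question_entry(
                grp, "doper", config.design, config,
                weight_col="weight" if margins is not None else None,
            )
    report["dopers"] = doper_block

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _fmt_row(entry: dict) -> str:
    if not entry or not entry.get("estimable", False):
        n = entry.get("n", 0) if entry else 0
        return f"  n={n:>6}  not estimable"
    e = entry["estimate"]
    lo, hi = entry["ci"]["theta_yes"]
    b = entry["bounds"]
    return (
        f"  n={entry['n']:>6}  yes={100 * e['yes']:5.1f}%  no={100 * e['no']:5.1f}%  "
        f"inc={100 * e['inc']:5.1f}%  ci_yes=[{100 * lo:.1f}%, {100 * hi:.1f}%]  "
        f"bounds=[{100 * b['lower']:.1f}%, {100 * b['upper']:.1f}%]"
    )


def summarize(report: dict) -> str:
    """Human-readable per-question / per-group summary of a report bundle."""
    lines = ["RRT prevalence report", "====================="]
    for entry in report.get("questions", []):
        lines.append(f"question {entry['question']}:")
        lines.append(_fmt_row(entry))
    dop = report.get("doping", {})
    if dop.get("overall"):
        lines.append("doping (per sport record), overall:")
        lines.append(_fmt_row(dop["overall"]))
        for cat, entry in dop.get("by_category", {}).items():
            sig = dop.get("contrasts", {}).get(cat, {}).get("significant")
            tag = "" if sig is None else f"  vs overall: {'significant' if sig else 'n.s.'}"
            lines.append(f"doping, {cat}:")
            lines.append(_fmt_row(entry) + tag)
    dpr = report.get("dopers", {})
    if dpr.get("overall"):
        lines.append("dopers (per individual), overall:")
        lines.append(_fmt_row(dpr["overall"]))
        for g, entry in dpr.get("by_gender", {}).items():
            lines.append(f"dopers, {g}:")
            lines.append(_fmt_row(entry))
    return "\n".join(lines)
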