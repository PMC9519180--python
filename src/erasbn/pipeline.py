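"""End-to-end run: selection protocol per outcome, then structure learning.

For each numeric outcome the pipeline binarizes at the mean, fits the star
model, retains high-posterior combinations, runs the single-indicator and
cumulative analyses, selects the significant indicators, and finally learns
the decision DAG over (selected indicators + binarized outcome) with LSHCT.
Every artifact is written deterministically so a rerun with the same inputs
and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import DiscreteDataset
from .io import read_dataset, read_schema, write_graph
from .selection import SelectionReport, discretize_by_mean, run_selection
from .structure import LshctConfig, lshct
from .core import VariableSpec

__all__ = ["RunConfig", "run_pipeline", "render_breakdown_tsv",
           "render_cumulative_tsv", "report_to_json"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; all randomness derives from ``seed``."""

    input_path: str
    schema_path: str
    output_dir: str
    outcomes: tuple[str, ...] = ()
    retention_threshold: float = 0.9
    alpha: float = 0.05
    equivalent_sample_size: float = 1.0
    lshct: LshctConfig = field(default_factory=LshctConfig)
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.retention_threshold < 1.0):
            raise ValueError("retention_threshold must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def render_breakdown_tsv(report: SelectionReport) -> str:
    """Single-indicator table: grade counts/percents per pool, p per indicator."""
    lines = ["indicator\tgrade\tstate0_count\tstate0_percent\t"
             "state1_count\tstate1_percent\tp"]
    for r in report.breakdown:
        lines.append(
            f"{r.indicator}\t{r.grade}\t{r.count0}\t{r.percent0:.2f}\t"
            f"{r.count1}\t{r.percent1:.2f}\t{r.p:.6g}"
        )
    return "\n".join(lines) + "\n"


def render_cumulative_tsv(report: SelectionReport) -> str:
    """Cumulative combination table, one step per line."""
    lines = ["step\tindicator\tgrade\tstate0_count\tstate0_proportion\t"
             "state1_count\tstate1_proportion\tp"]
    for r in report.cumulative:
        p = "" if r.p is None else f"{r.p:.6g}"
        lines.append(
            f"{r.step}\t{r.indicator}\t{r.grade}\t{r.count0}\t"
            f"{r.proportion0:.4f}\t{r.count1}\t{r.proportion1:.4f}\t{p}"
        )
    return "\n".join(lines) + "\n"


def report_to_json(report: SelectionReport) -> str:
    doc = dataclasses.asdict(report)
    doc["selected"] = sorted(report.selected)
    doc["breakdown"] = [dataclasses.asdict(r) for r in report.breakdown]
    doc["cumulative"] = [dataclasses.asdict(r) for r in report.cumulative]
    return json.dumps(doc, indent=2, default=list) + "\n"


def run_pipeline(config: RunConfig) -> dict[str, dict[str, Path]]:
    """Execute the two-stage protocol; returns artifact paths per outcome."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema, schema_outcomes = read_schema(config.schema_path)
    outcomes = tuple(config.outcomes) or tuple(schema_outcomes)
    if not outcomes:
        raise ValueError("no outcome columns configured")
    data, numeric = read_dataset(config.input_path, schema)
    artifacts: dict[str, dict[str, Path]] = {}
    for outcome in outcomes:
        if outcome not in numeric.columns:
            raise ValueError(f"outcome column {outcome!r} not in input")
        values = [None if v != v else float(v) for v in numeric[outcome]]
        report = run_selection(
            data,
            values,
            outcome,
            retention_threshold=config.retention_threshold,
            alpha=config.alpha,
            equivalent_sample_size=config.equivalent_sample_size,
        )
        selected = sorted(report.selected,
                          key=[v.name for v in data.variables].index)
        # learn the decision DAG over the selected indicators + outcome state
        _, labels = discretize_by_mean(values, outcome)
        sub = data.select_variables(selected)
        frame = sub.frame.copy()
        frame[outcome] = labels
        learn_data = DiscreteDataset(
            list(sub.variables) + [VariableSpec(outcome, ("0", "1"), "outcome")],
            frame,
        )
        trace: dict = {}
        dag = lshct(learn_data, config.lshct, trace=trace)
        paths = {
            "breakdown": out_dir / f"{outcome}_breakdown.tsv",
            "cumulative": out_dir / f"{outcome}_cumulative.tsv",
            "report": out_dir / f"{outcome}_selection.json",
            "graph_dot": out_dir / f"{outcome}_dag.dot",
            "graph_edges": out_dir / f"{outcome}_dag.edges.tsv",
            "log": out_dir / f"{outcome}_log.json",
        }
        paths["breakdown"].write_text(render_breakdown_tsv(report), "utf-8")
        paths["cumulative"].write_text(render_cumulative_tsv(report), "utf-8")
        paths["report"].write_text(report_to_json(report), "utf-8")
        write_graph(dag, paths["graph_dot"], "dot")
        write_graph(dag, paths["graph_edges"], "edge_list")
        log = {
            "outcome": outcome,
            "threshold": report.binarization.threshold,
            "pool_sizes": list(report.pool_sizes),
            "n_combinations": list(report.n_combinations),
            "selected": sorted(report.selected),
            "score_assembled": trace.get("score_assembled"),
            "score_final": trace.get("score_final"),
            "sccs": [sorted(c) for c in trace.get("sccs", [])],
            "decisions": list(report.log),
        }
        if config.verbosity > 0:
            log["mi_matrix"] = trace["mi"].values.tolist()
            log["mi_order"] = list(trace["mi"].order)
            log["merged_edges"] = sorted(trace["merged"].edges)
        paths["log"].write_text(json.dumps(log, indent=2) + "\n", "utf-8")
        artifacts[outcome] = paths
    return artifacts
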