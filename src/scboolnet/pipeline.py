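"""End-to-end orchestration: network -> binarization -> attractors -> consensus.

One configuration object drives the full analysis: load (or construct) the
Boolean network, binarize the expression matrix per sample, simulate every
cell's trajectory to its attractor, group cells by (sample, cell type), and
call consensus gene states.  Outputs are plain CSV/TSV/JSON files under a
run directory, byte-identical across reruns of the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import attractor_analysis as aa
from . import binarization as bz
from . import network_construction as nc
from .boolean_network import BooleanNetwork, parse_rules, write_rules
from .dynamics import DEFAULT_MAX_STEPS, simulate_to_attractor

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class DataError(ValueError):
    """Input data violates a pipeline contract."""


@dataclass
class PipelineConfig:
    """All paths and thresholds of one pipeline run.

    Provide either ``rule_file`` (construction is skipped) or the full
    evidence set (pathway lists, cell-line expression, DE table,
    interactome, TF table, sign table).
    """

    expression: str = ""
    annotations: str = ""
    outdir: str = "run"
    seed: int = 0

    rule_file: str | None = None
    pathway_lists: dict[str, str] = field(default_factory=dict)
    cell_line_expression: str | None = None
    control_columns: tuple[str, ...] = ()
    de_table: str | None = None
    interactome: str | None = None
    tf_table: str | None = None
    sign_table: str | None = None

    min_hub_degree: int = 50
    max_intermediaries: int = 3
    low_expression_threshold: float | None = None
    reference_sample: str | None = None
    seed_genes: tuple[str, ...] = ()
    ncf_scheme: str = "inhibitor_dominant"
    default_unsigned_to_activation: bool = False

    binarization_scope: str = "per_sample"  # or "global"
    degenerate_policy: str = "zero"
    max_steps: int = DEFAULT_MAX_STEPS
    cycle_fraction: float = 1.0
    min_cell_fraction: float = 0.95
    summary_malignant_only: bool = True

    def __post_init__(self) -> None:
        if self.binarization_scope not in ("per_sample", "global"):
            raise ConfigError(f"unknown binarization scope {self.binarization_scope!r}")
        if not 0.5 < self.cycle_fraction <= 1.0:
            raise ConfigError("cycle_fraction must be in (0.5, 1]")
        if not 0.0 < self.min_cell_fraction <= 1.0:
            raise ConfigError("min_cell_fraction must be in (0, 1]")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("seed_genes", "control_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seed_genes"] = list(self.seed_genes)
        d["control_columns"] = list(self.control_columns)
        return d


@dataclass
class PipelineResult:
    network: BooleanNetwork
    binarized: pd.DataFrame
    attractors: pd.DataFrame
    consensus: list[aa.GroupConsensus]
    summary_matrix: pd.DataFrame
    patterns: dict
    report: dict
    paths: dict[str, Path]


def _build_or_load_network(config: PipelineConfig) -> tuple[BooleanNetwork, dict]:
    if config.rule_file:
        net = parse_rules(Path(config.rule_file).read_text())
        return net, {"source": "rule_file", "n_genes": net.n}
    needed = {"pathway_lists": config.pathway_lists,
              "cell_line_expression": config.cell_line_expression,
              "de_table": config.de_table, "interactome": config.interactome,
              "tf_table": config.tf_table, "sign_table": config.sign_table}
    missing = [k for k, v in needed.items() if not v]
    if missing:
        raise ConfigError(
            f"no rule_file and incomplete construction inputs (missing: {missing})")
    cc = nc.ConstructionConfig(
        min_hub_degree=config.min_hub_degree,
        max_intermediaries=config.max_intermediaries,
        low_expression_threshold=config.low_expression_threshold,
        reference_sample=config.reference_sample,
        seed_genes=config.seed_genes,
        ncf_scheme=config.ncf_scheme,
        default_unsigned_to_activation=config.default_unsigned_to_activation)
    cell_lines = nc.read_expression_table(config.cell_line_expression)
    control_cols = list(config.control_columns) or [cell_lines.columns[-1]]
    tumor = cell_lines.drop(columns=[c for c in control_cols if c in cell_lines])
    control = cell_lines[control_cols]
    net, report = nc.build_grn(
        nc.read_pathway_lists(config.pathway_lists), tumor, control,
        nc.read_de_table(config.de_table),
        nc.read_interactome(config.interactome),
        nc.read_tf_table(config.tf_table),
        nc.read_sign_table(config.sign_table), cc)
    report["source"] = "construction"
    return net, report


def _binarize(config: PipelineConfig, expr: pd.DataFrame,
              annotations: list[aa.CellAnnotation]
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.binarization_scope == "global":
        bits, results = bz.binarize_matrix(expr, degenerate=config.degenerate_policy)
        return bits, bz.thresholds_table(results)
    sample_of = {a.cell_id: a.sample_id for a in annotations}
    unknown = [c for c in expr.columns if c not in sample_of]
    if unknown:
        raise DataError(f"cells without annotation: {unknown[:5]}")
    pieces = []
    thresholds = []
    for sample in sorted({a.sample_id for a in annotations}):
        cols = [c for c in expr.columns if sample_of[c] == sample]
        if not cols:
            continue
        sub_bits, sub_res = bz.binarize_matrix(expr[cols],
                                               degenerate=config.degenerate_policy)
        pieces.append(sub_bits)
        tab = bz.thresholds_table(sub_res)
        tab.insert(0, "sample", sample)
        thresholds.append(tab)
    bits = pd.concat(pieces, axis=1)[expr.columns]
    return bits, pd.concat(thresholds)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the output bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    net, net_report = _build_or_load_network(config)
    logger.info("network: %d genes, %d edges", net.n, len(net.edges))

    expr = nc.read_expression_table(config.expression)
    annotations = aa.read_annotations(config.annotations)
    missing = [g for g in net.symbols if g not in expr.index]
    if missing:
        raise DataError(
            f"{len(missing)} network genes absent from expression matrix: "
            f"{missing[:10]}")
    expr = expr.loc[net.symbols]

    bits, thresholds = _binarize(config, expr, annotations)

    # per-cell trajectory to attractor
    kept = [a for a in annotations if not a.pooled]
    records = []
    attractor_of: dict[str, object] = {}
    for ann in kept:
        initial = net.state(bits[ann.cell_id].to_numpy())
        sim = simulate_to_attractor(net, initial, max_steps=config.max_steps)
        attractor_of[ann.cell_id] = sim.attractor
        records.append({
            "cell_id": ann.cell_id, "sample_id": ann.sample_id,
            "cell_type": ann.cell_type,
            "steps_to_cycle": (sim.trajectory.first_repeat_index
                               if sim.reached else -1),
            "period": sim.attractor.period if sim.reached else 0,
            "kind": sim.attractor.kind if sim.reached else "no_result",
            "cycle": sim.attractor.packed() if sim.reached else "",
        })
    attractors = pd.DataFrame.from_records(records)

    groups = aa.group_cells(kept)
    consensus: list[aa.GroupConsensus] = []
    group_report: dict[str, dict] = {}
    for key in sorted(groups):
        cells = groups[key]
        labels = {c: aa.label_all_genes(attractor_of[c], net.symbols,
                                        config.cycle_fraction)
                  for c in cells if attractor_of[c] is not None}
        n_no_result = len(cells) - len(labels)
        if not labels:
            logger.warning("group %s: every cell is no-result; skipped", key)
        else:
            consensus.append(aa.consensus_genes(key, labels,
                                                config.min_cell_fraction,
                                                n_no_result=n_no_result))
        group_report["|".join(key)] = {
            "n_cells": len(cells), "n_attractors": len(labels),
            "n_no_result": n_no_result}

    # per-sample percentage breakdown (pie-chart shape): attractor share per
    # cell type plus the no-result share, summing to 100 per sample
    sample_pcts: dict[str, dict[str, float]] = {}
    for sample in sorted({a.sample_id for a in kept}):
        sub = attractors[attractors["sample_id"] == sample]
        total = len(sub)
        entry: dict[str, float] = {}
        for ctype, n in sub[sub["kind"] != "no_result"]["cell_type"].value_counts().items():
            entry[ctype] = round(100.0 * n / total, 4)
        n_nores = int((sub["kind"] == "no_result").sum())
        entry["no_result"] = round(100.0 * n_nores / total, 4)
        sample_pcts[sample] = entry

    subtype_of = _read_subtypes(config.annotations)
    summary_consensus = ([c for c in consensus if c.group[1] == "malignant"]
                         if config.summary_malignant_only else consensus)
    if summary_consensus:
        summary_matrix, patterns = aa.summarize_across_groups(
            summary_consensus, net.symbols, subtype_of=subtype_of)
    else:
        summary_matrix, patterns = pd.DataFrame(), {}

    report = {
        "network": net_report,
        "n_cells": len(kept),
        "n_pooled_excluded": len(annotations) - len(kept),
        "groups": group_report,
        "sample_percentages": sample_pcts,
        "parameters": {
            "binarization_scope": config.binarization_scope,
            "max_steps": config.max_steps,
            "cycle_fraction": config.cycle_fraction,
            "min_cell_fraction": config.min_cell_fraction,
            "summary_malignant_only": config.summary_malignant_only,
        },
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
    }

    # ---- write the bundle -------------------------------------------------
    paths["rules"] = outdir / "network_rules.txt"
    paths["rules"].write_text(write_rules(net))
    paths["network_json"] = outdir / "network.json"
    paths["network_json"].write_text(net.to_json() + "\n")
    paths["binarized"] = outdir / "binarized.tsv"
    bits.to_csv(paths["binarized"], sep="\t")
    paths["thresholds"] = outdir / "thresholds.csv"
    thresholds.to_csv(paths["thresholds"], float_format="%.8g")
    paths["attractors"] = outdir / "attractors.csv"
    attractors.to_csv(paths["attractors"], index=False)
    paths["consensus"] = outdir / "consensus.csv"
    cons_rows = [{"sample_id": c.group[0], "cell_type": c.group[1], "gene": g,
                  "label": c.labels[g], "support": round(c.support[g], 8),
                  "n_cells": c.n_cells, "n_no_result": c.n_no_result}
                 for c in consensus for g in net.symbols]
    pd.DataFrame.from_records(cons_rows).to_csv(paths["consensus"], index=False)
    paths["summary_matrix"] = outdir / "summary_matrix.csv"
    summary_matrix.to_csv(paths["summary_matrix"])
    paths["patterns"] = outdir / "patterns.json"
    paths["patterns"].write_text(json.dumps(patterns, indent=2, sort_keys=True) + "\n")
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest = {"outputs": {k: p.name for k, p in sorted(paths.items())},
                "config": config.to_dict()}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath

    return PipelineResult(network=net, binarized=bits, attractors=attractors,
                          consensus=consensus, summary_matrix=summary_matrix,
                          patterns=patterns, report=report, paths=paths)


def _read_subtypes(annotation_path) -> dict[str, str] | None:
    df = pd.read_csv(annotation_path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "subtype" not in df.columns:
        return None
    pairs = df[["sample_id", "subtype"]].dropna().drop_duplicates()
    return {str(r.sample_id): str(r.subtype) for r in pairs.itertuples(index=False)}
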