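"""Gene-level readout of per-cell attractors.

For each cell's attractor, every gene is labeled ``True`` (constantly 1
across the cycle), ``False`` (constantly 0) or ``X`` (toggling).  Cells are
grouped by (sample, cell type); a group-level consensus call requires the
same constant label in at least 95% of the group's attractor-bearing cells.
Cross-group summaries flag genes constantly expressed (or silent) per group
and per tumor subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .dynamics import Attractor

__all__ = [
    "CellAnnotation",
    "GeneConstancyLabel",
    "GroupConsensus",
    "read_annotations",
    "label_gene_constancy",
    "label_all_genes",
    "group_cells",
    "consensus_genes",
    "summarize_across_groups",
]

logger = logging.getLogger(__name__)

CELL_TYPES = ("malignant", "stromal", "immune_B", "immune_T", "myeloid", "other")

TRUE, FALSE, X = "True", "False", "X"


@dataclass(frozen=True)
class CellAnnotation:
    """One cell: id, sample (patient batch), cell type, pooled-sample flag."""

    cell_id: str
    sample_id: str
    cell_type: str
    pooled: bool = False


def read_annotations(path) -> list[CellAnnotation]:
    """Annotation TSV: cell_id, sample_id, cell_type[, pooled]."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    need = {"cell_id", "sample_id", "cell_type"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(need)}")
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in annotation table")
    pooled = df["pooled"].astype(bool) if "pooled" in df.columns else [False] * len(df)
    return [CellAnnotation(str(r.cell_id), str(r.sample_id), str(r.cell_type), bool(p))
            for r, p in zip(df.itertuples(index=False), pooled)]


@dataclass(frozen=True)
class GeneConstancyLabel:
    """Per-(cell, gene) constancy across the attractor cycle."""

    gene: str
    label: str  # True | False | X
    fraction_on: float  # fraction of cycle states with the gene at 1


def label_gene_constancy(attr: Attractor, gene_index: int, gene: str = "",
                         cycle_fraction: float = 1.0) -> GeneConstancyLabel:
    """Label one gene by its fraction of ON states across the cycle.

    ``cycle_fraction`` = 1.0 demands strict constancy; lowering it (e.g.
    0.8, must stay above 0.5) labels genes constant "in most states" of the
    cycle.
    """
    if not 0.5 < cycle_fraction <= 1.0:
        raise ValueError("cycle_fraction must be in (0.5, 1]")
    frac = attr.gene_fraction_on(gene_index)
    if frac >= cycle_fraction:
        label = TRUE
    elif (1.0 - frac) >= cycle_fraction:
        label = FALSE
    else:
        label = X
    return GeneConstancyLabel(gene=gene, label=label, fraction_on=frac)


def label_all_genes(attr: Attractor, genes: list[str],
                    cycle_fraction: float = 1.0) -> dict[str, GeneConstancyLabel]:
    return {g: label_gene_constancy(attr, i, g, cycle_fraction)
            for i, g in enumerate(genes)}


def group_cells(annotations: list[CellAnnotation]
                ) -> dict[tuple[str, str], list[str]]:
    """Partition non-pooled cells into (sample_id, cell_type) groups."""
    groups: dict[tuple[str, str], list[str]] = {}
    for ann in annotations:
        if ann.pooled:
            continue
        if not ann.sample_id or ann.sample_id.lower() == "nan":
            raise ValueError(f"cell {ann.cell_id!r} has no sample id")
        groups.setdefault((ann.sample_id, ann.cell_type), []).append(ann.cell_id)
    return groups


@dataclass
class GroupConsensus:
    """Group-level gene calls: True/False when supported by >= min_cell_fraction."""

    group: tuple[str, str]
    labels: dict[str, str]  # gene -> True | False | X (X = no-call)
    support: dict[str, float]  # gene -> fraction of cells behind the call
    n_cells: int  # attractor-bearing cells in the denominator
    n_no_result: int = 0


def consensus_genes(group: tuple[str, str],
                    cell_labels: dict[str, dict[str, GeneConstancyLabel]],
                    min_cell_fraction: float = 0.95,
                    n_no_result: int = 0) -> GroupConsensus:
    """Call a gene True/False when >= ``min_cell_fraction`` of the group's
    attractor-bearing cells carry that constant label; otherwise no-call (X).

    ``cell_labels`` maps cell id -> per-gene labels; no-result cells are
    excluded upstream and enter only via ``n_no_result`` (logged, never in
    the denominator).  Boundary inclusive: 19 of 20 cells is a call at 0.95.
    """
    if not cell_labels:
        raise ValueError(f"group {group} has no attractor-bearing cells")
    if not 0.0 < min_cell_fraction <= 1.0:
        raise ValueError("min_cell_fraction must be in (0, 1]")
    n = len(cell_labels)
    genes = next(iter(cell_labels.values())).keys()
    labels: dict[str, str] = {}
    support: dict[str, float] = {}
    for g in genes:
        counts = {TRUE: 0, FALSE: 0, X: 0}
        for per_gene in cell_labels.values():
            counts[per_gene[g].label] += 1
        frac_true = counts[TRUE] / n
        frac_false = counts[FALSE] / n
        if frac_true >= min_cell_fraction:
            labels[g], support[g] = TRUE, frac_true
        elif frac_false >= min_cell_fraction:
            labels[g], support[g] = FALSE, frac_false
        else:
            labels[g], support[g] = X, max(frac_true, frac_false)
    if n_no_result:
        logger.info("group %s: %d no-result cells excluded from consensus "
                    "denominator (%d cells kept)", group, n_no_result, n)
    return GroupConsensus(group=group, labels=labels, support=support,
                          n_cells=n, n_no_result=n_no_result)


CONSTANT_TRUE = "constant_true"
CONSTANT_FALSE = "constant_false"
NON_CONSTANT = "non_constant"


def summarize_across_groups(consensus: list[GroupConsensus],
                            gene_panel: list[str],
                            subtype_of: dict[str, str] | None = None
                            ) -> tuple[pd.DataFrame, dict]:
    """Genes x groups constancy matrix plus per-gene cross-group patterns.

    Matrix cells take {constant_true, constant_false, non_constant}.  Group
    columns are ordered by tumor subtype (when ``subtype_of`` maps sample ->
    subtype) then by sample.  Patterns flag, per gene, the groups where it
    is constantly expressed/silent and the subtypes in which it is never
    expressed.
    """
    if not consensus:
        raise ValueError("need at least one group consensus")
    for g in gene_panel:
        for c in consensus:
            if g not in c.labels:
                raise ValueError(f"gene {g!r} absent from group {c.group} consensus")

    def group_key(c: GroupConsensus):
        subtype = (subtype_of or {}).get(c.group[0], "")
        return (subtype, c.group[0], c.group[1])

    ordered = sorted(consensus, key=group_key)
    col_names = [f"{c.group[0]}|{c.group[1]}" for c in ordered]
    matrix = pd.DataFrame(index=gene_panel, columns=col_names, dtype=object)
    for c, col in zip(ordered, col_names):
        for g in gene_panel:
            lab = c.labels[g]
            matrix.loc[g, col] = (CONSTANT_TRUE if lab == TRUE
                                  else CONSTANT_FALSE if lab == FALSE
                                  else NON_CONSTANT)

    patterns: dict[str, dict] = {}
    for g in gene_panel:
        expressed = [c.group for c in ordered if c.labels[g] == TRUE]
        silent = [c.group for c in ordered if c.labels[g] == FALSE]
        entry: dict = {
            "expressed_in": [f"{s}|{t}" for s, t in expressed],
            "silent_in": [f"{s}|{t}" for s, t in silent],
            "no_call_in": [f"{s}|{t}" for c in ordered if c.labels[g] == X
                           for s, t in [c.group]],
        }
        all_groups = [c.group for c in ordered]
        not_expressed = [grp for grp in all_groups if grp not in expressed]
        if len(not_expressed) == 1:
            entry["expressed_in_all_groups_except"] = "|".join(not_expressed[0])
        if subtype_of:
            never_in: list[str] = []
            for subtype in sorted(set(subtype_of.values())):
                grps = [c for c in ordered if subtype_of.get(c.group[0]) == subtype]
                if grps and all(c.labels[g] == FALSE for c in grps):
                    never_in.append(subtype)
            if never_in:
                entry["never_expressed_in_subtypes"] = never_in
        patterns[g] = entry
    return matrix, patterns
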