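"""Assembly of the signed gene regulatory network from flat-file evidence.

The construction mirrors a hub-and-intermediary strategy for building a
tumor-specific GRN: (1) keep pathway genes that are present in the tumor /
control expression tables; (2) keep only differentially expressed genes;
(3) keep interactome hubs (>= 50 distinct interaction partners by default);
(4) connect unlinked hub pairs through short interactome paths with at most
three sufficiently-expressed intermediary proteins; (5) add transcription
factors that regulate any network vertex; (6) resolve every edge to an
activation/inhibition sign and emit one nested canalyzing rule per gene.

All evidence sources are flat files: pathway gene lists (plain or GMT), a
differential-expression status table, a PSI-MITAB or two-column interactome,
a TF->target regulation table, and a (source, target, sign) table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .boolean_network import (ACTIVATION, INHIBITION, BooleanNetwork,
                              NestedCanalyzingRule, SignedEdge, build_ncf)

__all__ = [
    "ConstructionConfig",
    "InteractomeGraph",
    "GRNDraft",
    "read_interactome",
    "read_pathway_lists",
    "read_de_table",
    "read_tf_table",
    "read_sign_table",
    "read_expression_table",
    "select_expressed_pathway_genes",
    "retain_differential",
    "select_hubs",
    "connect_with_intermediaries",
    "enrich_transcription_factors",
    "assemble_network",
    "build_grn",
]

logger = logging.getLogger(__name__)


@dataclass
class ConstructionConfig:
    """Tunable thresholds of the construction stages.

    ``min_hub_degree`` — minimum distinct interactome partners for hub
    selection (boundary inclusive).  ``max_intermediaries`` — maximum
    internal vertices allowed on a connecting path.
    ``low_expression_threshold`` — intermediaries at or below this value in
    the reference sample are rejected; ``None`` means the 10th percentile of
    the nonzero reference values.  ``seed_genes`` — manually added genes
    that bypass the DE/hub filters.
    """

    min_hub_degree: int = 50
    max_intermediaries: int = 3
    low_expression_threshold: float | None = None
    reference_sample: str | None = None
    seed_genes: tuple[str, ...] = ()
    ncf_scheme: str = "inhibitor_dominant"
    default_unsigned_to_activation: bool = False
    tf_edges_inherit_mode: bool = True

    def __post_init__(self) -> None:
        if self.min_hub_degree < 1:
            raise ValueError("min_hub_degree must be >= 1")
        if self.max_intermediaries < 0:
            raise ValueError("max_intermediaries must be >= 0")


class InteractomeGraph:
    """Undirected protein interaction graph; degree = distinct partners."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def degree(self, node: str) -> int:
        """Distinct interaction partners; a self-interaction counts once."""
        if node not in self.graph:
            return 0
        return len(list(self.graph.neighbors(node)))

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)


def _strip_prefix(ident: str) -> str:
    return ident.split(":", 1)[1] if ":" in ident else ident


def read_interactome(path, id_mapping: dict[str, str] | None = None) -> InteractomeGraph:
    """Read a PSI-MITAB 2.5 file or a 2-column TSV into an interaction graph.

    PSI-MITAB is detected by database-prefixed identifiers (``db:acc``) or
    by >2 columns; identifiers are optionally translated to gene symbols via
    ``id_mapping``.  Redundant evidence lines collapse to one edge.
    """
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "ID(s) interactor")):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                continue
            a = _strip_prefix(cols[0].strip())
            b = _strip_prefix(cols[1].strip())
            if id_mapping:
                a = id_mapping.get(a, a)
                b = id_mapping.get(b, b)
            if a and b and a != "-" and b != "-":
                g.add_edge(a, b)
    return InteractomeGraph(g)


def read_pathway_lists(paths: dict[str, str | Path]) -> dict[str, set[str]]:
    """Read named pathway gene lists: one symbol per line, or GMT rows."""
    out: dict[str, set[str]] = {}
    for name, path in paths.items():
        genes: set[str] = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "\t" in line:  # GMT: name, description, genes...
                    fields = line.split("\t")
                    genes.update(g for g in fields[2:] if g)
                else:
                    genes.add(line)
        if not genes:
            raise ValueError(f"pathway list {name!r} is empty")
        out[name] = genes
    return out


def read_de_table(path) -> pd.DataFrame:
    """gene / status TSV; status in {up, down, ns}."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if not {"gene", "status"} <= set(df.columns):
        raise ValueError("DE table needs 'gene' and 'status' columns")
    bad = set(df["status"].str.lower()) - {"up", "down", "ns"}
    if bad:
        raise ValueError(f"DE table has unknown status values {sorted(bad)}")
    df["status"] = df["status"].str.lower()
    return df.set_index("gene")


def read_tf_table(path) -> pd.DataFrame:
    """TF / target / mode TSV (TRRUST-style); duplicates dropped."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["tf", "target", "mode"], usecols=[0, 1, 2])
    df["mode"] = df["mode"].str.lower().map(
        {"activation": ACTIVATION, "repression": INHIBITION,
         "inhibition": INHIBITION, "unknown": "unknown"})
    if df["mode"].isna().any():
        raise ValueError("TF table has unrecognized mode values")
    return df.drop_duplicates(subset=["tf", "target"], keep="first")


def read_sign_table(path) -> dict[tuple[str, str], str]:
    """source / target / sign TSV -> {(source, target): sign}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["source", "target", "sign"], usecols=[0, 1, 2])
    signs = {}
    for row in df.itertuples(index=False):
        sign = row.sign.lower()
        if sign in ("activation", "+"):
            sign = ACTIVATION
        elif sign in ("inhibition", "repression", "-"):
            sign = INHIBITION
        else:
            raise ValueError(f"unknown sign {row.sign!r} for {row.source}->{row.target}")
        signs[(row.source, row.target)] = sign
    return signs


def read_expression_table(path) -> pd.DataFrame:
    """genes x samples/cells TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression table contains negative values")
    if df.index.has_duplicates:
        raise ValueError("expression table has duplicate gene rows")
    return df


# ---------------------------------------------------------------------------
# Construction stages
# ---------------------------------------------------------------------------

def select_expressed_pathway_genes(
        pathway_lists: dict[str, set[str]],
        tumor_expr: pd.DataFrame,
        control_expr: pd.DataFrame) -> tuple[dict[str, set[str]], dict]:
    """Keep pathway genes present in either cell line's expression table."""
    if tumor_expr.empty or control_expr.empty:
        raise ValueError("expression tables must be non-empty")
    present = set(tumor_expr.index) | set(control_expr.index)
    retained: dict[str, set[str]] = {}
    report: dict[str, dict[str, int]] = {}
    for name, genes in pathway_lists.items():
        keep = genes & present
        if not keep:
            logger.warning("pathway %s: no gene present in expression data", name)
        retained[name] = keep
        report[name] = {"total": len(genes), "retained": len(keep),
                        "excluded": len(genes) - len(keep)}
    return retained, report


def retain_differential(genes: set[str], de: pd.DataFrame) -> tuple[dict[str, str], dict]:
    """Keep genes with DE status up/down; missing rows default to ns."""
    status = {}
    missing = []
    for g in sorted(genes):
        if g in de.index:
            status[g] = de.loc[g, "status"]
        else:
            missing.append(g)
            status[g] = "ns"
    if missing:
        logger.warning("%d genes missing from DE table, treated as ns: %s",
                       len(missing), missing[:10])
    kept = {g: s for g, s in status.items() if s in ("up", "down")}
    report = {"input": len(genes),
              "retained": len(kept),
              "up": sum(1 for s in kept.values() if s == "up"),
              "down": sum(1 for s in kept.values() if s == "down")}
    if not kept:
        logger.warning("no differentially expressed genes retained")
    return kept, report


def select_hubs(genes: set[str], interactome: InteractomeGraph,
                min_hub_degree: int = 50) -> set[str]:
    """Keep genes with at least ``min_hub_degree`` distinct interactome partners."""
    return {g for g in genes if interactome.degree(g) >= min_hub_degree}


@dataclass
class GRNDraft:
    """Intermediate network under construction: nodes with provenance, raw edges."""

    nodes: dict[str, str] = field(default_factory=dict)  # symbol -> provenance
    edges: list[dict] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def add_node(self, symbol: str, provenance: str) -> None:
        self.nodes.setdefault(symbol, provenance)

    def add_edge(self, source: str, target: str, provenance: str,
                 directed: bool, sign: str | None = None) -> None:
        for e in self.edges:
            if e["source"] == source and e["target"] == target:
                return
        self.edges.append({"source": source, "target": target, "sign": sign,
                           "provenance": provenance, "directed": directed})


def connect_with_intermediaries(seeds: set[str], interactome: InteractomeGraph,
                                expr: pd.DataFrame,
                                config: ConstructionConfig) -> GRNDraft:
    """Link seed pairs directly or through short admissible interactome paths.

    An intermediary is admissible if it is a row of ``expr`` with a
    reference-sample value above the low-expression threshold.  For each
    seed pair without a direct interactome edge, the shortest path whose
    internal vertices are all admissible non-seed proteins is admitted when
    it has at most ``max_intermediaries`` internal vertices; among
    equal-length paths the lexicographically smallest internal tuple wins.
    """
    ref = config.reference_sample or expr.columns[0]
    if ref not in expr.columns:
        raise ValueError(f"reference sample {ref!r} not in expression table")
    ref_vals = expr[ref]
    low = config.low_expression_threshold
    if low is None:
        nonzero = ref_vals[ref_vals > 0]
        low = float(nonzero.quantile(0.10)) if len(nonzero) else 0.0

    admissible = {g for g in interactome.nodes - set(seeds)
                  if g in expr.index and float(ref_vals.get(g, 0.0)) > low}

    draft = GRNDraft()
    for s in sorted(seeds):
        draft.add_node(s, "seed")
    g = interactome.graph
    sub = g.subgraph(admissible | set(seeds))
    for a, b in combinations(sorted(seeds), 2):
        if interactome.has_edge(a, b):
            draft.add_edge(a, b, "interactome", directed=False)
            continue
        if a not in g or b not in g:
            draft.log.append(f"unconnected pair {a}--{b}: absent from interactome")
            continue
        best: tuple[str, ...] | None = None
        try:
            for path in nx.all_shortest_paths(sub, a, b):
                internal = tuple(path[1:-1])
                if any(v in seeds for v in internal):
                    continue  # covered by other pairwise searches
                if best is None or internal < best:
                    best = internal
        except nx.NetworkXNoPath:
            pass
        if best is None or len(best) > config.max_intermediaries:
            draft.log.append(f"unconnected pair {a}--{b}: no admissible path "
                             f"with <= {config.max_intermediaries} intermediaries")
            continue
        chain = [a, *best, b]
        for v in best:
            draft.add_node(v, "intermediary")
        for u, w in zip(chain[:-1], chain[1:]):
            draft.add_edge(u, w, "intermediary" if best else "interactome",
                           directed=False)
    return draft


def enrich_transcription_factors(draft: GRNDraft, tfs: pd.DataFrame) -> GRNDraft:
    """Add every TF that regulates a current vertex, with a directed edge per target."""
    vertices = set(draft.nodes)
    norm = {"activation": ACTIVATION, "repression": INHIBITION,
            "inhibition": INHIBITION}
    for row in tfs.itertuples(index=False):
        if row.target in vertices:
            draft.add_node(row.tf, "tf_table")
            sign = norm.get(str(row.mode).lower())
            draft.add_edge(row.tf, row.target, "tf_table", directed=True, sign=sign)
    return draft


def assemble_network(draft: GRNDraft, signs: dict[tuple[str, str], str],
                     config: ConstructionConfig,
                     interactome: InteractomeGraph | None = None
                     ) -> tuple[BooleanNetwork, dict]:
    """Resolve edge signs and emit one nested canalyzing rule per gene.

    Undirected edges contribute both directions.  Sign resolution order:
    explicit sign table, then the TF table's mode (if enabled), then the
    default-to-activation fallback (if enabled) — otherwise an error listing
    every unresolvable pair.  Regulators of each gene are ordered by
    descending interactome degree (ties alphabetical) before the NCF is
    built; genes without regulators become frozen inputs.
    """
    directed: list[tuple[str, str, str, str]] = []  # source, target, sign, provenance
    unresolved: list[tuple[str, str]] = []

    def resolve(s: str, t: str, provisional: str | None) -> str | None:
        if (s, t) in signs:
            return signs[(s, t)]
        if provisional in (ACTIVATION, INHIBITION) and config.tf_edges_inherit_mode:
            return provisional
        if config.default_unsigned_to_activation:
            logger.info("edge %s->%s defaulted to activation", s, t)
            return ACTIVATION
        return None

    for e in draft.edges:
        pairs = [(e["source"], e["target"])]
        if not e["directed"]:
            pairs.append((e["target"], e["source"]))
        for s, t in pairs:
            sign = resolve(s, t, e["sign"])
            if sign is None:
                unresolved.append((s, t))
            else:
                directed.append((s, t, sign, e["provenance"]))
    if unresolved:
        raise ValueError(
            "edges with unresolvable sign: "
            + ", ".join(f"{s}->{t}" for s, t in sorted(unresolved)))

    def deg(sym: str) -> int:
        return interactome.degree(sym) if interactome is not None else 0

    # deterministic gene order: seeds, intermediaries, TFs; alphabetical within
    prov_rank = {"seed": 0, "manual": 0, "intermediary": 1, "tf_table": 2}
    order = sorted(draft.nodes, key=lambda s: (prov_rank.get(draft.nodes[s], 3), s))

    regulators: dict[str, dict[str, str]] = {g: {} for g in order}
    for s, t, sign, _prov in directed:
        if t in regulators and s in draft.nodes:
            regulators[t][s] = sign  # later assignment overwrites, never duplicates

    rules: dict[str, NestedCanalyzingRule] = {}
    frozen = []
    for gsym in order:
        regs = regulators[gsym]
        if not regs:
            rules[gsym] = NestedCanalyzingRule(target=gsym, expr=("var", gsym))
            frozen.append(gsym)
            continue
        ordered = sorted(regs, key=lambda r: (-deg(r), r))
        activators = [r for r in ordered if regs[r] == ACTIVATION]
        inhibitors = [r for r in ordered if regs[r] == INHIBITION]
        rules[gsym] = build_ncf(gsym, activators, inhibitors, scheme=config.ncf_scheme)

    edge_objs = [SignedEdge(s, t, sign, prov) for s, t, sign, prov in directed
                 if t in regulators and s in draft.nodes
                 and regulators[t].get(s) == sign]
    # de-duplicate (source, target)
    seen = set()
    uniq = []
    for e in edge_objs:
        if (e.source, e.target) not in seen:
            seen.add((e.source, e.target))
            uniq.append(e)
    net = BooleanNetwork(order, rules, edges=uniq)
    report = {
        "n_genes": net.n,
        "n_edges": len(uniq),
        "n_frozen_inputs": len(frozen),
        "nodes_by_provenance": {p: sum(1 for v in draft.nodes.values() if v == p)
                                for p in sorted(set(draft.nodes.values()))},
    }
    return net, report


def build_grn(pathway_lists: dict[str, set[str]],
              tumor_expr: pd.DataFrame,
              control_expr: pd.DataFrame,
              de: pd.DataFrame,
              interactome: InteractomeGraph,
              tfs: pd.DataFrame,
              signs: dict[tuple[str, str], str],
              config: ConstructionConfig) -> tuple[BooleanNetwork, dict]:
    """Run every construction stage in order; returns network + stage report."""
    retained, pathway_report = select_expressed_pathway_genes(
        pathway_lists, tumor_expr, control_expr)
    pool = set().union(*retained.values()) if retained else set()
    de_genes, de_report = retain_differential(pool, de)
    hubs = select_hubs(set(de_genes), interactome, config.min_hub_degree)
    seeds = hubs | set(config.seed_genes)
    draft = connect_with_intermediaries(seeds, interactome, tumor_expr, config)
    for s in config.seed_genes:
        draft.nodes[s] = "manual"
    draft = enrich_transcription_factors(draft, tfs)
    net, assembly_report = assemble_network(draft, signs, config, interactome)
    report = {
        "pathways": pathway_report,
        "differential": de_report,
        "n_hubs": len(hubs),
        "n_seeds": len(seeds),
        "n_intermediaries": sum(1 for v in draft.nodes.values() if v == "intermediary"),
        "n_tfs": sum(1 for v in draft.nodes.values() if v == "tf_table"),
        "unconnected_pairs": draft.log,
        **assembly_report,
    }
    return net, report
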