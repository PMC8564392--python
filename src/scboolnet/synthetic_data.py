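"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: bimodal
single-cell expression matrices with patient/cell-type annotations, a toy
knowledge base (pathway lists, DE status, hub-structured interactome, TF
and sign tables) whose construction yields a fixed-size network, random
nested-canalyzing networks, and networks with a planted attractor.  All
generators are pure functions of their parameters and seed.

The default expression profile emulates a public breast-cancer single-cell
cohort: 549 cells across 11 patients / 14 sample groups (two lymph-node
samples and one re-biopsy are separate groups), four tumor subtypes, and
malignant plus stromal/immune cell types.  Expression is a two-component
log-normal mixture per gene (moment-matched so each component has the
requested arithmetic mean and sd), with optional zero-inflation dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attractor_analysis import CellAnnotation
from .boolean_network import (BooleanNetwork, NestedCanalyzingRule, build_ncf)
from .dynamics import Attractor, synchronous_step

__all__ = [
    "ExpressionSimParams",
    "PlantedNetworkSpec",
    "PlantedNetwork",
    "default_group_profile",
    "DEFAULT_SUBTYPES",
    "simulate_expression_matrix",
    "generate_random_ncf_network",
    "plant_fixed_point",
    "generate_knowledge_base",
    "write_fixture",
]

#: (sample, cell_type, n_cells) triples; totals per sample follow the
#: emulated cohort (26, 56, 37/55, 59, 77, 25, 51/53, 23, 29/31, 16, 11
#: cells = 549), with malignant/immune splits approximating its reports.
_DEFAULT_PROFILE: tuple[tuple[str, str, int], ...] = (
    ("BC01", "malignant", 24), ("BC01", "stromal", 2),
    ("BC02", "malignant", 56),
    ("BC03", "malignant", 25), ("BC03", "immune_B", 7), ("BC03", "immune_T", 5),
    ("BC03LN", "malignant", 17), ("BC03LN", "immune_B", 35), ("BC03LN", "immune_T", 3),
    ("BC04", "malignant", 54), ("BC04", "immune_T", 3), ("BC04", "myeloid", 2),
    ("BC05", "malignant", 77),
    ("BC06", "malignant", 17), ("BC06", "stromal", 2), ("BC06", "immune_B", 6),
    ("BC07", "malignant", 32), ("BC07", "stromal", 4), ("BC07", "immune_B", 3),
    ("BC07", "immune_T", 4), ("BC07", "myeloid", 8),
    ("BC07LN", "malignant", 34), ("BC07LN", "immune_B", 19),
    ("BC08", "malignant", 17), ("BC08", "stromal", 6),
    ("BC09", "stromal", 2), ("BC09", "immune_B", 1), ("BC09", "immune_T", 11),
    ("BC09", "myeloid", 15),
    ("BC09Re", "stromal", 2), ("BC09Re", "immune_B", 1), ("BC09Re", "immune_T", 22),
    ("BC09Re", "myeloid", 6),
    ("BC10", "malignant", 12), ("BC10", "stromal", 2), ("BC10", "myeloid", 2),
    ("BC11", "malignant", 11),
)

DEFAULT_SUBTYPES: dict[str, str] = {
    "BC01": "luminal_A", "BC02": "luminal_A",
    "BC03": "luminal_B", "BC03LN": "luminal_B",
    "BC04": "HER2", "BC05": "HER2", "BC06": "HER2",
    "BC07": "TNBC", "BC07LN": "TNBC", "BC08": "TNBC",
    "BC09": "TNBC", "BC09Re": "TNBC", "BC10": "TNBC", "BC11": "TNBC",
}


def default_group_profile() -> list[tuple[str, str, int]]:
    return list(_DEFAULT_PROFILE)


@dataclass
class ExpressionSimParams:
    """Parameters of the bimodal expression generator.

    Each gene x cell value is drawn from the low or high log-normal
    component according to the gene's per-group probability of the high
    (expressed) state; ``dropout`` zero-inflates after sampling.
    """

    n_genes: int = 103
    genes: tuple[str, ...] | None = None
    group_profile: list[tuple[str, str, int]] = field(default_factory=default_group_profile)
    low_mean: float = 2.0
    high_mean: float = 8.0
    sd: float = 0.5
    p_high: np.ndarray | float | None = None  # (n_genes, n_groups) or scalar
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.low_mean < self.high_mean):
            raise ValueError("need 0 < low_mean < high_mean")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and sd."""
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def simulate_expression_matrix(params: ExpressionSimParams
                               ) -> tuple[pd.DataFrame, list[CellAnnotation], pd.DataFrame]:
    """Simulate genes x cells expression with known component labels.

    Returns (expression table, cell annotations, true binary matrix), the
    last holding the high-component indicator each value was drawn from —
    the ground truth that binarization is meant to recover.
    """
    rng = np.random.default_rng(params.seed)
    genes = list(params.genes) if params.genes is not None else [
        f"G{i + 1:03d}" for i in range(params.n_genes)]
    if len(genes) != params.n_genes:
        raise ValueError("genes list length != n_genes")
    profile = list(params.group_profile)
    n_cells = sum(n for _, _, n in profile)
    if n_cells <= 0:
        raise ValueError("group profile is empty")
    n_groups = len(profile)

    if params.p_high is None:
        # U-shaped probabilities: most gene/group pairs are clearly on or off
        p = rng.beta(0.3, 0.3, size=(params.n_genes, n_groups))
    elif np.isscalar(params.p_high):
        p = np.full((params.n_genes, n_groups), float(params.p_high))
    else:
        p = np.asarray(params.p_high, dtype=float)
        if p.shape != (params.n_genes, n_groups):
            raise ValueError(
                f"p_high shape {p.shape} != ({params.n_genes}, {n_groups})")

    annotations: list[CellAnnotation] = []
    cols: list[str] = []
    group_of_cell: list[int] = []
    for gi, (sample, ctype, n) in enumerate(profile):
        for k in range(n):
            cid = f"{sample}_{ctype}_{k + 1:03d}"
            cols.append(cid)
            annotations.append(CellAnnotation(cid, sample, ctype))
            group_of_cell.append(gi)
    gidx = np.asarray(group_of_cell)

    shape = (params.n_genes, n_cells)
    high = rng.random(shape) < p[:, gidx]
    low_vals = _lognormal(rng, params.low_mean, params.sd, shape)
    high_vals = _lognormal(rng, params.high_mean, params.sd, shape)
    values = np.where(high, high_vals, low_vals)
    if params.dropout > 0:
        values = np.where(rng.random(shape) < params.dropout, 0.0, values)

    expr = pd.DataFrame(values, index=genes, columns=cols)
    truth = pd.DataFrame(high.astype(np.int8), index=genes, columns=cols)
    return expr, annotations, truth


def generate_random_ncf_network(n: int, mean_in_degree: float = 2.0,
                                seed: int = 0) -> BooleanNetwork:
    """Random network where every gene gets a nested canalyzing rule.

    In-degrees are Poisson(mean_in_degree) clipped to [1, n]; regulators are
    sampled without replacement and split at random into activators and
    inhibitors (inhibitor-dominant rules).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:03d}" for i in range(n)]
    rules: dict[str, NestedCanalyzingRule] = {}
    for g in genes:
        k = int(min(n, max(1, rng.poisson(mean_in_degree))))
        regs = [genes[i] for i in rng.choice(n, size=k, replace=False)]
        is_act = rng.random(k) < 0.5
        activators = [r for r, a in zip(regs, is_act) if a]
        inhibitors = [r for r, a in zip(regs, is_act) if not a]
        rules[g] = build_ncf(g, activators, inhibitors, scheme="inhibitor_dominant")
    return BooleanNetwork(genes, rules)


@dataclass
class PlantedNetworkSpec:
    """Spec for a network constructed around a known attractor.

    ``constant_fraction`` of the genes hold a fixed value in the planted
    attractor; the rest toggle with period 2 (requires < 1.0).  With
    ``anchor_size`` set (fixed points only), all rules read a small set of
    frozen anchor genes, making the planted state globally attracting for
    any initial state that agrees on the anchors.
    """

    n_genes: int = 103
    constant_fraction: float = 1.0
    mean_extra_regulators: float = 1.0
    anchor_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.constant_fraction <= 1.0:
            raise ValueError("constant_fraction must be in (0, 1]")
        if self.anchor_size is not None and self.constant_fraction < 1.0:
            raise ValueError("anchored construction requires constant_fraction = 1.0")


@dataclass
class PlantedNetwork:
    network: BooleanNetwork
    attractor: Attractor
    target_state: "NetworkState"
    constant_genes: list[str]
    toggling_genes: list[str]
    anchors: list[str]


def plant_fixed_point(spec: PlantedNetworkSpec) -> PlantedNetwork:
    """Construct NCF rules under which a chosen state is a fixed point
    (or, with toggling genes, a 2-cycle through it); verified before return.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    if n < 3:
        raise ValueError("need at least 3 genes to plant an attractor")
    genes = [f"G{i + 1:03d}" for i in range(n)]
    target = rng.integers(0, 2, size=n)

    n_toggle = int(round(n * (1.0 - spec.constant_fraction)))
    if 0 < spec.constant_fraction < 1.0 and n_toggle == 0:
        n_toggle = 1
    toggle_idx = list(rng.choice(n, size=n_toggle, replace=False)) if n_toggle else []
    const_idx = [i for i in range(n) if i not in set(toggle_idx)]
    if len(const_idx) < 2:
        raise ValueError("infeasible spec: need at least 2 constant genes")
    # constructability: at least one constant gene on and one off
    target[const_idx[0]] = 1
    target[const_idx[1]] = 0
    const_on = [i for i in const_idx if target[i] == 1]
    const_off = [i for i in const_idx if target[i] == 0]

    anchors: list[int] = []
    if spec.anchor_size is not None:
        if spec.anchor_size < 2:
            raise ValueError("anchor_size must be >= 2")
        anchors = const_idx[:spec.anchor_size]
        pool_on = [i for i in anchors if target[i] == 1]
        pool_off = [i for i in anchors if target[i] == 0]
        if not pool_on or not pool_off:
            raise ValueError("infeasible spec: anchors must cover both values")
    else:
        pool_on, pool_off = const_on, const_off

    def pick(pool: list[int], k: int) -> list[str]:
        k = min(k, len(pool))
        return [genes[i] for i in rng.choice(pool, size=k, replace=False)]

    rules: dict[str, NestedCanalyzingRule] = {}
    clock = toggle_idx[0] if toggle_idx else None
    for i, g in enumerate(genes):
        if spec.anchor_size is not None and i in anchors:
            rules[g] = NestedCanalyzingRule(target=g, expr=("var", g))  # frozen
            continue
        extra = int(rng.poisson(spec.mean_extra_regulators))
        if i in toggle_idx:
            c = genes[clock]
            if i == clock or target[i] == target[clock]:
                rules[g] = build_ncf(g, [], [c])  # rule: not clock
            else:
                rules[g] = build_ncf(g, [c], [])  # rule: clock
        elif target[i] == 1:
            activators = pick(pool_on, 1 + extra)
            inhibitors = pick(pool_off, extra)
            rules[g] = build_ncf(g, activators, inhibitors)
        else:
            # an always-on inhibitor forces the gene off
            inhibitors = pick(pool_on, 1 + extra)
            activators = pick(pool_off, extra)
            rules[g] = build_ncf(g, activators, inhibitors)

    net = BooleanNetwork(genes, rules)
    s = net.state(target)
    nxt = synchronous_step(net, s)
    if toggle_idx:
        flipped = list(target)
        for i in toggle_idx:
            flipped[i] = 1 - flipped[i]
        s2 = net.state(flipped)
        if nxt != s2 or synchronous_step(net, s2) != s:
            raise RuntimeError("planted 2-cycle failed verification")
        attractor = Attractor.from_cycle([s, s2])
    else:
        if nxt != s:
            raise RuntimeError("planted fixed point failed verification")
        attractor = Attractor.from_cycle([s])
    return PlantedNetwork(
        network=net, attractor=attractor, target_state=s,
        constant_genes=[genes[i] for i in const_idx],
        toggling_genes=[genes[i] for i in toggle_idx],
        anchors=[genes[i] for i in anchors],
    )


def sample_cells_near_state(state, n_cells: int, flip_prob: float = 0.0,
                            seed: int = 0) -> list[tuple[int, ...]]:
    """Initial bit vectors for synthetic cells: copies of ``state`` with
    each bit flipped independently with probability ``flip_prob``."""
    rng = np.random.default_rng(seed)
    base = np.asarray(list(state), dtype=np.int8)
    out = []
    for _ in range(n_cells):
        flips = rng.random(base.size) < flip_prob
        out.append(tuple(int(b) for b in np.where(flips, 1 - base, base)))
    return out


# ---------------------------------------------------------------------------
# Toy knowledge base for the construction pipeline
# ---------------------------------------------------------------------------

_HUB_GENES = ("BAX", "EGFR", "ERBB2", "ETV1", "IKBKG", "MAP3K7", "ST14",
              "PLAT", "DDR1", "ANXA1", "SMAD4", "TP53", "MYC", "AKT1", "CASP3")
_MANUAL_GENES = ("HSP90AB1", "YWHAB", "VIM", "CSNK2B", "TK1")


@dataclass
class KnowledgeBase:
    """In-memory flat-file evidence set plus the ground truth that built it."""

    pathway_lists: dict[str, set[str]]
    cell_line_expr: pd.DataFrame  # columns: tumor line, control line
    de_table: pd.DataFrame
    interactome_edges: list[tuple[str, str]]
    tf_table: pd.DataFrame
    sign_table: dict[tuple[str, str], str]
    seed_genes: tuple[str, ...]
    expected_genes: list[str]


def generate_knowledge_base(seed: int = 0, n_hubs: int = 15,
                            n_intermediaries: int = 53, n_tfs: int = 30,
                            hub_degree: int = 55,
                            n_direct_pairs: int = 60) -> KnowledgeBase:
    """Deterministic toy evidence set whose construction yields
    ``n_hubs + 5 manual + n_intermediaries + n_tfs`` network genes
    (103 with the defaults).

    Hubs get ``hub_degree`` distinct filler partners so they clear the
    50-partner hub threshold; selected seed pairs are joined directly or
    through one dedicated, well-expressed intermediary each.
    """
    rng = np.random.default_rng(seed)
    hubs = list(_HUB_GENES[:n_hubs]) + [f"HUB{i:02d}" for i in range(max(0, n_hubs - len(_HUB_GENES)))]
    manual = list(_MANUAL_GENES)
    intermediaries = [f"IM{i + 1:02d}" for i in range(n_intermediaries)]
    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    ns_genes = [f"NS{i + 1:02d}" for i in range(10)]       # present but not DE
    absent = [f"ABS{i + 1:03d}" for i in range(120)]       # in pathways, no expression

    # pathway lists: hubs spread over four lists, plus ns and absent padding
    lists: dict[str, set[str]] = {"APOPTOSIS": set(), "TP53_PATHWAY": set(),
                                  "KRAS_UP": set(), "KRAS_DN": set()}
    names = list(lists)
    for i, h in enumerate(hubs):
        lists[names[i % 4]].add(h)
    for i, g in enumerate(ns_genes):
        lists[names[i % 4]].add(g)
    for i, g in enumerate(absent):
        lists[names[i % 4]].add(g)

    # cell-line expression (tumor reference column first)
    rows = {}
    for g in hubs + manual:
        rows[g] = (float(rng.uniform(8, 20)), float(rng.uniform(8, 20)))
    for g in intermediaries:
        rows[g] = (float(rng.uniform(5, 15)), float(rng.uniform(5, 15)))
    for g in ns_genes:
        rows[g] = (float(rng.uniform(1, 3)), float(rng.uniform(1, 3)))
    cell_line = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=["TUMOR_LINE", "CONTROL_LINE"])

    de_rows = [(g, "up" if rng.random() < 0.5 else "down") for g in hubs]
    de_rows += [(g, "ns") for g in ns_genes]
    de = pd.DataFrame(de_rows, columns=["gene", "status"]).set_index("gene")

    seeds = sorted(hubs + manual)
    edges: list[tuple[str, str]] = []
    for h in hubs:
        for k in range(hub_degree):
            edges.append((h, f"FILL_{h}_{k:03d}"))
    for g in ns_genes:  # below the hub threshold
        for k in range(5):
            edges.append((g, f"FILL_{g}_{k}"))
    for m in manual:
        edges.append((m, f"FILL_{m}_0"))

    pairs = [(a, b) for i, a in enumerate(seeds) for b in seeds[i + 1:]]
    order = rng.permutation(len(pairs))
    direct = [pairs[i] for i in order[:n_direct_pairs]]
    via_im = [pairs[i] for i in order[n_direct_pairs:n_direct_pairs + n_intermediaries]]
    for a, b in direct:
        edges.append((a, b))
    for (a, b), im in zip(via_im, intermediaries):
        edges.append((a, im))
        edges.append((im, b))

    net_vertices = seeds + intermediaries
    tf_rows = []
    for tf in tfs:
        n_targets = int(rng.integers(1, 4))
        targets = [net_vertices[i] for i in rng.choice(len(net_vertices),
                                                       size=n_targets, replace=False)]
        for t in targets:
            mode = "activation" if rng.random() < 0.7 else "repression"
            tf_rows.append((tf, t, mode))
    tf_rows.append(("TFDECOY", "NOT_IN_NETWORK", "activation"))
    tf_df = pd.DataFrame(tf_rows, columns=["tf", "target", "mode"])

    signs: dict[tuple[str, str], str] = {}
    undirected = direct + [(a, im) for (a, b), im in zip(via_im, intermediaries)] \
        + [(im, b) for (a, b), im in zip(via_im, intermediaries)]
    for a, b in undirected:
        for s, t in ((a, b), (b, a)):
            signs[(s, t)] = "activation" if rng.random() < 0.7 else "inhibition"

    expected = sorted(seeds) + intermediaries + tfs
    return KnowledgeBase(
        pathway_lists=lists, cell_line_expr=cell_line, de_table=de,
        interactome_edges=edges, tf_table=tf_df, sign_table=signs,
        seed_genes=tuple(manual), expected_genes=expected)


def write_fixture(outdir, seed: int = 0, params: ExpressionSimParams | None = None,
                  kb: KnowledgeBase | None = None) -> dict[str, Path]:
    """Write a complete input bundle (knowledge base + expression + annotations)
    in the flat-file formats the pipeline reads; returns the path map.

    The expression matrix covers the genes of the network the knowledge base
    constructs, under the default 549-cell / 14-group profile.
    """
    from .network_construction import (ConstructionConfig, InteractomeGraph,
                                       build_grn)
    import networkx as nx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kb = kb if kb is not None else generate_knowledge_base(seed=seed)

    g = nx.Graph()
    g.add_edges_from(kb.interactome_edges)
    config = ConstructionConfig(seed_genes=kb.seed_genes,
                                low_expression_threshold=1.0,
                                reference_sample="TUMOR_LINE")
    net, _report = build_grn(kb.pathway_lists, kb.cell_line_expr,
                             kb.cell_line_expr[["CONTROL_LINE"]], kb.de_table,
                             InteractomeGraph(g), kb.tf_table, kb.sign_table,
                             config)

    if params is None:
        params = ExpressionSimParams(n_genes=net.n, genes=tuple(net.symbols),
                                     seed=seed)
    else:
        params.genes = tuple(net.symbols)
        params.n_genes = net.n
    expr, annotations, truth = simulate_expression_matrix(params)

    paths: dict[str, Path] = {}
    pw_dir = outdir / "pathways"
    pw_dir.mkdir(exist_ok=True)
    for name, genes_ in kb.pathway_lists.items():
        p = pw_dir / f"{name}.txt"
        p.write_text("\n".join(sorted(genes_)) + "\n")
        paths[f"pathway_{name}"] = p

    p = outdir / "cell_line_expression.tsv"
    kb.cell_line_expr.to_csv(p, sep="\t", float_format="%.6g")
    paths["cell_line_expression"] = p

    p = outdir / "de_status.tsv"
    kb.de_table.to_csv(p, sep="\t")
    paths["de_status"] = p

    p = outdir / "interactome.tsv"
    with open(p, "w") as fh:
        for a, b in kb.interactome_edges:
            fh.write(f"{a}\t{b}\n")
    paths["interactome"] = p

    p = outdir / "tf_table.tsv"
    kb.tf_table.to_csv(p, sep="\t", header=False, index=False)
    paths["tf_table"] = p

    p = outdir / "sign_table.tsv"
    with open(p, "w") as fh:
        for (s, t), sign in kb.sign_table.items():
            fh.write(f"{s}\t{t}\t{sign}\n")
    paths["sign_table"] = p

    p = outdir / "expression.tsv"
    expr.to_csv(p, sep="\t", float_format="%.6g")
    paths["expression"] = p

    p = outdir / "annotations.tsv"
    with open(p, "w") as fh:
        fh.write("cell_id\tsample_id\tcell_type\tpooled\tsubtype\n")
        for a in annotations:
            subtype = DEFAULT_SUBTYPES.get(a.sample_id, "")
            fh.write(f"{a.cell_id}\t{a.sample_id}\t{a.cell_type}\t"
                     f"{str(a.pooled)}\t{subtype}\n")
    paths["annotations"] = p

    p = outdir / "truth_bits.tsv"
    truth.to_csv(p, sep="\t")
    paths["truth_bits"] = p
    return paths
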