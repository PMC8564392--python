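"""Constancy labels, cell grouping, and the 95%-of-cells consensus rule."""

import numpy as np
import pytest

from scboolnet.attractor_analysis import (CellAnnotation, consensus_genes,
                                          group_cells, label_all_genes,
                                          label_gene_constancy,
                                          summarize_across_groups)
from scboolnet.boolean_network import NetworkState
from scboolnet.dynamics import Attractor


def cycle(*packed: str) -> Attractor:
    return Attractor.from_cycle([NetworkState.from_packed(p) for p in packed])


def labels_for(attr: Attractor, genes, cycle_fraction=1.0):
    return label_all_genes(attr, list(genes), cycle_fraction)


class TestConstancyLabels:
    def test_constant_one_gene_labeled_true(self):
        attr = cycle("10", "11")
        lab = label_gene_constancy(attr, 0, "g0")
        assert lab.label == "True" and lab.fraction_on == 1.0

    def test_varying_gene_labeled_x(self):
        attr = cycle("10", "11")
        assert label_gene_constancy(attr, 1, "g1").label == "X"

    def test_constant_zero_gene_labeled_false(self):
        attr = cycle("10", "10")  # same state twice collapses to singleton? no:
        attr = cycle("00")
        assert label_gene_constancy(attr, 1, "g1").label == "False"

    def test_most_states_mode(self):
        # gene on in 5 of 6 cycle states: True at fraction 0.8, X at 1.0
        states = ["1", "1", "1", "1", "1", "0"]
        attr = Attractor(tuple(NetworkState.from_packed(s) for s in states))
        assert label_gene_constancy(attr, 0, cycle_fraction=0.8).label == "True"
        assert label_gene_constancy(attr, 0, cycle_fraction=1.0).label == "X"

    def test_labels_partition(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            period = int(rng.integers(1, 6))
            states = [NetworkState(rng.integers(0, 2, size=4))
                      for _ in range(period)]
            attr = Attractor(tuple(states))
            for i in range(4):
                lab = label_gene_constancy(attr, i)
                assert lab.label in ("True", "False", "X")

    def test_cycle_fraction_bounds(self):
        with pytest.raises(ValueError):
            label_gene_constancy(cycle("1"), 0, cycle_fraction=0.5)


class TestGroupCells:
    def test_pooled_cells_dropped(self):
        anns = [CellAnnotation("c1", "S1", "malignant"),
                CellAnnotation("c2", "S1", "stromal"),
                CellAnnotation("c3", "S1", "malignant", pooled=True)]
        groups = group_cells(anns)
        assert groups == {("S1", "malignant"): ["c1"], ("S1", "stromal"): ["c2"]}

    def test_group_sizes_partition_nonpooled_cells(self):
        rng = np.random.default_rng(1)
        anns = [CellAnnotation(f"c{i}", f"S{rng.integers(3)}",
                               ["malignant", "stromal"][rng.integers(2)],
                               pooled=bool(rng.random() < 0.2))
                for i in range(100)]
        groups = group_cells(anns)
        n_nonpooled = sum(1 for a in anns if not a.pooled)
        assert sum(len(v) for v in groups.values()) == n_nonpooled

    def test_missing_sample_id_rejected(self):
        with pytest.raises(ValueError, match="sample id"):
            group_cells([CellAnnotation("c1", "", "malignant")])


class TestConsensus:
    def group_of(self, n_true: int, n_total: int):
        attr_true = cycle("1")
        attr_x = cycle("1", "0")  # single gene toggling -> X
        labels = {}
        for i in range(n_total):
            attr = attr_true if i < n_true else attr_x
            labels[f"c{i}"] = labels_for(attr, ["g"])
        return labels

    def test_boundary_inclusive_19_of_20(self):
        cons = consensus_genes(("S", "malignant"), self.group_of(19, 20), 0.95)
        assert cons.labels["g"] == "True"
        assert cons.support["g"] == pytest.approx(0.95)

    def test_18_of_20_is_no_call(self):
        cons = consensus_genes(("S", "malignant"), self.group_of(18, 20), 0.95)
        assert cons.labels["g"] == "X"

    def test_threshold_monotonicity(self):
        """Raising min_cell_fraction never converts a no-call into a call."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            n_true = int(rng.integers(0, 21))
            labels = self.group_of(n_true, 20)
            for lo, hi in [(0.6, 0.8), (0.8, 0.95), (0.95, 1.0)]:
                c_lo = consensus_genes(("S", "t"), labels, lo)
                c_hi = consensus_genes(("S", "t"), labels, hi)
                if c_lo.labels["g"] == "X":
                    assert c_hi.labels["g"] == "X"

    def test_duplication_stability(self):
        labels = self.group_of(19, 20)
        doubled = {**labels, **{f"dup_{k}": v for k, v in labels.items()}}
        c1 = consensus_genes(("S", "t"), labels, 0.95)
        c2 = consensus_genes(("S", "t"), doubled, 0.95)
        assert c1.labels == c2.labels

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(5)]
        for _ in range(20):
            cells = {}
            for ci in range(int(rng.integers(5, 30))):
                period = int(rng.integers(1, 4))
                states = [NetworkState(rng.integers(0, 2, size=5))
                          for _ in range(period)]
                cells[f"c{ci}"] = labels_for(Attractor(tuple(states)), genes)
            cons = consensus_genes(("S", "t"), cells, 0.95)
            n = len(cells)
            for g in genes:
                n_true = sum(1 for lab in cells.values()
                             if lab[g].label == "True")
                n_false = sum(1 for lab in cells.values()
                              if lab[g].label == "False")
                if n_true / n >= 0.95:
                    assert cons.labels[g] == "True"
                elif n_false / n >= 0.95:
                    assert cons.labels[g] == "False"
                else:
                    assert cons.labels[g] == "X"

    def test_strict_thresholds_mean_every_state_every_cell(self):
        """cycle_fraction=1, min_cell_fraction=1: True iff gene is 1 in every
        state of every cell's attractor."""
        on_everywhere = {f"c{i}": labels_for(cycle("11"), ["a", "b"])
                         for i in range(5)}
        on_everywhere["c5"] = labels_for(cycle("10", "11"), ["a", "b"])
        cons = consensus_genes(("S", "t"), on_everywhere, 1.0)
        assert cons.labels["a"] == "True"
        assert cons.labels["b"] == "X"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no attractor"):
            consensus_genes(("S", "t"), {}, 0.95)


class TestSummarize:
    def make_consensus(self, group, labels):
        from scboolnet.attractor_analysis import GroupConsensus
        return GroupConsensus(group=group, labels=labels,
                              support={g: 1.0 for g in labels},
                              n_cells=10)

    def test_matrix_values_come_from_consensus(self):
        c1 = self.make_consensus(("S1", "malignant"), {"g": "True"})
        c2 = self.make_consensus(("S2", "malignant"), {"g": "X"})
        matrix, _ = summarize_across_groups([c1, c2], ["g"])
        assert matrix.loc["g", "S1|malignant"] == "constant_true"
        assert matrix.loc["g", "S2|malignant"] == "non_constant"

    def test_never_expressed_in_subtype_pattern(self):
        groups = [self.make_consensus((f"T{i}", "malignant"), {"g": "False"})
                  for i in range(3)]
        groups.append(self.make_consensus(("L1", "malignant"), {"g": "True"}))
        subtypes = {"T0": "TNBC", "T1": "TNBC", "T2": "TNBC",
                    "L1": "luminal_A"}
        _, patterns = summarize_across_groups(groups, ["g"],
                                              subtype_of=subtypes)
        assert patterns["g"]["never_expressed_in_subtypes"] == ["TNBC"]

    def test_expressed_in_all_groups_except_one(self):
        groups = [self.make_consensus((f"S{i}", "malignant"), {"g": "True"})
                  for i in range(3)]
        groups.append(self.make_consensus(("S9", "malignant"), {"g": "False"}))
        _, patterns = summarize_across_groups(groups, ["g"])
        assert patterns["g"]["expressed_in_all_groups_except"] == "S9|malignant"

    def test_unknown_panel_gene_rejected(self):
        c = self.make_consensus(("S1", "malignant"), {"g": "True"})
        with pytest.raises(ValueError, match="MISSING"):
            summarize_across_groups([c], ["MISSING"])

    def test_columns_ordered_by_subtype_then_sample(self):
        c1 = self.make_consensus(("B", "malignant"), {"g": "True"})
        c2 = self.make_consensus(("A", "malignant"), {"g": "True"})
        subtypes = {"B": "HER2", "A": "TNBC"}
        matrix, _ = summarize_across_groups([c1, c2], ["g"],
                                            subtype_of=subtypes)
        assert list(matrix.columns) == ["B|malignant", "A|malignant"]
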