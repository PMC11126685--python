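import itertools

import numpy as np
import pandas as pd
import pytest

from lichenscan import hgt
from lichenscan.tree import parse_newick

from conftest import random_tree

# eight-lineage host tree mirroring a bacteria-origin transfer scenario:
# presence in bacteria, one non-Dikarya fungal lineage and the symbiotic algae
LINEAGE_TREE = (
    "(bacteria:3,((Mucoromycotina:1,Dikarya:1):1,(animals:1.5,"
    "(land_plants:1,(other_chlorophytes:0.5,(NSA_algae:0.2,LAS_algae:0.2):0.3):0.5):0.5):0.5):1);"
)


def brute_force_min_changes(tree, present, gain_cost=1.0, loss_cost=1.0):
    """Minimum event cost over all ancestral labelings, by enumeration."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tip_state = {
        v: (1 if tree.labels[v] in present else 0) for v in tree.tip_indices()
    }
    best = float("inf")
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = dict(zip(internal, assign))
        states.update(tip_state)
        cost = 0.0
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            if states[p] == 0 and states[v] == 1:
                cost += gain_cost
            elif states[p] == 1 and states[v] == 0:
                cost += loss_cost
        best = min(best, cost)
    return best


class TestSpecificity:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(0)
        species = [f"las{i}" for i in range(13)] + [f"nsa{i}" for i in range(23)]
        m = pd.DataFrame(0, index=species, columns=["GH8", "everywhere", "nowhere"])
        m.loc[[f"las{i}" for i in range(11)], "GH8"] = 1  # 11/13 retained
        m.loc[[f"nsa{i}" for i in range(5)], "GH8"] = 1  # 5/23 retained
        m["everywhere"] = 2
        return m

    @pytest.fixture
    def groups(self, matrix):
        return pd.Series(
            ["focal"] * 13 + ["other"] * 23, index=matrix.index
        )

    def test_retention_fractions(self, matrix, groups):
        prof = hgt.specificity_profile(matrix, groups, "GH8")
        assert (prof["focal_present"], prof["focal_total"]) == (11, 13)
        assert (prof["other_present"], prof["other_total"]) == (5, 23)
        assert prof["focal_fraction"] == pytest.approx(11 / 13)
        assert prof["other_fraction"] == pytest.approx(5 / 23)

    def test_ubiquitous_and_absent_families(self, matrix, groups):
        assert hgt.specificity_profile(matrix, groups, "everywhere")["focal_fraction"] == 1.0
        prof = hgt.specificity_profile(matrix, groups, "nowhere")
        assert prof["focal_fraction"] == 0.0 and prof["other_fraction"] == 0.0

    def test_unknown_family_rejected(self, matrix, groups):
        with pytest.raises(KeyError):
            hgt.specificity_profile(matrix, groups, "GH99")


class TestEventScenarios:
    def test_bacterial_origin_worked_example(self):
        tree = parse_newick(LINEAGE_TREE)
        scen = hgt.event_scenarios(tree, {"bacteria", "Mucoromycotina", "LAS_algae"})
        assert scen.transfers == 2
        assert scen.dollo_losses == 5
        assert scen.verdict == "hgt_more_parsimonious"

    def test_counting_the_origin_is_optional(self):
        tree = parse_newick(LINEAGE_TREE)
        scen = hgt.event_scenarios(
            tree, {"bacteria", "Mucoromycotina", "LAS_algae"}, count_origin=True
        )
        assert scen.transfers == 3

    def test_single_clade_is_vertical(self):
        tree = parse_newick(LINEAGE_TREE)
        scen = hgt.event_scenarios(tree, {"NSA_algae", "LAS_algae"})
        assert (scen.transfers, scen.dollo_losses) == (0, 0)

    def test_full_presence_needs_no_events(self):
        tree = parse_newick(LINEAGE_TREE)
        scen = hgt.event_scenarios(tree, set(tree.tip_labels))
        assert (scen.transfers, scen.dollo_losses) == (0, 0)

    def test_unknown_tip_rejected(self):
        tree = parse_newick(LINEAGE_TREE)
        with pytest.raises(ValueError, match="martians"):
            hgt.event_scenarios(tree, {"martians"})

    def test_sankoff_matches_brute_force_on_small_trees(self):
        rng = np.random.default_rng(31)
        for n in range(4, 9):
            tree = random_tree(rng, n)
            labels = tree.tip_labels
            for _ in range(20):
                k = int(rng.integers(1, n + 1))
                present = set(rng.choice(labels, size=k, replace=False))
                got = hgt.sankoff_min_changes(tree, present)
                ref = brute_force_min_changes(tree, present)
                assert got == ref

    def test_sankoff_with_asymmetric_costs(self):
        rng = np.random.default_rng(32)
        tree = random_tree(rng, 7)
        labels = tree.tip_labels
        present = set(labels[:3])
        got = hgt.sankoff_min_changes(tree, present, gain_cost=2.5, loss_cost=1.0)
        ref = brute_force_min_changes(tree, present, gain_cost=2.5, loss_cost=1.0)
        assert got == pytest.approx(ref)

    def test_invariant_to_zero_length_subdivision(self):
        tree = parse_newick(LINEAGE_TREE)
        pres = {"bacteria", "Mucoromycotina", "LAS_algae"}
        base = hgt.event_scenarios(tree, pres)
        # subdivide the branch above the fungal pair with a zero-length node
        from lichenscan.tree import PhyloTree

        target = tree.mrca(["Mucoromycotina", "Dikarya"])
        parent = list(tree.parent)
        lengths = list(tree.lengths)
        labels = list(tree.labels)
        new = len(parent)
        parent.append(parent[target])
        lengths.append(lengths[target])
        labels.append(None)
        parent[target] = new
        lengths[target] = 0.0
        tree2 = PhyloTree(parent, lengths, labels, tree.root)
        again = hgt.event_scenarios(tree2, pres)
        assert (again.transfers, again.dollo_losses) == (base.transfers, base.dollo_losses)
        assert again.sankoff_min_changes == base.sankoff_min_changes

    def test_event_count_bounds(self):
        rng = np.random.default_rng(33)
        tree = random_tree(rng, 8)
        labels = tree.tip_labels
        for _ in range(30):
            k = int(rng.integers(1, 9))
            present = set(rng.choice(labels, size=k, replace=False))
            scen = hgt.event_scenarios(tree, present)
            assert scen.transfers + 1 <= len(present)
            assert scen.dollo_losses <= len(labels) - len(present)


class TestGeneTreeNesting:
    def test_nested_in_bacteria(self):
        gt = parse_newick(
            "(((alga1|chlorophyte:1,alga2|chlorophyte:1):1,bact1|bacteria:1):1,"
            "(bact2|bacteria:1,(fung1|fungi:1,fung2|fungi:1):1):1);"
        )
        rep = hgt.gene_tree_nesting(gt, "chlorophyte", "fungi")
        assert rep.rooted
        assert rep.focal_monophyletic
        assert rep.donor_hypothesis == "bacteria"

    def test_two_scattered_clades_suggest_double_transfer(self):
        gt = parse_newick(
            "((fung1|fungi:1,fung2|fungi:1):1,((algA|chlorophyte:1,bactA|bacteria:1):1,"
            "((algB1|chlorophyte:1,algB2|chlorophyte:1):1,bactB|bacteria:1):1):1);"
        )
        rep = hgt.gene_tree_nesting(gt, "chlorophyte", "fungi")
        assert not rep.focal_monophyletic
        assert rep.n_focal_clades == 2
        assert rep.donor_hypothesis == "bacteria"

    def test_sister_chlorophytes_mean_vertical(self):
        gt = parse_newick(
            "((fung1|fungi:1,fung2|fungi:1):1,((cand1|lichen_alga:1,cand2|lichen_alga:1):1,"
            "(chl1|chlorophyte:1,chl2|chlorophyte:1):1):1);"
        )
        rep = hgt.gene_tree_nesting(
            gt, "lichen_alga", "fungi", vertical_taxa={"chlorophyte"}
        )
        assert rep.donor_hypothesis == "none"

    def test_missing_focal_tips_rejected(self):
        gt = parse_newick("((a|bacteria:1,b|bacteria:1):1,c|fungi:1);")
        with pytest.raises(ValueError, match="focal"):
            hgt.gene_tree_nesting(gt, "chlorophyte", "fungi")

    def test_unrooted_fallback_flagged(self):
        gt = parse_newick("((a|chlorophyte:1,b|bacteria:1):1,c|bacteria:1);")
        rep = hgt.gene_tree_nesting(gt, "chlorophyte", "fungi")
        assert not rep.rooted
        assert rep.donor_hypothesis == "bacteria"


class TestAnchoring:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "scaffold", "start", "end", "strand", "assignment"]
        )

    def test_host_surrounded_candidate_is_anchored(self):
        rows = []
        for i in range(11):
            name = "cand" if i == 5 else f"nb{i}"
            assign = "unassigned" if i == 5 else ("unassigned" if i == 2 else "host")
            rows.append((name, "s1", 1000 * (i + 1), 1000 * (i + 1) + 800, "+", assign))
        v = hgt.check_anchoring(self._table(rows), "cand", window=5)
        assert v.verdict == "anchored"
        assert v.n_host == 9

    def test_contaminant_neighborhood_is_suspect(self):
        rows = [
            ("nb1", "s2", 1000, 1800, "+", "non-host"),
            ("cand", "s2", 3000, 3800, "+", "unassigned"),
            ("nb2", "s2", 5000, 5800, "+", "non-host"),
        ]
        v = hgt.check_anchoring(self._table(rows), "cand")
        assert v.verdict == "suspect"

    def test_lonely_gene_has_insufficient_context(self):
        rows = [("cand", "s3", 1000, 1800, "+", "unassigned")]
        v = hgt.check_anchoring(self._table(rows), "cand")
        assert v.verdict == "insufficient_context"

    def test_unknown_gene_rejected(self):
        rows = [("cand", "s3", 1000, 1800, "+", "unassigned")]
        with pytest.raises(KeyError):
            hgt.check_anchoring(self._table(rows), "ghost")


class TestScaffoldIO:
    def test_gff_round_trip(self, tmp_path):
        from lichenscan.simulate import SimConfig, sim_hgt_evidence, scaffold_table_to_gff

        rng = np.random.default_rng(3)
        _, table, truth = sim_hgt_evidence(SimConfig(seed=3), "xenolog", rng, family="OGX")
        gff_text, taxa = scaffold_table_to_gff(table)
        gff_path = tmp_path / "genes.gff3"
        taxa_path = tmp_path / "taxa.tsv"
        gff_path.write_text(gff_text)
        taxa.to_csv(taxa_path, sep="\t", index=False)
        loaded = hgt.load_scaffold_table(gff_path, taxa_path)
        assert set(loaded["gene"]) == set(table["gene"])
        v = hgt.check_anchoring(loaded, truth["candidate_gene"])
        assert v.verdict == "anchored"
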