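"""Horizontal-gene-transfer triage: lineage specificity, event parsimony,
gene-tree nesting and scaffold-anchoring contamination checks.

A candidate xenolog is supported when (i) the family is present almost only
in the focal (symbiotic) species, (ii) explaining its lineage distribution by
transfers takes fewer events than a single ancient origin followed by Dollo
losses, (iii) the recipient sequences are nested inside the putative donor
clade in the gene tree, and (iv) the gene is anchored in a scaffold
surrounded by host-assigned genes (ruling out contamination).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from .tree import PhyloTree, parse_newick

__all__ = [
    "specificity_profile",
    "event_scenarios",
    "sankoff_min_changes",
    "gene_tree_nesting",
    "check_anchoring",
    "load_gene_tree",
    "load_scaffold_table",
    "EventScenario",
    "NestingReport",
    "AnchoringVerdict",
]


# ---------------------------------------------------------------------------
# lineage specificity
# ---------------------------------------------------------------------------

def specificity_profile(
    matrix: pd.DataFrame, groups: pd.Series, family: str
) -> dict:
    """Presence fractions (count >= 1) of a family in focal vs other species."""
    if family not in matrix.columns:
        raise KeyError(f"family {family!r} absent from matrix")
    groups = groups.reindex(matrix.index).dropna()
    focal = matrix.index[groups == "focal"]
    other = matrix.index[groups == "other"]
    pres = matrix[family] > 0
    n_focal_present = int(pres.loc[focal].sum())
    n_other_present = int(pres.loc[other].sum())
    return {
        "family": family,
        "focal_present": n_focal_present,
        "focal_total": len(focal),
        "focal_fraction": n_focal_present / len(focal) if len(focal) else float("nan"),
        "other_present": n_other_present,
        "other_total": len(other),
        "other_fraction": n_other_present / len(other) if len(other) else float("nan"),
    }


# ---------------------------------------------------------------------------
# transfer vs Dollo-loss event parsimony
# ---------------------------------------------------------------------------

@dataclass
class EventScenario:
    transfers: int
    dollo_losses: int
    verdict: str  # hgt_more_parsimonious / loss_more_parsimonious / tie
    sankoff_min_changes: float
    present_clades: list[list[str]] = field(default_factory=list)


def _pure_presence(tree: PhyloTree, present: set[str]) -> np.ndarray:
    """per-node: 1 if all subtree tips present, 0 if none, -1 if mixed."""
    status = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.postorder():
        if tree.is_tip(v):
            status[v] = 1 if tree.labels[v] in present else 0
        else:
            vals = {status[c] for c in tree.children[v]}
            status[v] = vals.pop() if len(vals) == 1 and -1 not in vals else -1
    return status


def event_scenarios(
    host_tree: PhyloTree,
    presence: set[str] | list[str],
    count_origin: bool = False,
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> EventScenario:
    """Compare transfer and Dollo-loss explanations of a presence pattern.

    ``transfers`` counts maximal present clades minus one (the donor lineage
    is treated as the native origin and not counted; ``count_origin=True``
    counts it).  ``dollo_losses`` counts maximal absent clades strictly inside
    the subtree of the MRCA of the present tips.  A Sankoff minimum-change
    count with configurable gain/loss costs is reported for sensitivity.
    """
    present = set(presence)
    tips = set(host_tree.tip_labels)
    stray = present - tips
    if stray:
        raise ValueError(f"presence tips not in tree: {sorted(stray)}")
    if not present:
        raise ValueError("presence set is empty")
    sank = sankoff_min_changes(host_tree, present, gain_cost, loss_cost)
    if present == tips:
        return EventScenario(0, 0, "tie", sank, [sorted(tips)])
    status = _pure_presence(host_tree, present)
    parent = host_tree.parent
    present_clades = [
        v
        for v in range(host_tree.n_nodes)
        if status[v] == 1 and (parent[v] < 0 or status[parent[v]] != 1)
    ]
    transfers = len(present_clades) if count_origin else len(present_clades) - 1
    mrca = host_tree.mrca(present)
    in_mrca = np.zeros(host_tree.n_nodes, dtype=bool)
    stack = [mrca]
    while stack:
        v = stack.pop()
        in_mrca[v] = True
        stack.extend(host_tree.children[v])
    losses = [
        v
        for v in range(host_tree.n_nodes)
        if in_mrca[v] and v != mrca and status[v] == 0 and status[parent[v]] != 0
    ]
    dollo = len(losses)
    if transfers < dollo:
        verdict = "hgt_more_parsimonious"
    elif transfers > dollo:
        verdict = "loss_more_parsimonious"
    else:
        verdict = "tie"
    clades = [
        sorted(host_tree.labels[t] for t in host_tree.subtree_tips(v))
        for v in present_clades
    ]
    return EventScenario(transfers, dollo, verdict, sank, clades)


def sankoff_min_changes(
    tree: PhyloTree,
    present: set[str],
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> float:
    """Minimum total cost of 0->1 (gain) and 1->0 (loss) edge changes
    explaining tip presence, over all ancestral labelings (root state free)."""
    INF = float("inf")
    cost = np.zeros((tree.n_nodes, 2))
    for v in tree.postorder():
        if tree.is_tip(v):
            obs = 1 if tree.labels[v] in present else 0
            cost[v, 0] = 0.0 if obs == 0 else INF
            cost[v, 1] = 0.0 if obs == 1 else INF
        else:
            for s in (0, 1):
                total = 0.0
                for c in tree.children[v]:
                    stay = cost[c, s]
                    flip = cost[c, 1 - s] + (gain_cost if s == 0 else loss_cost)
                    total += min(stay, flip)
                cost[v, s] = total
    return float(cost[tree.root].min())


# ---------------------------------------------------------------------------
# gene-tree nesting
# ---------------------------------------------------------------------------

@dataclass
class NestingReport:
    focal_monophyletic: bool
    n_focal_clades: int
    sister_composition: list[dict[str, int]]
    donor_hypothesis: str
    rooted: bool


def _tip_taxon(label: str) -> str:
    if "|" not in label:
        raise ValueError(f"gene-tree tip {label!r} lacks a '|taxon' suffix")
    return label.rsplit("|", 1)[1]


def load_gene_tree(source: str) -> PhyloTree:
    """Parse a gene-tree newick whose tips are labelled ``seqid|taxon_group``."""
    source = str(source)
    if "(" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    gt = parse_newick(text)
    for lab in gt.tip_labels:
        _tip_taxon(lab)
    return gt


def gene_tree_nesting(
    gene_tree: PhyloTree,
    focal_group: str,
    outgroup: str,
    vertical_taxa: set[str] | None = None,
) -> NestingReport:
    """Where do the focal sequences sit in the gene tree?

    The tree is rooted on the MRCA of the outgroup tips (if present —
    otherwise the analysis runs on the tree as supplied with ``rooted=False``).
    Maximal focal-only clades are located and the taxon composition of each
    clade's sister lineage(s) is tallied; the donor hypothesis is the majority
    taxon of that tally.  A majority belonging to ``vertical_taxa`` (or to the
    focal group itself) means vertical signal and yields donor ``none``.
    """
    vertical = set(vertical_taxa or ()) | {focal_group}
    taxa = {i: _tip_taxon(gene_tree.labels[i]) for i in gene_tree.tip_indices()}
    focal_tips = [i for i, t in taxa.items() if t == focal_group]
    if not focal_tips:
        raise ValueError(f"no tips of focal group {focal_group!r}")
    out_tips = [gene_tree.labels[i] for i, t in taxa.items() if t == outgroup]
    rooted = False
    tree = gene_tree
    if out_tips and len(out_tips) < len(taxa):
        mrca = tree.mrca(out_tips)
        if mrca != tree.root:
            tree = tree.reroot_above(mrca)
        rooted = True
        taxa = {i: _tip_taxon(tree.labels[i]) for i in tree.tip_indices()}
    focal_labels = {tree.labels[i] for i, t in taxa.items() if t == focal_group}
    status = _pure_presence(tree, focal_labels)
    parent = tree.parent
    clades = [
        v
        for v in range(tree.n_nodes)
        if status[v] == 1 and (parent[v] < 0 or status[parent[v]] != 1)
    ]
    sisters: list[dict[str, int]] = []
    overall: Counter = Counter()
    for v in clades:
        p = parent[v]
        comp: Counter = Counter()
        if p >= 0:
            for sib in tree.children[p]:
                if sib == v:
                    continue
                for t in tree.subtree_tips(sib):
                    comp[_tip_taxon(tree.labels[t])] += 1
        sisters.append(dict(comp))
        overall.update(comp)
    if overall:
        donor = overall.most_common(1)[0][0]
        if donor in vertical:
            donor = "none"
    else:
        donor = "none"
    return NestingReport(
        focal_monophyletic=len(clades) == 1,
        n_focal_clades=len(clades),
        sister_composition=sisters,
        donor_hypothesis=donor,
        rooted=rooted,
    )


# ---------------------------------------------------------------------------
# scaffold anchoring
# ---------------------------------------------------------------------------

@dataclass
class AnchoringVerdict:
    gene: str
    n_host: int
    n_non_host: int
    n_unassigned: int
    host_fraction: float
    verdict: str  # anchored / suspect / insufficient_context


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def load_scaffold_table(gff_path, taxa_path) -> pd.DataFrame:
    """Combine gene features from a GFF3 file with a taxonomic-assignment TSV.

    The sidecar TSV has columns (gene, assignment) with assignment in
    {host, non-host, unassigned}.  Coordinates stay 1-based inclusive as on
    disk; neighbor ordering uses start coordinates only.
    """
    gff = pd.read_csv(
        gff_path, sep="\t", comment="#", header=None, names=_GFF_COLS, dtype={"seqid": str}
    )
    gff = gff[gff["type"] == "gene"].copy()
    ids = []
    for attr in gff["attributes"]:
        m = re.search(r"ID=([^;]+)", attr)
        if not m:
            raise ValueError(f"gene feature without ID attribute: {attr!r}")
        ids.append(m.group(1))
    gff["gene"] = ids
    taxa = pd.read_csv(taxa_path, sep="\t")
    taxa.columns = ["gene", "assignment"]
    table = gff.merge(taxa, on="gene", how="left")
    table["assignment"] = table["assignment"].fillna("unassigned")
    bad = (table["start"] > table["end"]).to_numpy()
    if bad.any():
        raise ValueError(f"start > end for gene {table['gene'][bad].iloc[0]!r}")
    return table[["gene", "seqid", "start", "end", "strand", "assignment"]].rename(
        columns={"seqid": "scaffold"}
    )


def check_anchoring(
    scaffold_table: pd.DataFrame, gene: str, window: int = 5,
    host_fraction_min: float = 0.6, min_assigned_per_side: int = 2,
) -> AnchoringVerdict:
    """Is a candidate gene surrounded by host-assigned neighbors?

    Up to ``window`` genes on each side (start-coordinate order, same
    scaffold) are inspected.  ``anchored`` requires at least
    ``min_assigned_per_side`` assigned (host or non-host) neighbors on each
    side that exists and a host fraction among assigned neighbors of at least
    ``host_fraction_min``; a lower fraction is ``suspect``; fewer than two
    assigned neighbors in total is ``insufficient_context``.
    """
    rows = scaffold_table[scaffold_table["gene"] == gene]
    if rows.empty:
        raise KeyError(f"gene {gene!r} not found on any scaffold")
    row = rows.iloc[0]
    scaf = scaffold_table[scaffold_table["scaffold"] == row["scaffold"]].sort_values(
        "start", kind="mergesort"
    )
    order = list(scaf["gene"])
    pos = order.index(gene)
    left = scaf.iloc[max(0, pos - window):pos]
    right = scaf.iloc[pos + 1:pos + 1 + window]
    neighbors = pd.concat([left, right])
    n_host = int((neighbors["assignment"] == "host").sum())
    n_non = int((neighbors["assignment"] == "non-host").sum())
    n_un = int((neighbors["assignment"] == "unassigned").sum())
    assigned = n_host + n_non
    frac = n_host / assigned if assigned else float("nan")
    if assigned < 2:
        verdict = "insufficient_context"
    elif frac < host_fraction_min:
        verdict = "suspect"
    else:
        sides_ok = True
        for side in (left, right):
            if len(side) == 0:
                continue  # side does not exist (scaffold edge)
            if (side["assignment"] != "unassigned").sum() < min_assigned_per_side:
                sides_ok = False
        verdict = "anchored" if sides_ok else "insufficient_context"
    return AnchoringVerdict(gene, n_host, n_non, n_un, frac, verdict)
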