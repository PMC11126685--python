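"""Synthetic datasets with known ground truth for the whole pipeline.

The generator emulates the statistical structure of a chlorophyte-wide
comparative screen: an ultrametric Yule species tree (~141 tips, height 1), a
binary symbiotic-status trait with a few independent planted gains and nested
tip losses, an orthogroup count matrix mixing background families,
trait-linked "expanded" families (count multiplier in symbiotic species) and
near-symbiont-specific "xenolog" families, per-gene differential-expression
tables for one profiled symbiotic species, gene trees with donor-nested or
vertical placements, and scaffold fixtures with host-like or
contaminant-like neighborhoods.  Every quantity drawn is recorded in a
:class:`SimTruth` so recovery can be scored exactly.

A single RNG stream per dataset is used, with the draw order
tree -> trait -> families -> genes -> fixtures, so identical configurations
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import PhyloTree, write_newick

__all__ = [
    "SimConfig",
    "SimTruth",
    "sim_tree",
    "sim_trait",
    "sim_matrix",
    "sim_deg",
    "sim_deg_partition",
    "sim_hgt_evidence",
    "simulate_dataset",
    "strong_effect_config",
]


@dataclass
class SimConfig:
    seed: int = 1
    n_species: int = 141
    # trait
    trait_mode: str = "planted"  # or "mk"
    k_gains: int = 3
    n_losses: int = 11
    clade_min: int = 10
    clade_max: int = 28
    q01: float = 0.5
    q10: float = 1.5
    # families
    n_background: int = 2000
    n_expanded: int = 20
    multiplier: float = 4.0
    n_xenolog: int = 2
    rho: float = 0.85  # xenolog retention in trait-1 species
    eps: float = 0.2  # xenolog retention in trait-0 species
    gamma_shape: float = 2.0
    gamma_scale: float = 1.0
    xenolog_extra_mean: float = 0.3
    # differential expression
    link_prob: float = 0.8
    background_de_prob: float = 0.05
    lfc_threshold: float = 1.5
    lfc_excess_mean: float = 1.0
    null_lfc_sd: float = 0.5
    de_fdr_max: float = 0.05
    # HGT fixtures
    n_vertical_controls: int = 2
    anchoring_window: int = 5

    def __post_init__(self):
        for p in (self.rho, self.eps, self.link_prob, self.background_de_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.trait_mode == "planted" and self.k_gains < 1:
            raise ValueError("planted mode needs k_gains >= 1")
        if self.multiplier <= 1.0:
            raise ValueError("expansion multiplier must exceed 1")


def strong_effect_config(seed: int = 1) -> SimConfig:
    """Preset with many strongly expanded families, so the discriminant
    top-100 is expected to sit entirely inside the enrichment-significant set."""
    return SimConfig(seed=seed, n_expanded=100, multiplier=6.0)


@dataclass
class SimTruth:
    n_gains: int = 0
    n_losses: int = 0
    gain_edges: list[int] = field(default_factory=list)
    loss_edges: list[int] = field(default_factory=list)
    node_states: list[int] = field(default_factory=list)
    trait: dict = field(default_factory=dict)
    expanded_families: list[str] = field(default_factory=list)
    xenolog_families: list[str] = field(default_factory=list)
    gene_status: dict = field(default_factory=dict)  # gene -> up/down/none
    gene_tree_roles: dict = field(default_factory=dict)  # family -> xenolog/vertical
    scaffold_roles: dict = field(default_factory=dict)  # gene -> clean/contaminated

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def sim_tree(n_species: int, rng: np.random.Generator) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree scaled to height 1."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    death = [0.0, None, None]
    active = [1, 2]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        v = active.pop(idx)
        death[v] = t
        for _ in range(2):
            parent.append(v)
            birth.append(t)
            death.append(None)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / n_species)
    lengths = []
    labels: list[str | None] = []
    n_tip = 0
    for v in range(len(parent)):
        end = death[v] if death[v] is not None else t_end
        lengths.append((end - birth[v]) / t_end if v != 0 else 0.0)
        if death[v] is None:
            n_tip += 1
            labels.append(f"sp{n_tip:03d}")
        else:
            labels.append(None)
    return PhyloTree(parent, lengths, labels, 0)


# ---------------------------------------------------------------------------
# trait history
# ---------------------------------------------------------------------------

def _transition_prob(q01: float, q10: float, t: float) -> np.ndarray:
    s = q01 + q10
    e = np.exp(-s * t)
    p00 = (q10 + q01 * e) / s
    p11 = (q01 + q10 * e) / s
    return np.array([[p00, 1 - p00], [1 - p11, p11]])


# clade-selection relaxation ladder for planted gains:
# (min stem length, min intervening tips between clades, min side branches on
#  the inter-clade path, max parent-stem / clade-stem ratio, max crown depth)
_CLADE_LADDER = [
    (0.10, 15, 5, 0.6, 0.40),
    (0.10, 12, 5, 0.8, 0.40),
    (0.08, 12, 4, 1.0, 0.50),
    (0.06, 10, 4, None, None),
    (0.04, 8, 2, None, None),
    (0.02, 4, 1, None, None),
    (0.00, 0, 0, None, None),
]
# loss-placement ladder: (min terminal branch length, min fraction of tips
# kept present under every internal node of the clade)
_LOSS_LADDER = [(0.08, 0.55), (0.06, 0.55), (0.04, 0.50), (0.00, 0.45)]


def _select_planted_clades(tree: PhyloTree, cfg: SimConfig) -> list[int]:
    """Greedy largest-first selection of k disjoint gain clades.

    Constraints (relaxed stepwise if the tree cannot satisfy them) keep the
    planted gains identifiable for likelihood-based reconstruction: each clade
    hangs on a long stem relative to its parent's, is compact (shallow crown),
    and any two clades are separated by several intervening lineages.
    """
    parent = tree.parent
    depths = tree.depths()
    sizes = {v: len(tree.subtree_tips(v)) for v in range(tree.n_nodes) if not tree.is_tip(v)}
    tipsets = {v: set(tree.subtree_tips(v)) for v in sizes}
    crown = {v: max(depths[t] for t in tipsets[v]) - depths[v] for v in sizes}

    def path_between(a: int, b: int):
        up_a = []
        x = a
        while x >= 0:
            up_a.append(x)
            x = int(parent[x])
        aset = set(up_a)
        up_b = []
        x = b
        while x not in aset:
            up_b.append(x)
            x = int(parent[x])
        mrca = x
        return up_a[1:up_a.index(mrca)], up_b[1:], mrca

    def side_branches(a: int, b: int) -> int:
        above_a, above_b, mrca = path_between(a, b)
        on_path = set(above_a) | set(above_b) | {a, b, mrca}
        return sum(
            1
            for v in [*above_a, *above_b, mrca]
            for c in tree.children[v]
            if c not in on_path
        )

    for min_stem, sep, side, pstem_ratio, crown_max in _CLADE_LADDER:
        cands = [
            v
            for v, s in sizes.items()
            if cfg.clade_min <= s <= cfg.clade_max
            and v != tree.root
            and tree.lengths[v] >= min_stem
            and (
                pstem_ratio is None
                or parent[v] < 0
                or tree.lengths[parent[v]] <= pstem_ratio * tree.lengths[v]
            )
            and (crown_max is None or crown[v] <= crown_max)
        ]
        cands.sort(key=lambda v: (-sizes[v], v))
        chosen: list[int] = []
        covered: set[int] = set()
        for v in cands:
            tv = tipsets[v]
            if tv & covered:
                continue
            ok = True
            for c in chosen:
                _, _, mrca = path_between(v, c)
                between = len(tipsets[mrca]) - len(tipsets[v]) - len(tipsets[c])
                if between < sep or side_branches(v, c) < side:
                    ok = False
                    break
            if not ok:
                continue
            chosen.append(v)
            covered |= tv
            if len(chosen) == cfg.k_gains:
                return chosen
    raise ValueError(
        f"cannot place {cfg.k_gains} disjoint clades of size "
        f"[{cfg.clade_min}, {cfg.clade_max}] on this tree"
    )


def _place_planted_losses(
    tree: PhyloTree, chosen: list[int], cfg: SimConfig, rng: np.random.Generator
) -> list[int]:
    """Flip loss tips inside the gained clades, keeping the losses readable:
    never two sibling tips, never a direct child of a clade root, losses on
    reasonably long terminal branches, and every internal clade node keeps a
    majority of its tips present."""
    parent = tree.parent
    tipsets = {v: set(tree.subtree_tips(v)) for v in range(tree.n_nodes) if not tree.is_tip(v)}
    clade_of: dict[int, int] = {}
    for v in chosen:
        for t in tree.subtree_tips(v):
            clade_of[t] = v
    tips = set(clade_of)
    for min_len, guard in _LOSS_LADDER:
        present = dict.fromkeys(tips, True)
        eligible = [
            t
            for t in sorted(tips)
            if parent[t] not in chosen and tree.lengths[t] >= min_len
        ]
        losses: list[int] = []
        used_parents: set[int] = set()
        for j in rng.permutation(len(eligible)):
            t = eligible[j]
            par = int(parent[t])
            if par in used_parents:
                continue
            ok = True
            x = par
            while True:
                sub = tipsets.get(x)
                if sub is None:
                    break
                kept = sum(1 for u in sub if present[u] and u != t)
                if kept < guard * len(sub):
                    ok = False
                    break
                if x == clade_of[t]:
                    break
                x = int(parent[x])
            if not ok:
                continue
            losses.append(t)
            used_parents.add(par)
            present[t] = False
            if len(losses) == cfg.n_losses:
                return losses
    raise ValueError(
        f"could only place {len(losses)} of {cfg.n_losses} losses under the "
        "identifiability constraints; enlarge clades or reduce losses"
    )


def sim_trait(
    tree: PhyloTree, cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, int], SimTruth]:
    """Binary trait history with exact bookkeeping of gains and losses.

    Planted mode selects ``k_gains`` disjoint, well-separated clades (greedy,
    largest first, sizes within [clade_min, clade_max], long stems, compact
    crowns), sets them to state 1 and flips ``n_losses`` tips back to 0.
    Loss tips are never siblings of one another, never direct children of a
    gained-clade root, sit on reasonably long terminal branches, and every
    internal node of a gained clade keeps a majority of its tips present, so
    the planted history is the identifiable reading of the tip pattern.
    """
    truth = SimTruth()
    if cfg.trait_mode == "mk":
        states = np.zeros(tree.n_nodes, dtype=np.int64)
        pi1 = cfg.q01 / (cfg.q01 + cfg.q10)
        states[tree.root] = int(rng.random() < pi1)
        gains, losses = [], []
        for v in tree.preorder():
            p = tree.parent[v]
            if p < 0:
                continue
            P = _transition_prob(cfg.q01, cfg.q10, tree.lengths[v])
            states[v] = int(rng.random() < P[states[p], 1])
            if states[p] == 0 and states[v] == 1:
                gains.append(v)
            elif states[p] == 1 and states[v] == 0:
                losses.append(v)
        trait = {tree.labels[i]: int(states[i]) for i in tree.tip_indices()}
        truth.n_gains, truth.n_losses = len(gains), len(losses)
        truth.gain_edges, truth.loss_edges = gains, losses
        truth.node_states = [int(s) for s in states]
        truth.trait = trait
        return trait, truth

    # planted mode: choose well-separated, compact clades on long stems so the
    # planted history is the identifiable reading of the tip pattern
    chosen = _select_planted_clades(tree, cfg)
    loss_tips = _place_planted_losses(tree, chosen, cfg, rng)
    states = np.zeros(tree.n_nodes, dtype=np.int64)
    # mark whole clades, then apply losses
    for v in chosen:
        stack = [v]
        while stack:
            u = stack.pop()
            states[u] = 1
            stack.extend(tree.children[u])
    for tip in loss_tips:
        states[tip] = 0
    trait = {tree.labels[i]: int(states[i]) for i in tree.tip_indices()}
    truth.n_gains, truth.n_losses = len(chosen), len(loss_tips)
    truth.gain_edges = sorted(chosen)
    truth.loss_edges = sorted(loss_tips)
    truth.node_states = [int(s) for s in states]
    truth.trait = trait
    return trait, truth


# ---------------------------------------------------------------------------
# orthogroup matrix
# ---------------------------------------------------------------------------

def sim_matrix(
    tree: PhyloTree,
    trait: dict[str, int],
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Species x family count matrix with background / expanded / xenolog roles.

    Background families: per-family rate lambda_f ~ Gamma(shape, scale), counts
    iid Poisson(lambda_f) across species.  Expanded families multiply the
    Poisson mean by ``multiplier`` in trait-1 species.  Xenolog families are
    present in trait-1 species with probability ``rho`` (count 1 + Poisson)
    and in trait-0 species with probability ``eps``.
    """
    truth = truth or SimTruth()
    species = [tree.labels[i] for i in tree.tip_indices()]
    missing = [s for s in species if s not in trait]
    if missing:
        raise ValueError(f"trait undefined for species {missing[:5]}")
    is_one = np.array([trait[s] == 1 for s in species])
    n_sp = len(species)
    blocks = []
    names = []
    lam_bg = rng.gamma(cfg.gamma_shape, cfg.gamma_scale, size=cfg.n_background)
    blocks.append(rng.poisson(np.broadcast_to(lam_bg, (n_sp, cfg.n_background))))
    names += [f"OG{i:05d}" for i in range(cfg.n_background)]
    lam_exp = rng.gamma(cfg.gamma_shape, cfg.gamma_scale, size=cfg.n_expanded)
    mean_exp = np.where(is_one[:, None], cfg.multiplier * lam_exp, lam_exp)
    blocks.append(rng.poisson(mean_exp))
    exp_names = [f"OG{cfg.n_background + i:05d}" for i in range(cfg.n_expanded)]
    names += exp_names
    xen = np.zeros((n_sp, cfg.n_xenolog), dtype=np.int64)
    for j in range(cfg.n_xenolog):
        pres = np.where(
            is_one,
            rng.random(n_sp) < cfg.rho,
            rng.random(n_sp) < cfg.eps,
        )
        xen[:, j] = np.where(pres, 1 + rng.poisson(cfg.xenolog_extra_mean, n_sp), 0)
    blocks.append(xen)
    xen_names = [
        f"OG{cfg.n_background + cfg.n_expanded + i:05d}" for i in range(cfg.n_xenolog)
    ]
    names += xen_names
    matrix = pd.DataFrame(
        np.hstack(blocks).astype(np.int64), index=species, columns=names
    )
    matrix.index.name = "species"
    truth.expanded_families = exp_names
    truth.xenolog_families = xen_names
    return matrix, truth


def groups_from_trait(trait: dict[str, int]) -> pd.Series:
    """focal = trait-1 (symbiotic) species, other = the rest."""
    return pd.Series(
        {sp: ("focal" if st == 1 else "other") for sp, st in trait.items()}
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _draw_de_stats(status: str, cfg: SimConfig, rng: np.random.Generator):
    if status in ("up", "down"):
        lfc = cfg.lfc_threshold + rng.exponential(cfg.lfc_excess_mean)
        if status == "down":
            lfc = -lfc
        fdr = rng.uniform(0.0, cfg.de_fdr_max)
    else:
        lfc = rng.normal(0.0, cfg.null_lfc_sd)
        fdr = rng.uniform(0.0, 1.0)
    return float(lfc), float(fdr)


def sim_deg(
    matrix: pd.DataFrame,
    trait: dict[str, int],
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: SimTruth | None = None,
    profiled_species: str | None = None,
) -> tuple[pd.DataFrame, dict[str, str], SimTruth]:
    """Per-gene DE table and gene -> family map for one profiled species.

    Genes are instantiated from the profiled species' per-family counts.
    Genes of expanded/xenolog families are differentially expressed with
    probability ``link_prob`` (direction a fair coin per gene); background
    genes with probability ``background_de_prob``.  DE statistics are drawn so
    the thresholds |logFC| > 1.5 and fdr < 0.05 recover the planted status.
    """
    truth = truth or SimTruth()
    if profiled_species is None:
        ones = [s for s in matrix.index if trait.get(s) == 1]
        if not ones:
            raise ValueError("no trait-1 species available to profile")
        profiled_species = ones[0]
    if profiled_species not in matrix.index:
        raise ValueError(f"profiled species {profiled_species!r} absent from matrix")
    candidate = set(truth.expanded_families) | set(truth.xenolog_families)
    counts = matrix.loc[profiled_species]
    rows = []
    gene_to_family: dict[str, str] = {}
    for fam in matrix.columns:
        c = int(counts[fam])
        for i in range(c):
            gene = f"{fam}_g{i + 1}"
            gene_to_family[gene] = fam
            p_de = cfg.link_prob if fam in candidate else cfg.background_de_prob
            if rng.random() < p_de:
                status = "up" if rng.random() < 0.5 else "down"
            else:
                status = "none"
            lfc, fdr = _draw_de_stats(status, cfg, rng)
            truth.gene_status[gene] = status
            rows.append((gene, lfc, fdr * 0.8, fdr))
    table = pd.DataFrame(rows, columns=["gene", "logFC", "pvalue", "fdr"]).set_index(
        "gene"
    )
    return table, gene_to_family, truth


def sim_deg_partition(
    matrix: pd.DataFrame,
    profiled_species: str,
    rng: np.random.Generator,
    n_up: int = 14,
    n_both: int = 7,
    n_down: int = 21,
    cfg: SimConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Engineer a DE table whose family-level partition is exactly
    ``n_up`` up / ``n_both`` both / ``n_down`` down (remaining families none).

    Returns (DegTable, gene -> family map, planted family -> class truth).
    """
    cfg = cfg or SimConfig()
    counts = matrix.loc[profiled_species]
    multi = [f for f in matrix.columns if counts[f] >= 2]
    single = [f for f in matrix.columns if counts[f] >= 1]
    need = n_up + n_both + n_down
    if len(multi) < n_both or len(single) < need:
        raise ValueError("not enough profiled families to engineer the partition")
    both_fams = multi[:n_both]
    rest = [f for f in single if f not in set(both_fams)]
    up_fams = rest[:n_up]
    down_fams = rest[n_up:n_up + n_down]
    if len(down_fams) < n_down:
        raise ValueError("not enough families for the down class")
    family_class = {f: "both" for f in both_fams}
    family_class.update({f: "up" for f in up_fams})
    family_class.update({f: "down" for f in down_fams})
    rows = []
    gene_to_family = {}
    for fam in matrix.columns:
        c = int(counts[fam])
        cls = family_class.get(fam, "none")
        for i in range(c):
            gene = f"{fam}_g{i + 1}"
            gene_to_family[gene] = fam
            if cls == "none":
                status = "none"
            elif cls == "both":
                status = "up" if i == 0 else ("down" if i == 1 else "none")
            else:
                status = cls if i == 0 else "none"
            lfc, fdr = _draw_de_stats(status, cfg, rng)
            if status == "none":
                # keep engineered nulls strictly inside the thresholds
                lfc = float(np.clip(lfc, -cfg.lfc_threshold, cfg.lfc_threshold))
            rows.append((gene, lfc, fdr * 0.8, fdr))
    table = pd.DataFrame(rows, columns=["gene", "logFC", "pvalue", "fdr"]).set_index(
        "gene"
    )
    return table, gene_to_family, family_class


# ---------------------------------------------------------------------------
# HGT evidence fixtures
# ---------------------------------------------------------------------------

def _clade(labels: list[str], blen: float = 1.0) -> str:
    if len(labels) == 1:
        return f"{labels[0]}:{blen}"
    return "(" + ",".join(f"{l}:{blen}" for l in labels) + f"):{blen}"


def sim_hgt_evidence(
    cfg: SimConfig,
    role: str,
    rng: np.random.Generator,
    family: str = "OG_X",
    fixture: str = "clean",
) -> tuple[str, pd.DataFrame, dict]:
    """Gene-tree newick and scaffold fixture for one candidate family.

    ``role="xenolog"`` grafts the algal (candidate) clade inside a bacterial
    clade, with a fungal clade present for rooting; ``role="vertical"`` places
    the candidates as sister to other chlorophytes.  ``fixture="clean"``
    surrounds the candidate gene with host-assigned neighbors on a long
    scaffold; ``fixture="contaminated"`` puts it on a 3-gene scaffold with
    non-host neighbors.
    """
    if role not in ("xenolog", "vertical"):
        raise ValueError(f"role must be xenolog or vertical, got {role!r}")
    if fixture not in ("clean", "contaminated"):
        raise ValueError(f"fixture must be clean or contaminated, got {fixture!r}")
    n_alg = int(rng.integers(2, 5))
    n_bact = int(rng.integers(3, 6))
    n_fung = int(rng.integers(2, 4))
    algae = [f"{family}_alg{i}|lichen_alga" for i in range(1, n_alg + 1)]
    bact = [f"{family}_bac{i}|bacteria" for i in range(1, n_bact + 1)]
    fung = [f"{family}_fun{i}|fungi" for i in range(1, n_fung + 1)]
    if role == "xenolog":
        inner = f"({_clade(algae)},{_clade(bact[:2])}):1"
        rest = bact[2:]
        newick = f"({_clade(fung)},({_clade(rest)},{inner}):1);"
    else:
        chloro = [f"{family}_chl{i}|chlorophyte" for i in range(1, 4)]
        newick = (
            f"({_clade(fung)},({_clade(bact)},"
            f"({_clade(algae)},{_clade(chloro)}):1):1);"
        )

    cand = f"{family}_g1"
    w = cfg.anchoring_window
    rows = []
    if fixture == "clean":
        # lay out 2w+1 genes, candidate in the middle; one neighbor unassigned
        scaf = f"scaf_{family}"
        genes = [f"{family}_nb{i}" for i in range(1, 2 * w + 1)]
        layout = genes[:w] + [cand] + genes[w:]
        unassigned_at = genes[int(rng.integers(0, len(genes)))]
        for i, g in enumerate(layout):
            start = 1000 * (i + 1)
            if g == cand:
                assign = "candidate"
            elif g == unassigned_at:
                assign = "unassigned"
            else:
                assign = "host"
            rows.append((g, scaf, start, start + 800, "+", assign))
    else:
        scaf = f"scaf_{family}_short"
        layout = [f"{family}_nb1", cand, f"{family}_nb2"]
        for i, g in enumerate(layout):
            start = 1000 * (i + 1)
            assign = "non-host" if g != cand else "candidate"
            rows.append((g, scaf, start, start + 800, "+", assign))
    table = pd.DataFrame(
        rows, columns=["gene", "scaffold", "start", "end", "strand", "assignment"]
    )
    table.loc[table["assignment"] == "candidate", "assignment"] = "unassigned"
    truth = {"family": family, "role": role, "fixture": fixture, "candidate_gene": cand}
    return newick, table, truth


def scaffold_table_to_gff(table: pd.DataFrame) -> tuple[str, pd.DataFrame]:
    """Serialize a scaffold fixture as GFF3 text plus the sidecar taxa table."""
    lines = ["##gff-version 3"]
    for _, r in table.iterrows():
        lines.append(
            "\t".join(
                [
                    str(r["scaffold"]), "lichenscan_sim", "gene",
                    str(int(r["start"])), str(int(r["end"])), ".",
                    str(r["strand"]), ".", f"ID={r['gene']}",
                ]
            )
        )
    taxa = table[["gene", "assignment"]].copy()
    return "\n".join(lines) + "\n", taxa


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig, outdir: str | None = None):
    """Generate a complete dataset (and optionally write it to ``outdir``).

    Returns a dict with in-memory objects: tree, trait, groups, matrix, deg,
    gene_to_family, gene_trees (family -> newick), scaffold table, truth.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = sim_tree(cfg.n_species, rng)
    trait, truth = sim_trait(tree, cfg, rng)
    matrix, truth = sim_matrix(tree, trait, cfg, rng, truth)
    groups = groups_from_trait(trait)
    deg, gene_to_family, truth = sim_deg(matrix, trait, cfg, rng, truth)
    gene_trees: dict[str, str] = {}
    scaffold_parts = []
    for fam in truth.xenolog_families:
        nwk, scaf, t = sim_hgt_evidence(cfg, "xenolog", rng, family=fam, fixture="clean")
        gene_trees[fam] = nwk
        scaffold_parts.append(scaf)
        truth.gene_tree_roles[fam] = "xenolog"
        truth.scaffold_roles[t["candidate_gene"]] = "clean"
    for i in range(cfg.n_vertical_controls):
        fam = f"OG{i:05d}"  # background families as vertical controls
        nwk, scaf, t = sim_hgt_evidence(cfg, "vertical", rng, family=fam, fixture="clean")
        gene_trees[fam] = nwk
        scaffold_parts.append(scaf)
        truth.gene_tree_roles[fam] = "vertical"
        truth.scaffold_roles[t["candidate_gene"]] = "clean"
    # one deliberately contaminated fixture for the anchoring check
    nwk, scaf, t = sim_hgt_evidence(
        cfg, "xenolog", rng, family="OG_CONTAM", fixture="contaminated"
    )
    gene_trees["OG_CONTAM"] = nwk
    scaffold_parts.append(scaf)
    truth.gene_tree_roles["OG_CONTAM"] = "xenolog"
    truth.scaffold_roles[t["candidate_gene"]] = "contaminated"
    scaffolds = pd.concat(scaffold_parts, ignore_index=True)

    data = {
        "tree": tree,
        "trait": trait,
        "groups": groups,
        "matrix": matrix,
        "deg": deg,
        "gene_to_family": gene_to_family,
        "gene_trees": gene_trees,
        "scaffolds": scaffolds,
        "truth": truth,
        "config": cfg,
    }
    if outdir is not None:
        _write_dataset(data, outdir)
    return data


def _write_dataset(data, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    tree: PhyloTree = data["tree"]
    write_newick(tree, os.path.join(outdir, "tree.nwk"))
    trait_rows = [(sp, "LAS" if st == 1 else "NSA") for sp, st in sorted(data["trait"].items())]
    pd.DataFrame(trait_rows, columns=["species", "status"]).to_csv(
        os.path.join(outdir, "traits.tsv"), sep="\t", index=False
    )
    data["matrix"].to_csv(os.path.join(outdir, "matrix.tsv"), sep="\t")
    data["groups"].rename("group").rename_axis("species").to_csv(
        os.path.join(outdir, "groups.tsv"), sep="\t"
    )
    data["deg"].to_csv(os.path.join(outdir, "deg.tsv"), sep="\t")
    pd.Series(data["gene_to_family"], name="family").rename_axis("gene").to_csv(
        os.path.join(outdir, "gene2fam.tsv"), sep="\t"
    )
    gt_dir = os.path.join(outdir, "gene_trees")
    os.makedirs(gt_dir, exist_ok=True)
    for fam, nwk in data["gene_trees"].items():
        with open(os.path.join(gt_dir, f"{fam}.nwk"), "w") as fh:
            fh.write(nwk + "\n")
    gff_text, taxa = scaffold_table_to_gff(data["scaffolds"])
    with open(os.path.join(outdir, "genes.gff3"), "w") as fh:
        fh.write(gff_text)
    taxa.to_csv(os.path.join(outdir, "taxa.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(data["truth"].to_json() + "\n")
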