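"""Cross-referencing candidate families with differential expression.

Applies the DE thresholds (FDR < 0.05 and |log2 fold change| > 1.5, strict)
to a synthetic per-gene table for one profiled symbiotic species, aggregates
gene calls to family regulation classes, and triages candidates against
enrichment and phylogenetic flags.
"""

import numpy as np

from lichenscan import SimConfig, call_degs, classify_family_regulation
from lichenscan.deg import triage_candidates
from lichenscan.ortho import enrichment_scan, filter_families
from lichenscan.simulate import (
    groups_from_trait, sim_deg, sim_matrix, sim_trait, sim_tree,
)
from lichenscan.splsda import SplsdaParams, fit_splsda, top_contributors

rng = np.random.default_rng(1)
cfg = SimConfig(seed=1)
tree = sim_tree(cfg.n_species, rng)
trait, truth = sim_trait(tree, cfg, rng)
matrix, truth = sim_matrix(tree, trait, cfg, rng, truth)
groups = groups_from_trait(trait)
deg_table, gene2fam, truth = sim_deg(matrix, trait, cfg, rng, truth)

calls = call_degs(deg_table, fdr_max=0.05, lfc_min=1.5)
print(f"{(calls != 'none').sum()} of {len(calls)} profiled genes are "
      "differentially expressed under the thresholds")

filtered = filter_families(matrix)
model = fit_splsda(filtered, groups, SplsdaParams(n_components=2, keepX=100))
top = top_contributors(model, 0, 100)
g2f = {g: f for g, f in gene2fam.items() if f in set(top)}
reg = classify_family_regulation(calls, g2f, top)
c = reg.counts()
print(f"top-100 family regulation: {c['up']} up, {c['both']} both, "
      f"{c['down']} down, {c['none']} without DE members")

enr = enrichment_scan(filtered, groups, alpha=0.01)
report = triage_candidates(top, enr.table, reg)
print(f"triage: {len(report.retained)} candidates retained "
      f"(statuses: {report.status_counts()})")
planted = set(truth.expanded_families) | set(truth.xenolog_families)
print(f"{len(set(report.retained) & planted)} of the retained candidates are "
      "planted symbiosis-linked families")
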