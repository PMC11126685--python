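"""Differential-expression thresholding and candidate-family triage.

This module consumes per-gene differential-expression statistics (log2 fold
change and FDR-adjusted p-values, as produced by standard count-based DE
tools) and applies fixed thresholds: a gene is called up-regulated iff
``fdr < 0.05 and logFC > 1.5`` and down-regulated iff
``fdr < 0.05 and logFC < -1.5`` (strict inequalities; logFC is log2, so 1.5
corresponds to a ~2.8-fold change).  Gene calls are aggregated to families
through a gene -> family map, and the final triage intersects the
discriminant top-k list with enrichment, regulation and phylogenetic flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "low_count_filter",
    "call_degs",
    "classify_family_regulation",
    "triage_candidates",
    "RegulationCall",
    "CandidateReport",
]


def low_count_filter(
    counts: pd.DataFrame,
    class_map: dict[str, str],
    min_reads: int = 10,
    require_all_classes: bool = False,
) -> list[str]:
    """Drop consistently low-expressed genes.

    ``counts`` is a gene x sample integer table; every sample must belong to a
    class.  Default reading: a gene is retained iff its summed reads reach
    ``min_reads`` in at least one class (i.e. removed only when below the
    threshold in every class).  ``require_all_classes=True`` switches to the
    stricter reading (>= min_reads in all classes).
    """
    missing = [s for s in counts.columns if s not in class_map]
    if missing:
        raise ValueError(f"samples without a class assignment: {missing}")
    classes = sorted(set(class_map[s] for s in counts.columns))
    sums = pd.DataFrame(
        {
            cls: counts[[s for s in counts.columns if class_map[s] == cls]].sum(axis=1)
            for cls in classes
        }
    )
    ok = (sums >= min_reads).all(axis=1) if require_all_classes else (sums >= min_reads).any(axis=1)
    return list(counts.index[ok])


def call_degs(
    table: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 1.5
) -> pd.Series:
    """Per-gene status in {up, down, none} from (logFC, fdr) columns.

    Strict inequalities on both thresholds; genes with missing fdr are skipped
    with a warning.
    """
    required = {"logFC", "fdr"}
    if not required.issubset(table.columns):
        raise ValueError(f"DEG table must have columns {sorted(required)}")
    t = table.copy()
    bad = t.index[t["fdr"].isna()]
    if len(bad):
        warnings.warn(f"skipping {len(bad)} genes with missing fdr", stacklevel=2)
        t = t.drop(index=bad)
    status = pd.Series("none", index=t.index, dtype=object)
    sig = t["fdr"] < fdr_max
    status[sig & (t["logFC"] > lfc_min)] = "up"
    status[sig & (t["logFC"] < -lfc_min)] = "down"
    return status


@dataclass
class RegulationCall:
    classes: dict[str, str]  # family -> up/down/both/none
    genes: dict[str, dict[str, list[str]]]  # family -> status -> gene ids

    def counts(self) -> dict[str, int]:
        out = {"up": 0, "both": 0, "down": 0, "none": 0}
        for cls in self.classes.values():
            out[cls] += 1
        return out


def classify_family_regulation(
    calls: pd.Series,
    gene_to_family: dict[str, str],
    families: list[str],
) -> RegulationCall:
    """Aggregate member-gene DE statuses into a family regulation class.

    ``both`` iff the family has at least one up and one down member; ``none``
    iff it has no differentially expressed member (including families with no
    profiled gene).  Genes mapped to families outside ``families`` are ignored
    with a warning.
    """
    fam_set = set(families)
    unknown = sorted({f for f in gene_to_family.values() if f not in fam_set})
    if unknown:
        warnings.warn(
            f"{len(unknown)} genes map to families outside the candidate list; ignored",
            stacklevel=2,
        )
    genes: dict[str, dict[str, list[str]]] = {
        f: {"up": [], "down": [], "none": []} for f in families
    }
    for gene, status in calls.items():
        fam = gene_to_family.get(gene)
        if fam is None or fam not in fam_set:
            continue
        genes[fam][status].append(gene)
    classes = {}
    for fam in families:
        has_up = bool(genes[fam]["up"])
        has_down = bool(genes[fam]["down"])
        if has_up and has_down:
            classes[fam] = "both"
        elif has_up:
            classes[fam] = "up"
        elif has_down:
            classes[fam] = "down"
        else:
            classes[fam] = "none"
    return RegulationCall(classes=classes, genes=genes)


@dataclass
class CandidateReport:
    table: pd.DataFrame  # ordered by discriminant rank

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "retained"])

    def status_counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()


def triage_candidates(
    top_families: list[str],
    enrichment_table: pd.DataFrame,
    regulation: RegulationCall,
    phylo_flags: dict[str, str] | None = None,
    loadings: dict[str, float] | None = None,
) -> CandidateReport:
    """Synthesize the candidate triage in pipeline order.

    Starting from the discriminant top-k list (in rank order): families not in
    the enrichment-significant set are dropped (``dropped_not_enriched``);
    families with regulation ``none`` are dropped (``dropped_no_expression``);
    families whose phylogenetic flag is ``refuted`` are dropped
    (``dropped_phylogeny``); ``unresolved`` flags leave the family
    ``unresolved``; everything else is ``retained``.  Missing flags default to
    ``supported``.
    """
    phylo_flags = phylo_flags or {}
    universe = set(enrichment_table.index)
    missing = [f for f in top_families if f not in universe]
    if missing:
        raise ValueError(
            f"top families absent from the enrichment universe: {missing[:5]}"
        )
    unknown_reg = [f for f in top_families if f not in regulation.classes]
    if unknown_reg:
        raise ValueError(
            f"top families without a regulation call: {unknown_reg[:5]}"
        )
    rows = []
    for rank, fam in enumerate(top_families, start=1):
        enriched = bool(enrichment_table.loc[fam, "significant"])
        reg = regulation.classes[fam]
        flag = phylo_flags.get(fam, "supported")
        if flag not in ("supported", "refuted", "unresolved"):
            raise ValueError(f"unknown phylogeny flag {flag!r} for {fam}")
        if not enriched:
            status = "dropped_not_enriched"
        elif reg == "none":
            status = "dropped_no_expression"
        elif flag == "refuted":
            status = "dropped_phylogeny"
        elif flag == "unresolved":
            status = "unresolved"
        else:
            status = "retained"
        rows.append(
            (
                fam,
                rank,
                loadings.get(fam, np.nan) if loadings else np.nan,
                float(enrichment_table.loc[fam, "p"]),
                enrichment_table.loc[fam, "direction"],
                reg,
                flag,
                status,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "family",
            "splsda_rank",
            "loading",
            "wilcoxon_p",
            "direction",
            "regulation",
            "phylo_flag",
            "status",
        ],
    ).set_index("family")
    return CandidateReport(table=table)
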