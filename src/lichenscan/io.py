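"""Small text-format helpers shared by the CLI and pipeline stages."""

from __future__ import annotations

import pandas as pd

from .mk import AsrResult
from .tree import PhyloTree

__all__ = ["load_trait", "write_asr_result"]

_TRAIT_CODES = {"LAS": 1, "NSA": 0, "1": 1, "0": 0, 1: 1, 0: 0}


def load_trait(path) -> dict[str, int]:
    """Two-column TSV (species, state); accepted encodings LAS/NSA/1/0."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("trait table must have exactly two columns")
    out: dict[str, int] = {}
    for sp, code in zip(df.iloc[:, 0], df.iloc[:, 1]):
        key = code.strip() if isinstance(code, str) else code
        if key not in _TRAIT_CODES:
            raise ValueError(f"unrecognized trait code {code!r} for species {sp!r}")
        out[str(sp)] = _TRAIT_CODES[key]
    return out


def write_asr_result(asr: AsrResult, tree: PhyloTree, prefix: str) -> None:
    """Export posteriors as TSV and as an annotated newick (posterior labels)."""
    rows = []
    for v in range(tree.n_nodes):
        rows.append(
            (
                v,
                tree.labels[v] or "",
                float(asr.posteriors[v]),
                int(asr.node_states[v]) if asr.node_states is not None else "",
            )
        )
    pd.DataFrame(rows, columns=["node", "label", "posterior_state1", "called_state"]).to_csv(
        f"{prefix}.tsv", sep="\t", index=False
    )
    node_labels = {
        v: format(float(asr.posteriors[v]), ".4f")
        for v in range(tree.n_nodes)
        if not tree.is_tip(v)
    }
    with open(f"{prefix}.nwk", "w") as fh:
        fh.write(tree.to_newick(node_labels=node_labels) + "\n")
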