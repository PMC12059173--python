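"""Bundled gene signatures used throughout the TLS analyses.

The 12-chemokine and TLS-imprint signatures are the published curated lists
commonly used to detect tertiary lymphoid structures in bulk and spatial
transcriptomes; the T-cell-state signatures mark naive, cytotoxic,
proliferating, progenitor-exhausted/Tfh-like and terminally exhausted
states. Lists are bundled verbatim as printed in their source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


_BUNDLED = {
    "chemokine_12": [
        "CCL2", "CCL3", "CCL4", "CCL5", "CCL8", "CCL18", "CCL19", "CCL21",
        "CXCL9", "CXCL10", "CXCL11", "CXCL13",
    ],
    "tls_imprint": [
        "IGHA1", "IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHGP", "IGHM", "IGKC",
        "IGLC1", "IGLC2", "IGLC3", "JCHAIN", "CD79A", "FCRL5", "MZB1", "SSR4",
        "XBP1", "TRBC2", "IL7R", "CXCL12", "LUM", "C1QA", "C7", "CD52",
        "APOE", "PTLP", "PTGDS", "PIM2", "DERL3",
    ],
    "t_naive": ["CCR7", "IL7R", "TCF7"],
    "t_cytotoxicity": ["GZMA", "GZMB", "GZMH", "PRF1", "NKG7", "GNLY"],
    "t_proliferation": ["STMN1", "TUBB", "MKI67"],
    "tex_prog_tfh": ["CXCL13", "TCF7", "PDCD1"],
    "tex_term": ["TOX", "HAVCR2", "CD101", "PDCD1", "LAG3", "CXCL13",
                 "ENTPD1", "TIGIT"],
}


def bundled_gene_sets() -> dict[str, GeneSet]:
    """The seven bundled signatures, keyed by name."""
    return {name: GeneSet(name, frozenset(genes)) for name, genes in _BUNDLED.items()}


def write_gene_sets_json(sets: dict[str, GeneSet], path: str | Path) -> None:
    payload = {name: sorted(gs.genes) for name, gs in sets.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_gene_sets_json(path: str | Path) -> dict[str, GeneSet]:
    payload = json.loads(Path(path).read_text())
    return {name: GeneSet(name, frozenset(genes)) for name, genes in payload.items()}


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        sets[fields[0]] = GeneSet(fields[0], frozenset(fields[2:]))
    return sets


def write_gmt(sets: dict[str, GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + sorted(gs.genes)) for name, gs in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
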