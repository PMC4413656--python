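"""Murine-gene ↔ human-probe-set ortholog mapping.

The map is an explicit input table (TSV with columns ``murine_gene`` and
``human_probe``), many-to-many: one murine gene may map to several human
probe sets and vice versa.  Each mapped human probe is screened
independently downstream (the probe set, not the gene, is the statistical
unit).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = ["OrthologMap", "map_orthologs"]

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """Many-to-many murine gene symbol ↔ human probe set map."""

    gene_to_probes: dict  # murine gene -> sorted list of human probes

    def __post_init__(self):
        for gene, probes in self.gene_to_probes.items():
            if not probes:
                raise ValueError(f"gene {gene!r} maps to no probes")

    @classmethod
    def from_pairs(cls, pairs) -> "OrthologMap":
        mapping: dict = {}
        for gene, probe in pairs:
            mapping.setdefault(str(gene), set()).add(str(probe))
        return cls({g: sorted(ps) for g, ps in sorted(mapping.items())})

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"murine_gene", "human_probe"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"ortholog map {path!r} needs columns {sorted(required)}"
            )
        bad = df.index[df["murine_gene"].isna() | df["human_probe"].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in bad]
            raise ValueError(f"malformed ortholog map rows at lines {lines}")
        return cls.from_pairs(df[["murine_gene", "human_probe"]].itertuples(index=False))

    def to_tsv(self, path) -> None:
        rows = [
            {"murine_gene": g, "human_probe": p}
            for g, probes in self.gene_to_probes.items()
            for p in probes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def probes_for(self, gene: str) -> list:
        return list(self.gene_to_probes.get(gene, []))

    @property
    def genes(self):
        return set(self.gene_to_probes)


def map_orthologs(murine_genes, ortholog_map: OrthologMap):
    """Translate a murine gene set into the union of its human probe sets.

    Returns ``(probes, unmapped)``: the sorted probe union across all mapped
    genes, and the sorted list of genes with no entry in the map (reported,
    never silently dropped).
    """
    probes: set = set()
    unmapped = []
    for gene in murine_genes:
        hits = ortholog_map.probes_for(gene)
        if hits:
            probes.update(hits)
        else:
            unmapped.append(gene)
    if unmapped:
        logger.warning(
            "map_orthologs: %d murine genes without human orthologs: %s",
            len(unmapped), sorted(unmapped),
        )
    return sorted(probes), sorted(unmapped)
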