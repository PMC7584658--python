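"""GENCODE-style gene models and breakpoint annotation.

Breakpoints are annotated with a strict priority: an overlapping coding gene,
else an overlapping lincRNA, else the closest gene for which the position
lies upstream (5′) of its transcription start site on the gene's own strand.
Overlap uses the full gene-body span.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np

from .segio import normalize_chrom


class GtfFormatError(ValueError):
    """A GTF gene feature lacks a required attribute."""


#: GTF biotype → the three-way classification used downstream.
_BIOTYPE_MAP = {"protein_coding": "coding", "lincRNA": "lincRNA",
                "lncRNA": "lincRNA"}


@dataclass(frozen=True)
class GeneModel:
    """Gene-body span with strand-dependent TSS (start if ``+``, end if ``-``)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str  # coding | lincRNA | other

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class Relation(str, enum.Enum):
    WITHIN_CODING = "WITHIN_CODING"
    WITHIN_LINC = "WITHIN_LINC"
    UPSTREAM_OF = "UPSTREAM_OF"
    NONE = "NONE"


@dataclass(frozen=True)
class BreakpointAnnotation:
    """Gene assignment for one breakpoint position.

    ``distance`` is 0 for WITHIN_* relations and, for UPSTREAM_OF, the gap
    from the position to the gene's TSS measured along the gene's reading
    direction.
    """

    position: int
    gene: GeneModel | None
    relation: Relation
    distance: int | None


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Load gene-level features from a GENCODE-dialect GTF.

    Requires ``gene_id`` and a biotype attribute (``gene_type`` or
    ``gene_biotype``); ``gene_name`` falls back to ``gene_id``.  Biotypes map
    protein_coding → coding, lincRNA/lncRNA → lincRNA, everything else →
    other.
    """
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: list[GeneModel] = []
    for i, feat in enumerate(db.features_of_type("gene"), start=1):
        attrs = feat.attributes
        if "gene_id" not in attrs:
            raise GtfFormatError(
                f"gene feature #{i} at {feat.seqid}:{feat.start}-{feat.end}: "
                "missing gene_id attribute")
        raw_biotype = (attrs.get("gene_type") or attrs.get("gene_biotype"))
        if not raw_biotype:
            raise GtfFormatError(
                f"gene feature #{i} at {feat.seqid}:{feat.start}-{feat.end}: "
                "missing gene_type/gene_biotype attribute")
        gene_id = attrs["gene_id"][0]
        genes.append(GeneModel(
            gene_id=gene_id,
            gene_name=attrs.get("gene_name", [gene_id])[0],
            chrom=normalize_chrom(feat.seqid),
            start=int(feat.start), end=int(feat.end),
            strand=feat.strand,
            biotype=_BIOTYPE_MAP.get(raw_biotype[0], "other")))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


class GeneIndex:
    """Per-chromosome vectorized lookup over gene models."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: dict[str, dict] = {}
        grouped: dict[str, list[GeneModel]] = {}
        for g in genes:
            grouped.setdefault(g.chrom, []).append(g)
        for chrom, gs in grouped.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))
            self._by_chrom[chrom] = {
                "genes": gs,
                "start": np.array([g.start for g in gs]),
                "end": np.array([g.end for g in gs]),
                "tss": np.array([g.tss for g in gs]),
                "plus": np.array([g.strand == "+" for g in gs]),
                "coding": np.array([g.biotype == "coding" for g in gs]),
                "linc": np.array([g.biotype == "lincRNA" for g in gs]),
            }

    @property
    def genes(self) -> list[GeneModel]:
        return [g for d in self._by_chrom.values() for g in d["genes"]]

    def overlapping(self, chrom: str, position: int,
                    biotype: str | None = None) -> list[GeneModel]:
        d = self._by_chrom.get(chrom)
        if d is None:
            return []
        mask = (d["start"] <= position) & (d["end"] >= position)
        if biotype == "coding":
            mask &= d["coding"]
        elif biotype == "lincRNA":
            mask &= d["linc"]
        return [d["genes"][i] for i in np.flatnonzero(mask)]

    def nearest_upstream(self, chrom: str, position: int,
                         strand: str | None = None,
                         coding_only: bool = False,
                         max_distance: int | None = None
                         ) -> tuple[GeneModel, int] | None:
        """Nearest gene whose TSS lies downstream of ``position`` along the
        gene's own reading direction (i.e. the position is 5′ of the TSS)."""
        d = self._by_chrom.get(chrom)
        if d is None:
            return None
        dist = np.where(d["plus"], d["tss"] - position, position - d["tss"])
        mask = dist > 0
        if strand is not None:
            mask &= d["plus"] if strand == "+" else ~d["plus"]
        if coding_only:
            mask &= d["coding"]
        if max_distance is not None:
            mask &= dist <= max_distance
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return None
        best = min(idx, key=lambda i: (dist[i], d["genes"][i].gene_id))
        return d["genes"][best], int(dist[best])


def as_gene_index(genes: GeneIndex | Iterable[GeneModel]) -> GeneIndex:
    return genes if isinstance(genes, GeneIndex) else GeneIndex(genes)


def _most_specific(overlaps: list[GeneModel]) -> GeneModel:
    # smallest span, then lexicographic gene_id: deterministic and favors
    # the most specific locus
    return min(overlaps, key=lambda g: (g.span, g.gene_id))


def annotate_breakpoint(position: int, chrom: str,
                        genes: GeneIndex | Iterable[GeneModel]
                        ) -> BreakpointAnnotation:
    """Assign a gene to a breakpoint with the coding > lincRNA > upstream
    priority; no candidate at all gives relation NONE."""
    index = as_gene_index(genes)
    coding = index.overlapping(chrom, position, biotype="coding")
    if coding:
        return BreakpointAnnotation(position, _most_specific(coding),
                                    Relation.WITHIN_CODING, 0)
    linc = index.overlapping(chrom, position, biotype="lincRNA")
    if linc:
        return BreakpointAnnotation(position, _most_specific(linc),
                                    Relation.WITHIN_LINC, 0)
    hit = index.nearest_upstream(chrom, position)
    if hit is not None:
        gene, dist = hit
        return BreakpointAnnotation(position, gene, Relation.UPSTREAM_OF, dist)
    return BreakpointAnnotation(position, None, Relation.NONE, None)
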