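"""Promoter-substitution calling.

For every filtered SV the rearranged junction is oriented and, when a
promoter-bearing 5′ gene fragment is joined to the body (or near-upstream
region) of a second same-strand coding gene, a promoter-substitution (PS)
event is emitted.

Junction geometry.  A deletion of ``[bp1, bp2]`` joins the sequence left of
``bp1`` to the sequence right of ``bp2``; a tandem duplication of
``[bp1, bp2]`` creates a junction joining the segment's end (``bp2``) back to
its start (``bp1``).  In both cases the junction has a genomic "left side"
position and a "right side" position; for plus-strand genes the promoter
donor must sit on the left side and the activated partner on the right, for
minus-strand genes the roles are mirrored.

Only coding genes participate as either partner.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import PipelineConfig
from .gene_annot import (BreakpointAnnotation, GeneIndex, GeneModel, Relation,
                         annotate_breakpoint, as_gene_index)
from .sv_caller import SVCall, SVType


class PSCategory(str, enum.Enum):
    FUSION = "FUSION"
    UPSTREAM = "UPSTREAM"


@dataclass(frozen=True)
class PSEvent:
    """A predicted promoter substitution: the 3′ partner gains the 5′
    partner's promoter, by proper fusion or by upstream juxtaposition."""

    sv: SVCall
    five_prime_gene: GeneModel
    three_prime_gene: GeneModel
    category: PSCategory
    upstream_distance: int = 0

    def __post_init__(self) -> None:
        if self.five_prime_gene.gene_id == self.three_prime_gene.gene_id:
            raise ValueError("5' and 3' partners must differ")
        if self.five_prime_gene.strand != self.three_prime_gene.strand:
            raise ValueError("partners must share a strand")

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.five_prime_gene.gene_id, self.three_prime_gene.gene_id)


def _junction_sides(sv: SVCall,
                    ann1: BreakpointAnnotation,
                    ann2: BreakpointAnnotation):
    """Map (bp1, bp2) onto the junction's genomic left/right side."""
    if sv.sv_type is SVType.DEL:
        return sv.bp1, sv.bp2, ann1, ann2
    return sv.bp2, sv.bp1, ann2, ann1


def detect_ps(sv: SVCall,
              annotation_bp1: BreakpointAnnotation,
              annotation_bp2: BreakpointAnnotation,
              genes: GeneIndex | Iterable[GeneModel],
              config: PipelineConfig | None = None) -> PSEvent | None:
    """Decide whether ``sv`` creates a promoter substitution.

    FUSION: both breakpoints inside coding genes on the same strand; the
    promoter donor is the gene whose TSS-containing portion is retained on
    the junction's transcriptional 5′ side.  UPSTREAM: exactly one breakpoint
    inside a coding gene (with its TSS retained at the junction) and the
    other breakpoint intergenic with a same-strand coding gene no further
    than ``upstream_window`` downstream.  Returns None for everything else.
    """
    cfg = config or PipelineConfig()
    index = as_gene_index(genes)
    left_pos, right_pos, ann_left, ann_right = _junction_sides(
        sv, annotation_bp1, annotation_bp2)
    g_left = (ann_left.gene
              if ann_left.relation is Relation.WITHIN_CODING else None)
    g_right = (ann_right.gene
               if ann_right.relation is Relation.WITHIN_CODING else None)

    if g_left is not None and g_right is not None:
        if g_left.gene_id == g_right.gene_id:
            return None  # internal deletion/duplication of one gene
        if g_left.strand != g_right.strand:
            return None
        if g_left.strand == "+":
            g5, g3, p5 = g_left, g_right, left_pos
        else:
            g5, g3, p5 = g_right, g_left, right_pos
        if not _tss_retained(g5, p5):
            return None
        return PSEvent(sv, g5, g3, PSCategory.FUSION, 0)

    if (g_left is None) == (g_right is None):
        return None  # neither side provides a promoter-bearing fragment

    if g_left is not None:
        donor, donor_pos, target_pos, target_ann = (g_left, left_pos,
                                                    right_pos, ann_right)
        # the promoter fragment left of the junction feeds rightward
        # transcription only
        if donor.strand != "+":
            return None
    else:
        donor, donor_pos, target_pos, target_ann = (g_right, right_pos,
                                                    left_pos, ann_left)
        if donor.strand != "-":
            return None
    if not _tss_retained(donor, donor_pos):
        return None
    if target_ann.relation in (Relation.WITHIN_CODING, Relation.WITHIN_LINC):
        return None
    hit = index.nearest_upstream(sv.chrom, target_pos, strand=donor.strand,
                                 coding_only=True,
                                 max_distance=cfg.upstream_window)
    if hit is None:
        return None
    g3, dist = hit
    if g3.gene_id == donor.gene_id:
        return None
    return PSEvent(sv, donor, g3, PSCategory.UPSTREAM, dist)


def _tss_retained(gene: GeneModel, junction_pos: int) -> bool:
    # the breakpoint must lie between the TSS and the gene's 3' end in
    # reading direction; automatic for a within-body breakpoint, but guards
    # degenerate annotations
    if gene.strand == "+":
        return gene.tss <= junction_pos
    return gene.tss >= junction_pos


def call_ps(svs: Sequence[SVCall],
            genes: GeneIndex | Iterable[GeneModel],
            config: PipelineConfig | None = None) -> list[PSEvent]:
    """Annotate both breakpoints of each SV and run :func:`detect_ps`."""
    cfg = config or PipelineConfig()
    index = as_gene_index(genes)
    events: list[PSEvent] = []
    for sv in svs:
        ann1 = annotate_breakpoint(sv.bp1, sv.chrom, index)
        ann2 = annotate_breakpoint(sv.bp2, sv.chrom, index)
        ev = detect_ps(sv, ann1, ann2, index, cfg)
        if ev is not None:
            events.append(ev)
    return events


# ---------------------------------------------------------------------------
# Recurrence

@dataclass(frozen=True)
class RecurrenceTable:
    """Distinct-sample counts per gene pair, per cancer type and overall."""

    per_type: pd.DataFrame   # pair, gene5, gene3, cancer_type, n_samples
    overall: pd.DataFrame    # pair, gene5, gene3, n_samples, n_cancer_types,
    #                          recurrent

    def recurrent_pairs(self) -> list[str]:
        return list(self.overall.loc[self.overall["recurrent"], "pair"])


def events_to_frame(events: Sequence[PSEvent]) -> pd.DataFrame:
    rows = [{
        "sample": e.sv.sample_id, "cancer_type": e.sv.cancer_type,
        "chrom": e.sv.chrom, "bp1": e.sv.bp1, "bp2": e.sv.bp2,
        "sv_type": e.sv.sv_type.value, "category": e.category.value,
        "gene5_id": e.five_prime_gene.gene_id,
        "gene5": e.five_prime_gene.gene_name,
        "gene3_id": e.three_prime_gene.gene_id,
        "gene3": e.three_prime_gene.gene_name,
        "upstream_distance": e.upstream_distance,
        "pair": f"{e.five_prime_gene.gene_id}::{e.three_prime_gene.gene_id}",
    } for e in events]
    return pd.DataFrame(rows, columns=[
        "sample", "cancer_type", "chrom", "bp1", "bp2", "sv_type", "category",
        "gene5_id", "gene5", "gene3_id", "gene3", "upstream_distance", "pair"])


def write_ps_table(events: Sequence[PSEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def build_recurrence(events: Sequence[PSEvent] | pd.DataFrame,
                     recurrence_min: int = 2) -> RecurrenceTable:
    """Count distinct samples per (pair, cancer type); a pair is recurrent
    iff its overall distinct-sample count reaches ``recurrence_min``."""
    frame = (events if isinstance(events, pd.DataFrame)
             else events_to_frame(list(events)))
    if frame.empty:
        empty_pt = pd.DataFrame(columns=["pair", "gene5", "gene3",
                                         "cancer_type", "n_samples"])
        empty_ov = pd.DataFrame(columns=["pair", "gene5", "gene3",
                                         "n_samples", "n_cancer_types",
                                         "recurrent"])
        return RecurrenceTable(empty_pt, empty_ov)
    per_type = (frame.groupby(["pair", "gene5", "gene3", "cancer_type"],
                              as_index=False)
                .agg(n_samples=("sample", "nunique")))
    overall = (per_type.groupby(["pair", "gene5", "gene3"], as_index=False)
               .agg(n_samples=("n_samples", "sum"),
                    n_cancer_types=("cancer_type", "nunique")))
    overall["recurrent"] = overall["n_samples"] >= recurrence_min
    return RecurrenceTable(per_type, overall)
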