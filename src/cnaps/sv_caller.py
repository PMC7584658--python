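"""SV inference from classified segment runs.

Intrachromosomal deletions and tandem duplications are read off per-sample
state sequences with three rules:

* ``HEMI_RUN``   — a hemizygously deleted segment whose neighbors are both
  not homozygous deletions → DEL;
* ``HOM_IN_HEMI`` — a homozygously deleted segment whose neighbors both exist
  and are both hemizygous deletions → DEL;
* ``GAIN_RUN``   — a gained segment with no amplified neighbor → TDUP.

A missing neighbor (chromosome-terminal segment) satisfies "not HOMDEL" /
"not AMP" but fails "is HEMIDEL".  Calls smaller than ``sv_min_size`` or with
a breakpoint within ``telocent_excl`` of a telomere or centromere are then
removed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .segio import (ClassifiedSegment, CNState, DataError, GenomeRef,
                    SegmentRecord, _check_one_group, classify_segments,
                    filter_gap_adjacent, merge_segments, normalize_chrom)


class SVType(str, enum.Enum):
    DEL = "DEL"
    TDUP = "TDUP"


class CallRule(str, enum.Enum):
    HEMI_RUN = "HEMI_RUN"
    HOM_IN_HEMI = "HOM_IN_HEMI"
    GAIN_RUN = "GAIN_RUN"


@dataclass(frozen=True)
class SVCall:
    """An inferred intrachromosomal SV with ordered breakpoints.

    ``bp1``/``bp2`` are the first and last base of the event segment; SNP-array
    resolution places the true breaks somewhere in the flanking probe gaps.
    """

    sample_id: str
    cancer_type: str
    chrom: str
    bp1: int
    bp2: int
    sv_type: SVType
    rule: CallRule
    source_segments: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.bp1 >= self.bp2:
            raise DataError(f"bp1 must be < bp2 ({self.bp1} >= {self.bp2})")

    @property
    def span(self) -> int:
        return self.bp2 - self.bp1 + 1


def call_svs(segments: Sequence[ClassifiedSegment]) -> list[SVCall]:
    """Apply the three segment-run rules to one sample-chromosome."""
    _check_one_group(segments)
    calls: list[SVCall] = []
    states = [cs.state for cs in segments]
    for i, cs in enumerate(segments):
        left = states[i - 1] if i > 0 else None
        right = states[i + 1] if i < len(segments) - 1 else None
        seg = cs.segment
        call = None
        if cs.state is CNState.HEMIDEL:
            if left is not CNState.HOMDEL and right is not CNState.HOMDEL:
                call = (SVType.DEL, CallRule.HEMI_RUN)
        elif cs.state is CNState.HOMDEL:
            if left is CNState.HEMIDEL and right is CNState.HEMIDEL:
                call = (SVType.DEL, CallRule.HOM_IN_HEMI)
        elif cs.state is CNState.GAIN:
            if left is not CNState.AMP and right is not CNState.AMP:
                call = (SVType.TDUP, CallRule.GAIN_RUN)
        if call is not None and seg.start < seg.end:
            calls.append(SVCall(
                sample_id=seg.sample_id, cancer_type=seg.cancer_type,
                chrom=seg.chrom, bp1=seg.start, bp2=seg.end,
                sv_type=call[0], rule=call[1], source_segments=(i,)))
    return calls


def _near_excluded(bp: int, chrom_len: int, cen_start: int, cen_end: int,
                   excl: int) -> bool:
    if bp - 1 <= excl or chrom_len - bp <= excl:
        return True
    if bp < cen_start:
        dist = cen_start - bp
    elif bp > cen_end:
        dist = bp - cen_end
    else:
        dist = 0
    return dist <= excl


def filter_svs(svs: Sequence[SVCall], genome: GenomeRef,
               config: PipelineConfig | None = None) -> list[SVCall]:
    """Remove SVs smaller than ``sv_min_size`` or with a breakpoint within
    ``telocent_excl`` of a telomere or of the centromere interval."""
    cfg = config or PipelineConfig()
    kept: list[SVCall] = []
    for sv in svs:
        ref = genome.require(sv.chrom)
        if sv.span < cfg.sv_min_size:
            continue
        if any(_near_excluded(bp, ref.length, ref.cen_start, ref.cen_end,
                              cfg.telocent_excl) for bp in (sv.bp1, sv.bp2)):
            continue
        kept.append(sv)
    return kept


def call_svs_cohort(records: Sequence[SegmentRecord], genome: GenomeRef,
                    config: PipelineConfig | None = None) -> list[SVCall]:
    """Full per-sample-chromosome pipeline: classify → merge → gap-filter →
    rule-based calling → size/telomere/centromere filtering."""
    cfg = config or PipelineConfig()
    groups: dict[tuple[str, str], list[SegmentRecord]] = {}
    for r in records:
        groups.setdefault((r.sample_id, r.chrom), []).append(r)
    calls: list[SVCall] = []
    for key in sorted(groups):
        classified = classify_segments(groups[key], cfg)
        merged = merge_segments(classified, cfg)
        clean = filter_gap_adjacent(merged, cfg)
        calls.extend(call_svs(clean))
    return filter_svs(calls, genome, cfg)


def summarize_by_cancer(svs: Iterable[SVCall]) -> pd.DataFrame:
    """Per cancer-type DEL / TDUP counts and their ratio (inf if no TDUP)."""
    frame = svs_to_frame(list(svs))
    if frame.empty:
        return pd.DataFrame(columns=["n_del", "n_tdup", "del_tdup_ratio"])
    counts = (frame.groupby(["cancer_type", "sv_type"]).size()
              .unstack(fill_value=0))
    out = pd.DataFrame({
        "n_del": counts.get("DEL", pd.Series(0, index=counts.index)),
        "n_tdup": counts.get("TDUP", pd.Series(0, index=counts.index)),
    })
    with np.errstate(divide="ignore"):
        out["del_tdup_ratio"] = np.where(
            out["n_tdup"] > 0, out["n_del"] / out["n_tdup"].replace(0, 1),
            np.inf)
    return out


# ---------------------------------------------------------------------------
# Tables

_SV_COLUMNS = ["sample", "cancer_type", "chrom", "bp1", "bp2", "sv_type",
               "rule"]


def svs_to_frame(svs: Sequence[SVCall]) -> pd.DataFrame:
    rows = [{"sample": s.sample_id, "cancer_type": s.cancer_type,
             "chrom": s.chrom, "bp1": s.bp1, "bp2": s.bp2,
             "sv_type": s.sv_type.value, "rule": s.rule.value}
            for s in svs]
    return pd.DataFrame(rows, columns=_SV_COLUMNS)


def write_sv_table(svs: Sequence[SVCall], path: str | Path) -> None:
    svs_to_frame(svs).to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    return [SVCall(sample_id=str(r.sample),
                   cancer_type=str(r.cancer_type),
                   chrom=normalize_chrom(r.chrom),
                   bp1=int(r.bp1), bp2=int(r.bp2),
                   sv_type=SVType(r.sv_type), rule=CallRule(r.rule))
            for r in df.itertuples()]


def write_bedpe(svs: Sequence[SVCall], path: str | Path) -> None:
    """Minimal BEDPE: each breakpoint as a 1 bp half-open interval."""
    rows = [{
        "chrom1": s.chrom, "start1": s.bp1 - 1, "end1": s.bp1,
        "chrom2": s.chrom, "start2": s.bp2 - 1, "end2": s.bp2,
        "name": f"{s.sample_id}:{s.sv_type.value}", "score": ".",
        "strand1": ".", "strand2": ".",
    } for s in svs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
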