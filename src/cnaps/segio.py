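"""SEG-file IO, copy-number state classification, segment merging and
gap-filtering.

Segments are 1-based closed genomic intervals carrying a log2 tumor/normal
copy ratio (``seg_mean``).  The five-state classification, the merging of
nearby same-state segments, and the removal of segments flanking large
no-data regions are the preprocessing contract of the SV caller.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger(__name__)


class SegFormatError(ValueError):
    """A SEG/reference file does not have the expected columns."""


class SegRecordError(ValueError):
    """A single record violates a field invariant."""


class DataError(ValueError):
    """Input data violates an operation precondition."""


class GenomeRefError(ValueError):
    """Genome-reference inconsistency (bad centromere, unknown chromosome)."""


def normalize_chrom(chrom: object) -> str:
    """Strip a leading ``chr`` prefix and surrounding whitespace."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


class CNState(enum.IntEnum):
    """Five discrete copy-number states, totally ordered by copy number."""

    HOMDEL = 0
    HEMIDEL = 1
    NEUTRAL = 2
    GAIN = 3
    AMP = 4


@dataclass(frozen=True)
class SegmentRecord:
    """One row of a segmented copy-number profile (1-based closed interval)."""

    sample_id: str
    cancer_type: str
    chrom: str
    start: int
    end: int
    seg_mean: float
    num_probes: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise SegRecordError("empty chromosome name")
        if self.start > self.end:
            raise SegRecordError(
                f"start > end ({self.start} > {self.end}) on {self.chrom}")
        if not math.isfinite(self.seg_mean):
            raise SegRecordError("seg_mean must be finite")
        if self.num_probes is not None and self.num_probes < 0:
            raise SegRecordError("num_probes must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClassifiedSegment:
    """A segment plus its discrete copy-number state."""

    segment: SegmentRecord
    state: CNState


@dataclass(frozen=True)
class ChromRef:
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.cen_start <= self.cen_end <= self.length):
            raise GenomeRefError(
                f"centromere [{self.cen_start}, {self.cen_end}] outside "
                f"chromosome [1, {self.length}]")


@dataclass(frozen=True)
class GenomeRef:
    """Per-chromosome length and centromere interval.

    Telomeres are implicitly positions 1 and ``length``.
    """

    chroms: Mapping[str, ChromRef]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def require(self, chrom: str) -> ChromRef:
        try:
            return self.chroms[chrom]
        except KeyError:
            raise GenomeRefError(
                f"chromosome {chrom!r} absent from genome reference") from None


# ---------------------------------------------------------------------------
# SEG reading / writing

_COLUMN_ALIASES: dict[str, set[str]] = {
    "sample": {"sample", "id", "sampleid", "samplename", "sampleid"},
    "chrom": {"chromosome", "chrom", "chr"},
    "start": {"start", "locstart", "startposition", "startpos"},
    "end": {"end", "locend", "endposition", "endpos"},
    "num_probes": {"numprobes", "nummark", "nummarkers", "numsnps", "probes",
                   "markers"},
    "seg_mean": {"segmean", "segmentmean", "log2ratio", "log2"},
}
_MANDATORY = ("sample", "chrom", "start", "end", "seg_mean")


def _canon(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for field, aliases in _COLUMN_ALIASES.items():
        for col in columns:
            if _canon(col) in aliases:
                resolved[field] = col
                break
    for field in _MANDATORY:
        if field not in resolved:
            raise SegFormatError(f"missing mandatory column: {field}")
    return resolved


def read_seg(path: str | Path,
             labels: Mapping[str, str] | None = None) -> list[SegmentRecord]:
    """Read a tab-separated SEG file into sorted :class:`SegmentRecord` s.

    Column-name dialects (``Sample``/``ID``, ``Segment_Mean``/``seg.mean`` …)
    are accepted; chromosome names are normalized (no ``chr`` prefix); rows
    with non-finite seg_mean are dropped with a logged count.  ``labels`` maps
    sample id to a cancer-type label (absent samples get ``"NA"``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(list(df.columns))

    seg_mean = pd.to_numeric(df[cols["seg_mean"]], errors="coerce")
    bad = ~seg_mean.apply(math.isfinite)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("read_seg(%s): dropped %d rows with non-finite seg_mean",
                    path, n_dropped)

    records: list[SegmentRecord] = []
    for idx in df.index[~bad]:
        row = df.loc[idx]
        line_no = int(idx) + 2  # 1-based, after the header line
        try:
            start = int(float(row[cols["start"]]))
            end = int(float(row[cols["end"]]))
        except (TypeError, ValueError):
            raise SegRecordError(
                f"{path}, line {line_no}: non-numeric coordinates") from None
        num_probes = None
        if "num_probes" in cols:
            raw = pd.to_numeric(row[cols["num_probes"]], errors="coerce")
            if pd.notna(raw):
                num_probes = int(raw)
        sample = str(row[cols["sample"]]).strip()
        try:
            records.append(SegmentRecord(
                sample_id=sample,
                cancer_type=(labels or {}).get(sample, "NA"),
                chrom=normalize_chrom(row[cols["chrom"]]),
                start=start,
                end=end,
                seg_mean=float(seg_mean.loc[idx]),
                num_probes=num_probes,
            ))
        except SegRecordError as exc:
            raise SegRecordError(f"{path}, line {line_no}: {exc}") from None
    records.sort(key=lambda r: (r.sample_id, _chrom_key(r.chrom), r.start))
    return records


def _chrom_key(chrom: str) -> tuple[int, int | str]:
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def write_seg(records: Iterable[SegmentRecord], path: str | Path) -> None:
    """Write records in the canonical SEG dialect."""
    rows = [{
        "Sample": r.sample_id,
        "Chromosome": r.chrom,
        "Start": r.start,
        "End": r.end,
        "Num_Probes": "" if r.num_probes is None else r.num_probes,
        "Segment_Mean": r.seg_mean,
    } for r in records]
    pd.DataFrame(rows, columns=["Sample", "Chromosome", "Start", "End",
                                "Num_Probes", "Segment_Mean"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# State classification

def classify_state(seg_mean: float,
                   config: PipelineConfig | None = None) -> CNState:
    """Map a log2 ratio onto one of the five copy-number states.

    With default thresholds: HOMDEL iff x < −1; HEMIDEL iff −1 ≤ x < −0.2;
    NEUTRAL iff −0.2 ≤ x < 0.3; GAIN iff 0.3 ≤ x < 0.7; AMP iff x ≥ 0.7.
    """
    if not math.isfinite(seg_mean):
        raise ValueError("seg_mean must be finite")
    cfg = config or PipelineConfig()
    if seg_mean < cfg.homdel_max:
        return CNState.HOMDEL
    if seg_mean < cfg.hemidel_max:
        return CNState.HEMIDEL
    if seg_mean < cfg.neutral_max:
        return CNState.NEUTRAL
    if seg_mean < cfg.gain_max:
        return CNState.GAIN
    return CNState.AMP


def classify_segments(records: Iterable[SegmentRecord],
                      config: PipelineConfig | None = None
                      ) -> list[ClassifiedSegment]:
    cfg = config or PipelineConfig()
    return [ClassifiedSegment(r, classify_state(r.seg_mean, cfg))
            for r in records]


# ---------------------------------------------------------------------------
# Merging and gap-filtering (one sample-chromosome at a time)

def _check_one_group(segments: Sequence[ClassifiedSegment]) -> None:
    keys = {(cs.segment.sample_id, cs.segment.chrom) for cs in segments}
    if len(keys) > 1:
        raise DataError(f"segments span multiple sample-chromosomes: {keys}")
    for prev, nxt in zip(segments, segments[1:]):
        if nxt.segment.start < prev.segment.start:
            raise DataError("segments are not sorted by start")
        if nxt.segment.start <= prev.segment.end:
            raise DataError(
                f"overlapping segments at {prev.segment.chrom}:"
                f"{nxt.segment.start} <= {prev.segment.end}")


def merge_segments(segments: Sequence[ClassifiedSegment],
                   config: PipelineConfig | None = None
                   ) -> list[ClassifiedSegment]:
    """Merge consecutive same-state segments separated by small gaps.

    Two consecutive segments with the same state and an intervening gap of
    fewer than ``merge_gap_max`` bases become one segment spanning both; the
    merged seg_mean is the probe-count-weighted mean (unweighted when any
    probe count is absent).  Idempotent.
    """
    cfg = config or PipelineConfig()
    _check_one_group(segments)
    if not segments:
        return []
    out: list[ClassifiedSegment] = []
    # running accumulator for the current merged segment
    cur = segments[0]
    members = [cur.segment]
    for nxt in segments[1:]:
        gap = nxt.segment.start - members[-1].end - 1
        if nxt.state == cur.state and gap < cfg.merge_gap_max:
            members.append(nxt.segment)
        else:
            out.append(_combine(members, cur.state))
            cur = nxt
            members = [nxt.segment]
    out.append(_combine(members, cur.state))
    return out


def _combine(members: list[SegmentRecord], state: CNState) -> ClassifiedSegment:
    if len(members) == 1:
        return ClassifiedSegment(members[0], state)
    have_probes = all(m.num_probes is not None for m in members)
    weights = [float(m.num_probes) if have_probes else 1.0 for m in members]
    total = sum(weights) or float(len(members))
    mean = sum(w * m.seg_mean for w, m in zip(weights, members)) / total
    merged = replace(members[0], end=members[-1].end, seg_mean=mean,
                     num_probes=sum(m.num_probes for m in members)
                     if have_probes else None)
    return ClassifiedSegment(merged, state)


def filter_gap_adjacent(segments: Sequence[ClassifiedSegment],
                        config: PipelineConfig | None = None
                        ) -> list[ClassifiedSegment]:
    """Drop segments immediately flanking a no-data region > ``nodata_gap_min``.

    A no-data region is the interval between consecutive segment records;
    chromosome ends do not count.  A gap of exactly the threshold is kept.
    """
    cfg = config or PipelineConfig()
    _check_one_group(segments)
    drop: set[int] = set()
    for i in range(len(segments) - 1):
        gap = segments[i + 1].segment.start - segments[i].segment.end - 1
        if gap > cfg.nodata_gap_min:
            drop.update((i, i + 1))
    return [cs for i, cs in enumerate(segments) if i not in drop]


# ---------------------------------------------------------------------------
# Genome reference

_REF_COLUMNS = ("chrom", "length", "cen_start", "cen_end")


def read_genome_ref(path: str | Path) -> GenomeRef:
    """Read a BED-like TSV (chrom, length, cen_start, cen_end)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REF_COLUMNS if c not in df.columns]
    if missing:
        raise SegFormatError(f"genome reference missing columns: {missing}")
    chroms = {
        normalize_chrom(row.chrom): ChromRef(int(row.length),
                                             int(row.cen_start),
                                             int(row.cen_end))
        for row in df.itertuples()
    }
    return GenomeRef(chroms)


def write_genome_ref(genome: GenomeRef, path: str | Path) -> None:
    rows = [{"chrom": c, "length": r.length, "cen_start": r.cen_start,
             "cen_end": r.cen_end} for c, r in genome.chroms.items()]
    pd.DataFrame(rows, columns=list(_REF_COLUMNS)).to_csv(
        path, sep="\t", index=False)
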