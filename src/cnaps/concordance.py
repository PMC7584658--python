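"""Concordance of CNA-inferred SVs with an external (WGS-derived) call set.

A CNA call matches a WGS call of the same sample and chromosome when both
breakpoints agree within ``wgs_match_tol`` (default strategy) or when the
two intervals reciprocally overlap.  Assignment is greedy one-to-one by
smallest total breakpoint offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import PipelineConfig
from .segio import DataError, normalize_chrom
from .sv_caller import SVCall, svs_to_frame

#: aliases for duplication-type labels in external call sets
_TYPE_ALIASES = {"DUP": "TDUP", "TANDEM_DUP": "TDUP", "TANDEMDUP": "TDUP"}


@dataclass(frozen=True)
class SVMatch:
    cna_index: int
    wgs_index: int
    bp1_offset: int
    bp2_offset: int
    coherent: bool


def read_wgs_sv(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample, chrom, bp1, bp2, type."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "bp1", "bp2", "type"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"WGS SV table missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["bp1"] >= df["bp2"]).any():
        raise DataError("WGS SVs must have bp1 < bp2")
    return df


def _as_frame(svs) -> pd.DataFrame:
    if isinstance(svs, pd.DataFrame):
        df = svs.copy()
        if "type" in df.columns and "sv_type" not in df.columns:
            df = df.rename(columns={"type": "sv_type"})
        return df
    return svs_to_frame(list(svs))


def match_svs(cna_svs: Sequence[SVCall] | pd.DataFrame,
              wgs_svs: pd.DataFrame,
              config: PipelineConfig | None = None,
              strategy: str = "breakpoint",
              min_reciprocal: float = 0.5
              ) -> tuple[list[SVMatch], dict]:
    """Match CNA SVs against WGS SVs; report correspondence and coherence.

    Returns the match list and a summary with the fraction of CNA calls
    matched and the fraction of matched calls with the same DEL/TDUP class.
    """
    cfg = config or PipelineConfig()
    cna = _as_frame(cna_svs).reset_index(drop=True)
    wgs = wgs_svs.reset_index(drop=True)
    candidates = []
    if not cna.empty and not wgs.empty:
        merged = cna.reset_index().merge(
            wgs.reset_index(), on=["sample", "chrom"],
            suffixes=("_cna", "_wgs"))
        for row in merged.itertuples():
            d1 = abs(int(row.bp1_cna) - int(row.bp1_wgs))
            d2 = abs(int(row.bp2_cna) - int(row.bp2_wgs))
            if strategy == "breakpoint":
                ok = d1 <= cfg.wgs_match_tol and d2 <= cfg.wgs_match_tol
            elif strategy == "reciprocal":
                inter = (min(row.bp2_cna, row.bp2_wgs)
                         - max(row.bp1_cna, row.bp1_wgs) + 1)
                len_c = row.bp2_cna - row.bp1_cna + 1
                len_w = row.bp2_wgs - row.bp1_wgs + 1
                ok = (inter > 0 and inter / len_c >= min_reciprocal
                      and inter / len_w >= min_reciprocal)
            else:
                raise ValueError(f"unknown strategy {strategy!r}")
            if ok:
                wtype = _TYPE_ALIASES.get(str(row.type).upper(),
                                          str(row.type).upper())
                candidates.append((d1 + d2, int(row.index_wgs),
                                   int(row.index_cna), d1, d2,
                                   str(row.sv_type) == wtype))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_cna: set[int] = set()
    used_wgs: set[int] = set()
    matches: list[SVMatch] = []
    for total, wi, ci, d1, d2, coherent in candidates:
        if ci in used_cna or wi in used_wgs:
            continue
        used_cna.add(ci)
        used_wgs.add(wi)
        matches.append(SVMatch(ci, wi, d1, d2, coherent))
    n_cna = len(cna)
    n_matched = len(matches)
    n_coherent = sum(m.coherent for m in matches)
    summary = {
        "n_cna": n_cna,
        "n_wgs": len(wgs),
        "n_matched": n_matched,
        "fraction_matched": n_matched / n_cna if n_cna else 0.0,
        "fraction_coherent": n_coherent / n_matched if n_matched else None,
    }
    return matches, summary
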