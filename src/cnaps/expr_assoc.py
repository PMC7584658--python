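"""Expression association of promoter-substitution events.

Promoter strength is proxied by a gene's median expression among unaffected
samples of the same cancer type; induction of the 3′ partner is the log2
difference of each affected sample to that unaffected median.  Two screens
are implemented: a global Fisher test of "stronger promoter" vs "3′ partner
induced" over all PS events, and a recurrent-pair significance screen
(pooled-variance t-test, Benjamini–Hochberg FDR).

All fold changes and tests operate on log2(x + 1) unless noted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .ps_caller import PSEvent, events_to_frame
from .segio import DataError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix of non-negative linear expression values with a
    per-sample cancer-type label."""

    values: pd.DataFrame   # rows: genes; columns: samples (linear scale)
    labels: pd.Series      # sample -> cancer type

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise DataError("expression values must be finite and >= 0")
        unlabeled = self.values.columns.difference(self.labels.index)
        if len(unlabeled):
            logger.info("dropping %d samples without cancer-type labels",
                        len(unlabeled))
            self.values = self.values.drop(columns=unlabeled)
        self.labels = self.labels.reindex(self.values.columns)

    @classmethod
    def from_tsv(cls, expr_path: str | Path,
                 labels_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        labels = pd.Series(lab.iloc[:, 1].values, index=lab.iloc[:, 0].values)
        return cls(values, labels)

    def to_tsv(self, expr_path: str | Path, labels_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t")
        self.labels.rename_axis("sample").rename("cancer_type").to_frame() \
            .to_csv(labels_path, sep="\t")

    def samples_of(self, cancer_type: str) -> list[str]:
        return list(self.labels.index[self.labels == cancer_type])

    def log2p(self, gene: str, samples: Sequence[str]) -> np.ndarray:
        return np.log2(self.values.loc[gene, list(samples)].to_numpy(
            dtype=float) + 1.0)


def _unaffected(expr: ExpressionMatrix, cancer_type: str,
                affected: Sequence[str]) -> list[str]:
    aff = set(affected)
    return [s for s in expr.samples_of(cancer_type) if s not in aff]


def promoter_strength_diff(gene5: str, gene3: str, cancer_type: str,
                           expr: ExpressionMatrix,
                           affected: Sequence[str] = ()) -> float:
    """log2(median5 + 1) − log2(median3 + 1) over unaffected samples of the
    cancer type.  ≥ 1 means the 5′ promoter is at least 2-fold stronger."""
    unaff = _unaffected(expr, cancer_type, affected)
    if not unaff:
        raise DataError(f"no unaffected samples in {cancer_type}")
    med5 = float(np.median(expr.values.loc[gene5, unaff]))
    med3 = float(np.median(expr.values.loc[gene3, unaff]))
    return math.log2(med5 + 1.0) - math.log2(med3 + 1.0)


def induction_fc(gene3: str, affected: Sequence[str], cancer_type: str,
                 expr: ExpressionMatrix) -> np.ndarray:
    """Per-affected-sample log2(x + 1) difference of the 3′ partner to the
    median of the unaffected samples of the same cancer type."""
    unaff = _unaffected(expr, cancer_type, affected)
    if not unaff:
        raise DataError(f"no unaffected samples in {cancer_type}")
    med = float(np.median(expr.values.loc[gene3, unaff]))
    return expr.log2p(gene3, affected) - math.log2(med + 1.0)


# ---------------------------------------------------------------------------
# Event-level strength / induction table and the global Fisher test

def _as_events_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events
    return events_to_frame(list(events))


def strength_induction_frame(events: Iterable[PSEvent] | pd.DataFrame,
                             expr: ExpressionMatrix) -> pd.DataFrame:
    """One row per (pair, cancer type): promoter_diff, mean induction and the
    affected-sample count.  Pairs whose genes are missing from the matrix are
    excluded with a logged count."""
    frame = _as_events_frame(events)
    rows = []
    n_missing = 0
    for (pair, ct), grp in frame.groupby(["pair", "cancer_type"]):
        g5, g3 = grp["gene5"].iloc[0], grp["gene3"].iloc[0]
        affected = [s for s in grp["sample"].unique()
                    if s in expr.values.columns]
        if (g5 not in expr.values.index or g3 not in expr.values.index
                or not affected):
            n_missing += 1
            continue
        pdiff = promoter_strength_diff(g5, g3, ct, expr, affected)
        ind = induction_fc(g3, affected, ct, expr)
        rows.append({"pair": pair, "cancer_type": ct, "gene5": g5,
                     "gene3": g3, "n_affected": len(affected),
                     "promoter_diff": pdiff,
                     "mean_induction": float(np.mean(ind))})
    if n_missing:
        logger.info("excluded %d pairs not resolvable in the expression "
                    "matrix", n_missing)
    return pd.DataFrame(rows, columns=["pair", "cancer_type", "gene5",
                                       "gene3", "n_affected", "promoter_diff",
                                       "mean_induction"])


@dataclass(frozen=True)
class FisherTable:
    """2×2 stronger-promoter × induced counts with Fisher's exact test."""

    table: np.ndarray      # rows: stronger yes/no, cols: induced yes/no
    odds_ratio: float
    p_value: float
    n_events: int


def fisher_table_from_flags(stronger: np.ndarray,
                            induced: np.ndarray) -> FisherTable:
    stronger = np.asarray(stronger, dtype=bool)
    induced = np.asarray(induced, dtype=bool)
    table = np.array([
        [int(np.sum(stronger & induced)), int(np.sum(stronger & ~induced))],
        [int(np.sum(~stronger & induced)), int(np.sum(~stronger & ~induced))],
    ])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate 2x2 table (empty margin); p set to 1")
        return FisherTable(table, float("nan"), 1.0, int(table.sum()))
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherTable(table, float(odds), float(p), int(table.sum()))


def fisher_strength_vs_induction(events: Iterable[PSEvent] | pd.DataFrame,
                                 expr: ExpressionMatrix,
                                 strength_cut: float = 0.0,
                                 induction_cut: float = 0.0) -> FisherTable:
    """Dichotomize every PS event at the cut points (default 0 on both axes)
    and run a two-sided Fisher's exact test on the 2×2."""
    si = strength_induction_frame(events, expr)
    return fisher_table_from_flags(si["promoter_diff"] > strength_cut,
                                   si["mean_induction"] > induction_cut)


# ---------------------------------------------------------------------------
# Recurrent-pair screen

def screen_recurrent(events: Iterable[PSEvent] | pd.DataFrame,
                     expr: ExpressionMatrix,
                     config: PipelineConfig | None = None,
                     welch: bool = False,
                     log_scale: bool = True) -> pd.DataFrame:
    """Significance screen over recurrently affected pairs with a stronger
    promoter.

    Candidates are (pair, cancer type) combinations with at least
    ``recurrence_min`` distinct affected samples and a promoter-strength
    difference of at least log2(``stronger_promoter_fold``).  Per candidate a
    two-sided pooled-variance t-test (Welch behind the flag) compares the 3′
    partner's log2(x+1) expression in affected vs unaffected samples; BH
    step-up is applied across the candidate set and candidates with
    q ≤ ``fdr_level`` are flagged significant.  Degenerate candidates
    (fewer than two affected samples or zero variance in both groups) keep
    p = 1 with ``degenerate=True``.
    """
    cfg = config or PipelineConfig()
    frame = _as_events_frame(events)
    gate = math.log2(cfg.stronger_promoter_fold)
    rows = []
    n_excluded = 0
    for (pair, ct), grp in frame.groupby(["pair", "cancer_type"]):
        g5, g3 = grp["gene5"].iloc[0], grp["gene3"].iloc[0]
        affected = sorted(s for s in set(grp["sample"])
                          if s in expr.values.columns)
        if len(affected) < cfg.recurrence_min:
            continue
        if g5 not in expr.values.index or g3 not in expr.values.index:
            n_excluded += 1
            continue
        unaff = _unaffected(expr, ct, affected)
        if not unaff:
            n_excluded += 1
            continue
        pdiff = promoter_strength_diff(g5, g3, ct, expr, affected)
        if pdiff < gate:
            continue
        if log_scale:
            a = expr.log2p(g3, affected)
            u = expr.log2p(g3, unaff)
        else:
            a = expr.values.loc[g3, affected].to_numpy(dtype=float)
            u = expr.values.loc[g3, unaff].to_numpy(dtype=float)
        induction = induction_fc(g3, affected, ct, expr)
        degenerate = (len(affected) < 2
                      or (np.ptp(a) == 0.0 and np.ptp(u) == 0.0))
        if degenerate:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, u, equal_var=not welch).pvalue)
            if not math.isfinite(p):
                p, degenerate = 1.0, True
        rows.append({"pair": pair, "cancer_type": ct, "gene5": g5,
                     "gene3": g3, "n_affected": len(affected),
                     "promoter_diff": pdiff,
                     "mean_induction": float(np.mean(induction)),
                     "p_value": p, "degenerate": degenerate})
    if n_excluded:
        logger.info("screen_recurrent: excluded %d candidates not resolvable "
                    "in the expression matrix", n_excluded)
    out = pd.DataFrame(rows, columns=["pair", "cancer_type", "gene5", "gene3",
                                      "n_affected", "promoter_diff",
                                      "mean_induction", "p_value",
                                      "degenerate"])
    if out.empty:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] <= cfg.fdr_level
    return out.sort_values(["p_value", "pair"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Statistical kernels

def ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration when both groups have
    at most 10 observations and no ties, normal approximation with tie
    correction otherwise; all-tied input gives p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10
                         and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def wilcoxon_case(gene: str, affected_samples: Sequence[str],
                  cancer_type: str, expr: ExpressionMatrix) -> float:
    """Rank-sum test of a gene's log2(x+1) expression, affected vs the other
    samples of the cancer type."""
    others = _unaffected(expr, cancer_type, affected_samples)
    return ranksum_p(expr.log2p(gene, affected_samples),
                     expr.log2p(gene, others))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
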