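"""Synthetic cohorts with a truth ledger.

The generator emulates the pipeline's four inputs at desk scale: a toy
genome reference, a gene annotation, per-sample segmented copy-number
profiles derived from planted integer copy numbers under a purity/noise
model, and an expression matrix with planted 3′-partner induction.

Amplitude model: a segment of tumor copy number ``CN`` observed at purity
``p`` has expected ``seg_mean = log2((p·CN + (1−p)·2) / 2)``; Gaussian noise
(log2 units) is added per emitted segment and the result floored at the
amplitude floor.  Segment boundaries are jittered uniformly within ± one
probe spacing to stand in for probe-grid discretization.  Ploidy is fixed
at 2; purity is the only confounder modeled.

Two light-weight generators (:func:`simulate_screen`,
:func:`simulate_coupled_events`) produce expression-only cohorts for the
statistics of the screen without the DNA layer.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr_assoc import ExpressionMatrix
from .gene_annot import GeneModel
from .segio import (ChromRef, GenomeRef, SegmentRecord, write_genome_ref,
                    write_seg)

#: distance kept between planted events and chromosome ends / centromeres,
#: slightly wider than the pipeline's 2 Mb exclusion zone
_SAFE_MARGIN = 2_500_000
#: minimum separation between planted events of one sample, wider than the
#: default merge gap so calls never coalesce
_EVENT_PAD = 200_000

_BIOTYPE_GTF = {"coding": "protein_coding", "lincRNA": "lincRNA",
                "other": "misc_RNA"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic cohort.

    A fixed seed yields byte-identical outputs.  ``purity`` is either a
    scalar applied to every sample or a mapping sample → purity.
    """

    seed: int = 0
    cancer_types: tuple[str, ...] = ("CA", "CB", "CC")
    n_samples: int = 30                      # per cancer type
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"1": 100_000_000, "2": 100_000_000,
                                 "3": 100_000_000})
    centromere_fraction: tuple[float, float] = (0.45, 0.50)
    n_genes_per_chrom: int = 60
    gene_length_range: tuple[int, int] = (30_000, 200_000)
    intergenic_mean: int = 250_000
    coding_fraction: float = 0.8
    linc_fraction: float = 0.1
    probe_spacing: int = 2_000
    purity: float | Mapping[str, float] = 0.6
    noise_sd: float = 0.1                    # log2 units per segment
    sv_rate: float = 3.0                     # mean background SVs per sample
    sv_size_range: tuple[int, int] = (50_000, 2_000_000)  # log-uniform
    del_fraction: float = 0.5
    nested_homdel_prob: float = 0.1
    extra_breakpoint_rate: float = 2.0       # spurious boundaries per chrom
    n_ps_pairs: int = 4
    ps_affected_per_pair: int = 4
    ps_fold: float = 8.0                     # linear induction of 3' partner
    ps_promoter_ratio: float = 4.0           # 5' vs 3' baseline (linear)
    expr_mu_range: tuple[float, float] = (3.0, 9.0)   # log2 baseline
    expr_sd: float = 0.5                     # log2 units
    amplitude_floor: float = -8.0

    def __post_init__(self) -> None:
        purities = ([self.purity] if isinstance(self.purity, (int, float))
                    else list(self.purity.values()))
        if any(not 0 < p <= 1 for p in purities):
            raise ValueError("purity must lie in (0, 1]")
        if self.noise_sd < 0 or self.expr_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.ps_fold <= 0:
            raise ValueError("ps_fold must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Planted events grounding parameter-recovery tests."""

    svs: pd.DataFrame        # sample, cancer_type, chrom, bp1, bp2, type, cn
    ps_events: pd.DataFrame  # sample, cancer_type, pair, gene5, gene3,
    #                          chrom, bp1, bp2, fold
    purity: pd.Series        # sample -> purity


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimConfig
    truth: SimTruth
    segments: list[SegmentRecord]
    genes: list[GeneModel]
    genome: GenomeRef
    expression: ExpressionMatrix
    labels: dict[str, str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit exactly the formats the pipeline consumes."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "seg": out / "cohort.seg", "gtf": out / "genes.gtf",
            "genome": out / "genome.tsv", "expr": out / "expression.tsv",
            "labels": out / "labels.tsv", "truth_svs": out / "truth_svs.tsv",
            "truth_ps": out / "truth_ps.tsv",
        }
        write_seg(self.segments, paths["seg"])
        write_gtf(self.genes, paths["gtf"])
        write_genome_ref(self.genome, paths["genome"])
        self.expression.to_tsv(paths["expr"], paths["labels"])
        self.truth.svs.to_csv(paths["truth_svs"], sep="\t", index=False)
        self.truth.ps_events.to_csv(paths["truth_ps"], sep="\t", index=False)
        return paths


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = []
    for g in genes:
        attrs = (f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                 f'gene_type "{_BIOTYPE_GTF[g.biotype]}";')
        lines.append(f"chr{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}"
                     f"\t.\t{g.strand}\t.\t{attrs}")
    Path(path).write_text("\n".join(lines) + "\n")


def expected_seg_mean(cn: int, purity: float, floor: float = -8.0) -> float:
    """Closed-form purity-mixture amplitude, floored."""
    mixture = (purity * cn + (1.0 - purity) * 2.0) / 2.0
    if mixture <= 0:
        return floor
    return max(math.log2(mixture), floor)


# ---------------------------------------------------------------------------
# genome / gene layout

def _make_genome(cfg: SimConfig) -> GenomeRef:
    lo, hi = cfg.centromere_fraction
    return GenomeRef({
        chrom: ChromRef(length, int(length * lo) + 1, int(length * hi))
        for chrom, length in cfg.chrom_lengths.items()})


def _arms(ref: ChromRef) -> list[tuple[int, int]]:
    return [(1 + _SAFE_MARGIN, ref.cen_start - _SAFE_MARGIN),
            (ref.cen_end + _SAFE_MARGIN, ref.length - _SAFE_MARGIN)]


def _make_genes(cfg: SimConfig, genome: GenomeRef,
                rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    counter = 0
    for chrom in sorted(genome.chroms, key=str):
        ref = genome.chroms[chrom]
        placed = 0
        for arm_start, arm_end in _arms(ref):
            pos = arm_start
            while placed < cfg.n_genes_per_chrom:
                gap = int(rng.exponential(cfg.intergenic_mean)) + 5_000
                start = pos + gap
                length = int(rng.integers(*cfg.gene_length_range))
                end = start + length - 1
                if end > arm_end:
                    break
                counter += 1
                u = rng.random()
                if u < cfg.coding_fraction:
                    biotype = "coding"
                elif u < cfg.coding_fraction + cfg.linc_fraction:
                    biotype = "lincRNA"
                else:
                    biotype = "other"
                gid = f"SYN{counter:04d}"
                genes.append(GeneModel(
                    gene_id=gid, gene_name=gid, chrom=chrom,
                    start=start, end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=biotype))
                pos = end
                placed += 1
    return genes


# ---------------------------------------------------------------------------
# event planting

def _plan_ps_pairs(cfg: SimConfig, genes: Sequence[GeneModel],
                   rng: np.random.Generator) -> list[dict]:
    """Pick disjoint consecutive same-strand coding gene pairs and a fixed
    deletion fusing them (bp1 inside the left gene, bp2 inside the right)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.biotype == "coding":
            by_chrom.setdefault(g.chrom, []).append(g)
    candidates = []
    for chrom, gs in sorted(by_chrom.items()):
        gs.sort(key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            gap = b.start - a.end - 1
            if a.strand == b.strand and 50_000 <= gap <= 800_000:
                candidates.append((a, b))
    plans: list[dict] = []
    used_regions: list[tuple[str, int, int]] = []
    order = rng.permutation(len(candidates))
    for idx in order:
        if len(plans) >= cfg.n_ps_pairs:
            break
        a, b = candidates[idx]
        region = (a.chrom, a.start - 1_000_000, b.end + 1_000_000)
        if any(c == region[0] and s <= region[2] and region[1] <= e
               for c, s, e in used_regions):
            continue
        bp1 = int(rng.integers(a.start + 2_000, a.end - 2_000))
        bp2 = int(rng.integers(b.start + 2_000, b.end - 2_000))
        g5, g3 = (a, b) if a.strand == "+" else (b, a)
        plans.append({"chrom": a.chrom, "bp1": bp1, "bp2": bp2,
                      "gene5": g5.gene_id, "gene3": g3.gene_id})
        used_regions.append(region)
    return plans


def _place_background_sv(cfg: SimConfig, genome: GenomeRef,
                         taken: list[tuple[str, int, int]],
                         rng: np.random.Generator) -> dict | None:
    chroms = sorted(genome.chroms, key=str)
    for _ in range(30):
        chrom = chroms[int(rng.integers(len(chroms)))]
        ref = genome.chroms[chrom]
        arm = _arms(ref)[int(rng.integers(2))]
        lo, hi = cfg.sv_size_range
        size = int(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        if arm[1] - arm[0] <= size + 2:
            continue
        start = int(rng.integers(arm[0], arm[1] - size))
        end = start + size - 1
        if any(c == chrom and s - _EVENT_PAD <= end and start <= e + _EVENT_PAD
               for c, s, e in taken):
            continue
        sv_type = "DEL" if rng.random() < cfg.del_fraction else "TDUP"
        return {"chrom": chrom, "bp1": start, "bp2": end, "type": sv_type}
    return None


# ---------------------------------------------------------------------------
# cohort assembly

def simulate_cohort(config: SimConfig | None = None,
                    outdir: str | Path | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort plus its truth ledger.

    Deletions set the tumor copy number 2→1 (with an optional nested 1→0
    core), tandem duplications 2→3.  Planted events sit outside the
    telomere/centromere exclusion zones and never overlap within a sample.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genome = _make_genome(cfg)
    genes = _make_genes(cfg, genome, rng)
    gene_by_id = {g.gene_id: g for g in genes}

    samples = [f"{ct}-S{i:03d}" for ct in cfg.cancer_types
               for i in range(cfg.n_samples)]
    labels = {s: s.split("-")[0] for s in samples}
    if isinstance(cfg.purity, (int, float)):
        purity = {s: float(cfg.purity) for s in samples}
    else:
        purity = {s: float(cfg.purity[s]) for s in samples}

    # planted promoter-substitution deletions (recurrent per cancer type)
    ps_plans = _plan_ps_pairs(cfg, genes, rng)
    sv_rows: list[dict] = []
    ps_rows: list[dict] = []
    events_by_sample: dict[str, list[dict]] = {s: [] for s in samples}
    for i, plan in enumerate(ps_plans):
        ct = cfg.cancer_types[i % len(cfg.cancer_types)]
        pool = [s for s in samples if labels[s] == ct]
        k = min(cfg.ps_affected_per_pair, len(pool))
        affected = sorted(rng.choice(pool, size=k, replace=False))
        for s in affected:
            ev = {"sample": s, "cancer_type": ct, "chrom": plan["chrom"],
                  "bp1": plan["bp1"], "bp2": plan["bp2"], "type": "DEL",
                  "cn": 1, "inner": None}
            events_by_sample[s].append(ev)
            sv_rows.append({k2: ev[k2] for k2 in
                            ("sample", "cancer_type", "chrom", "bp1", "bp2",
                             "type", "cn")})
            ps_rows.append({
                "sample": s, "cancer_type": ct,
                "pair": f"{plan['gene5']}::{plan['gene3']}",
                "gene5": plan["gene5"], "gene3": plan["gene3"],
                "chrom": plan["chrom"], "bp1": plan["bp1"],
                "bp2": plan["bp2"], "fold": cfg.ps_fold})

    # background SVs
    for s in samples:
        taken = [(e["chrom"], e["bp1"], e["bp2"]) for e in events_by_sample[s]]
        for _ in range(int(rng.poisson(cfg.sv_rate))):
            placed = _place_background_sv(cfg, genome, taken, rng)
            if placed is None:
                continue
            taken.append((placed["chrom"], placed["bp1"], placed["bp2"]))
            ev = {"sample": s, "cancer_type": labels[s], **placed,
                  "cn": 1 if placed["type"] == "DEL" else 3, "inner": None}
            size = ev["bp2"] - ev["bp1"] + 1
            if (ev["type"] == "DEL" and size >= 90_000
                    and rng.random() < cfg.nested_homdel_prob):
                third = size // 3
                ev["inner"] = (ev["bp1"] + third, ev["bp2"] - third)
            events_by_sample[s].append(ev)
            sv_rows.append({k2: ev[k2] for k2 in
                            ("sample", "cancer_type", "chrom", "bp1", "bp2",
                             "type", "cn")})
            if ev["inner"] is not None:
                sv_rows.append({"sample": s, "cancer_type": labels[s],
                                "chrom": ev["chrom"], "bp1": ev["inner"][0],
                                "bp2": ev["inner"][1], "type": "DEL",
                                "cn": 0})

    segments = _emit_segments(cfg, genome, samples, labels, purity,
                              events_by_sample, rng)
    expression = _emit_expression(cfg, genes, samples, labels, ps_rows, rng)

    truth = SimTruth(
        svs=pd.DataFrame(sv_rows, columns=["sample", "cancer_type", "chrom",
                                           "bp1", "bp2", "type", "cn"]),
        ps_events=pd.DataFrame(ps_rows, columns=["sample", "cancer_type",
                                                 "pair", "gene5", "gene3",
                                                 "chrom", "bp1", "bp2",
                                                 "fold"]),
        purity=pd.Series(purity, name="purity"))
    cohort = SimulatedCohort(cfg, truth, segments, genes, genome, expression,
                             labels)
    if outdir is not None:
        cohort.write(outdir)
    return cohort


def _emit_segments(cfg, genome, samples, labels, purity, events_by_sample,
                   rng) -> list[SegmentRecord]:
    segments: list[SegmentRecord] = []
    for s in samples:
        by_chrom: dict[str, list[dict]] = {}
        for ev in events_by_sample[s]:
            by_chrom.setdefault(ev["chrom"], []).append(ev)
        for chrom in sorted(genome.chroms, key=str):
            ref = genome.chroms[chrom]
            bounds = {1, ref.cen_start, ref.cen_end + 1, ref.length + 1}
            for ev in by_chrom.get(chrom, []):
                bounds.update((ev["bp1"], ev["bp2"] + 1))
                if ev["inner"] is not None:
                    bounds.update((ev["inner"][0], ev["inner"][1] + 1))
            n_extra = int(rng.poisson(cfg.extra_breakpoint_rate))
            if n_extra:
                bounds.update(int(b) for b in
                              rng.integers(2, ref.length, size=n_extra))
            bounds = sorted(bounds)
            # copy number per interval, decided on unjittered coordinates
            intervals = []
            for b0, b1 in zip(bounds, bounds[1:]):
                lo, hi = b0, b1 - 1
                if lo >= ref.cen_start and hi <= ref.cen_end:
                    continue  # centromere: no probe data
                cn = 2
                for ev in by_chrom.get(chrom, []):
                    if ev["bp1"] <= lo and hi <= ev["bp2"]:
                        cn = ev["cn"]
                        if (ev["inner"] is not None
                                and ev["inner"][0] <= lo
                                and hi <= ev["inner"][1]):
                            cn = 0
                intervals.append([lo, hi, cn])
            # boundary jitter within +/- one probe spacing
            jitter = {}
            for b in bounds[1:-1]:
                jitter[b] = int(np.clip(
                    b + rng.integers(-cfg.probe_spacing,
                                     cfg.probe_spacing + 1),
                    2, ref.length))
            prev_end = 0
            p = purity[s]
            for lo, hi, cn in intervals:
                jlo = jitter.get(lo, lo)
                jhi = jitter.get(hi + 1, hi + 1) - 1
                jlo = max(jlo, prev_end + 1)
                if jhi < jlo:
                    jhi = jlo
                prev_end = jhi
                base = expected_seg_mean(cn, p, float("-inf"))
                val = base + rng.normal(0.0, cfg.noise_sd)
                seg_mean = max(val, cfg.amplitude_floor)
                segments.append(SegmentRecord(
                    sample_id=s, cancer_type=labels[s], chrom=chrom,
                    start=jlo, end=jhi, seg_mean=float(seg_mean),
                    num_probes=max(1, round((jhi - jlo + 1)
                                            / cfg.probe_spacing))))
    return segments


def _emit_expression(cfg, genes, samples, labels, ps_rows,
                     rng) -> ExpressionMatrix:
    ct_index = {ct: i for i, ct in enumerate(cfg.cancer_types)}
    gene_index = {g.gene_name: i for i, g in enumerate(genes)}
    mu = rng.uniform(*cfg.expr_mu_range,
                     size=(len(genes), len(cfg.cancer_types)))
    # planted pairs carry a stronger 5' promoter in their cancer type
    for row in ps_rows:
        mu[gene_index[row["gene5"]], ct_index[row["cancer_type"]]] = (
            mu[gene_index[row["gene3"]], ct_index[row["cancer_type"]]]
            + math.log2(cfg.ps_promoter_ratio))
    log2_vals = np.empty((len(genes), len(samples)))
    for j, s in enumerate(samples):
        log2_vals[:, j] = (mu[:, ct_index[labels[s]]]
                           + rng.normal(0.0, cfg.expr_sd, size=len(genes)))
    values = pd.DataFrame(np.exp2(log2_vals),
                          index=[g.gene_name for g in genes],
                          columns=samples)
    for row in ps_rows:
        values.loc[row["gene3"], row["sample"]] *= row["fold"]
    return ExpressionMatrix(values, pd.Series(labels))


def null_cohort(config: SimConfig | None = None,
                outdir: str | Path | None = None) -> SimulatedCohort:
    """Same cohort but with every planted induction effect set to 1 (the DNA
    layer is untouched); used for FDR-control tests."""
    cfg = dataclasses.replace(config or SimConfig(), ps_fold=1.0)
    return simulate_cohort(cfg, outdir)


# ---------------------------------------------------------------------------
# expression-only generators for the screen statistics

def simulate_screen(seed: int, n_candidates: int = 50, n_induced: int = 1,
                    n_samples: int = 120,
                    affected_range: tuple[int, int] = (3, 5),
                    fold: float = 8.0, sigma: float = 0.5,
                    promoter_ratio: float = 4.0,
                    mu_range: tuple[float, float] = (4.0, 8.0),
                    cancer_type: str = "SCREEN"
                    ) -> tuple[pd.DataFrame, ExpressionMatrix, list[str]]:
    """A candidate set for :func:`cnaps.expr_assoc.screen_recurrent`.

    Every candidate pair passes the stronger-promoter gate
    (5′ baseline = ``promoter_ratio`` × 3′ baseline); the first ``n_induced``
    pairs carry a planted ``fold``-times induction of the 3′ partner in their
    affected samples.  Returns (events, expression, induced pair keys).
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    gene_names, mus = [], []
    for i in range(n_candidates):
        mu3 = rng.uniform(*mu_range)
        gene_names += [f"P5_{i:03d}", f"P3_{i:03d}"]
        mus += [mu3 + math.log2(promoter_ratio), mu3]
    log2_vals = (np.array(mus)[:, None]
                 + rng.normal(0.0, sigma, size=(len(mus), n_samples)))
    values = pd.DataFrame(np.exp2(log2_vals), index=gene_names,
                          columns=samples)
    rows, induced_pairs = [], []
    for i in range(n_candidates):
        k = int(rng.integers(affected_range[0], affected_range[1] + 1))
        affected = rng.choice(samples, size=k, replace=False)
        pair = f"P5_{i:03d}::P3_{i:03d}"
        if i < n_induced:
            induced_pairs.append(pair)
            values.loc[f"P3_{i:03d}", affected] *= fold
        for s in affected:
            rows.append({"sample": s, "cancer_type": cancer_type,
                         "gene5": f"P5_{i:03d}", "gene3": f"P3_{i:03d}",
                         "pair": pair})
    labels = pd.Series(cancer_type, index=samples)
    return (pd.DataFrame(rows), ExpressionMatrix(values, labels),
            induced_pairs)


def simulate_coupled_events(seed: int, n_events: int = 500,
                            p_stronger: float = 0.5, coupling: float = 0.85,
                            n_background: int = 100,
                            strength_ratio: float = 4.0,
                            effect_fold: float = 4.0, sigma: float = 0.3,
                            mu_range: tuple[float, float] = (4.0, 8.0),
                            cancer_type: str = "COUPLED"
                            ) -> tuple[pd.DataFrame, ExpressionMatrix,
                                       pd.DataFrame]:
    """PS events with a planted stronger-promoter ⇒ induced coupling.

    Each event owns one affected sample and a private gene pair; with
    probability ``p_stronger`` the 5′ baseline is ``strength_ratio``-fold the
    3′ baseline (else the inverse), and the 3′ partner is induced
    (``effect_fold``) with probability ``coupling`` when stronger, else
    ``1 − coupling``.  Returns (events, expression, truth flags).
    """
    rng = np.random.default_rng(seed)
    samples = ([f"A{i:04d}" for i in range(n_events)]
               + [f"B{i:03d}" for i in range(n_background)])
    stronger = rng.random(n_events) < p_stronger
    induced = np.where(stronger, rng.random(n_events) < coupling,
                       rng.random(n_events) < 1.0 - coupling)
    gene_names, mus = [], []
    for i in range(n_events):
        mu3 = rng.uniform(*mu_range)
        delta = math.log2(strength_ratio)
        mus += [mu3 + (delta if stronger[i] else -delta), mu3]
        gene_names += [f"F{i:04d}", f"T{i:04d}"]
    log2_vals = (np.array(mus)[:, None]
                 + rng.normal(0.0, sigma, size=(len(mus), len(samples))))
    values = pd.DataFrame(np.exp2(log2_vals), index=gene_names,
                          columns=samples)
    rows = []
    for i in range(n_events):
        factor = effect_fold if induced[i] else 1.0 / effect_fold
        values.loc[f"T{i:04d}", f"A{i:04d}"] *= factor
        rows.append({"sample": f"A{i:04d}", "cancer_type": cancer_type,
                     "gene5": f"F{i:04d}", "gene3": f"T{i:04d}",
                     "pair": f"F{i:04d}::T{i:04d}"})
    labels = pd.Series(cancer_type, index=samples)
    truth = pd.DataFrame({"pair": [r["pair"] for r in rows],
                          "stronger": stronger, "induced": induced})
    return pd.DataFrame(rows), ExpressionMatrix(values, labels), truth
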