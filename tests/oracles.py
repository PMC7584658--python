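"""Independent oracles: literal rule re-statements, brute-force scans and
exact enumerations used to check the package's implementations."""

from __future__ import annotations

import math
from itertools import combinations


# ---------------------------------------------------------------------------
# copy-number state classification: literal five-inequality restatement

def classify_oracle(x: float) -> str:
    if x < -1:
        return "HOMDEL"
    if -1 <= x < -0.2:
        return "HEMIDEL"
    if -0.2 <= x < 0.3:
        return "NEUTRAL"
    if 0.3 <= x < 0.7:
        return "GAIN"
    return "AMP"  # x >= 0.7


# ---------------------------------------------------------------------------
# SV rules: one-pass literal evaluation over a state sequence

def sv_rules_oracle(states: list[str]) -> list[tuple[int, str]]:
    """Return (segment index, DEL/TDUP) per the three printed rules; a
    missing neighbor passes 'not X' tests and fails 'is X' tests."""
    calls = []
    n = len(states)
    for i, s in enumerate(states):
        left = states[i - 1] if i > 0 else None
        right = states[i + 1] if i < n - 1 else None
        if s == "HEMIDEL" and left != "HOMDEL" and right != "HOMDEL":
            calls.append((i, "DEL"))
        elif s == "HOMDEL" and left == "HEMIDEL" and right == "HEMIDEL":
            calls.append((i, "DEL"))
        elif s == "GAIN" and left != "AMP" and right != "AMP":
            calls.append((i, "TDUP"))
    return calls


# ---------------------------------------------------------------------------
# promoter substitution: junction-construction oracle

def junction_ps_oracle(sv_type: str, bp1: int, bp2: int, genes,
                       window: int = 200_000):
    """Build the derived chromosome as explicit blocks, read off the
    junction's flanks, and decide FUSION / UPSTREAM / None by transcriptional
    continuity.  Assumes a toy genome without overlapping gene bodies.
    Returns (category, five_prime_id, three_prime_id) or None.
    """
    if sv_type == "DEL":
        o_left, o_right = bp1, bp2        # blocks [1, bp1] + [bp2, L]
    else:
        o_left, o_right = bp2, bp1        # blocks [1, bp2] + [bp1, L]

    def coding_at(pos):
        hits = [g for g in genes
                if g.biotype == "coding" and g.start <= pos <= g.end]
        return hits[0] if hits else None

    def linc_at(pos):
        return any(g.biotype == "lincRNA" and g.start <= pos <= g.end
                   for g in genes)

    gl, gr = coding_at(o_left), coding_at(o_right)

    if gl is not None and gr is not None:
        if gl.gene_id == gr.gene_id or gl.strand != gr.strand:
            return None
        if gl.strand == "+":
            # transcription runs left->right across the junction
            return ("FUSION", gl.gene_id, gr.gene_id) if gl.tss <= o_left \
                else None
        return ("FUSION", gr.gene_id, gl.gene_id) if gr.tss >= o_right \
            else None

    if gl is not None and gr is None and gl.strand == "+":
        if gl.tss > o_left or linc_at(o_right):
            return None
        cands = [(g.tss - o_right, g.gene_id, g) for g in genes
                 if g.biotype == "coding" and g.strand == "+"
                 and 0 < g.tss - o_right <= window]
        if not cands:
            return None
        _, _, g3 = min(cands)
        return None if g3.gene_id == gl.gene_id \
            else ("UPSTREAM", gl.gene_id, g3.gene_id)

    if gr is not None and gl is None and gr.strand == "-":
        if gr.tss < o_right or linc_at(o_left):
            return None
        cands = [(o_left - g.tss, g.gene_id, g) for g in genes
                 if g.biotype == "coding" and g.strand == "-"
                 and 0 < o_left - g.tss <= window]
        if not cands:
            return None
        _, _, g3 = min(cands)
        return None if g3.gene_id == gr.gene_id \
            else ("UPSTREAM", gr.gene_id, g3.gene_id)

    return None


# ---------------------------------------------------------------------------
# statistics: exact enumerations

def bh_oracle(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pvals[i] * m / rank)
        q[i] = prev
    return q


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over the support."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


def ranksum_exact_oracle(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments (no ties)."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n, m = len(x), len(y)
    order = sorted(range(n + m), key=lambda i: pooled[i])
    rank_of = {i: r for r, i in enumerate(order)}
    u_obs = sum(sorted(rank_of[i] for i in range(n))[j] - j
                for j in range(n))
    center = n * m / 2
    total = hits = 0
    for subset in combinations(range(n + m), n):
        u = sum(s - j for j, s in enumerate(subset))
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total
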