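"""Pairwise linkage disequilibrium and Gabriel confidence-interval blocks.

Works on inbred-line genotype matrices (allele strings per marker, "H" for
heterozygous, "-" missing).  Because the lines are nearly fully inbred,
almost every line contributes two phase-known haplotypes directly; only
double heterozygotes are phase-ambiguous and are resolved with the
standard EM haplotype-frequency estimator, which reduces exactly to direct
counting when no double heterozygotes exist.

Per pair of loci with haplotype frequencies p(AB) etc.:
    D  = p(AB) - p(A) p(B)
    D' = |D| / Dmax            (Dmax the admissible bound given the margins)
    r2 = D^2 / (p(A) p(a) p(B) p(b))
The D' confidence interval comes from a likelihood profile over a D' grid
(allele frequencies held at their estimates), as used by the Gabriel block
definition: a pair is in "strong LD" if CI_low >= 0.70 and CI_high >= 0.98
and shows "strong recombination" if CI_high < 0.90; a marker span is a
block when at least 95% of its informative pairs are strong LD.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

__all__ = [
    "LocusSummary",
    "LDPair",
    "LDBlock",
    "filter_loci",
    "haplotype_frequencies",
    "ld_pair",
    "gabriel_blocks",
    "dprime_triangle",
]


@dataclass(frozen=True)
class LocusSummary:
    marker: str
    position: int
    maf: float
    call_rate: float
    passes_filters: bool


def filter_loci(
    genotypes: pd.DataFrame,
    positions: dict,
    maf_min: float = 0.05,
    call_rate_min: float = 0.50,
    het: str = "H",
    missing: str = "-",
) -> list:
    """Haploview-style locus filters: MAF > maf_min and call rate > call_rate_min.

    The Hardy-Weinberg filter is disabled (cut-off 0), appropriate for an
    inbred population.  Alleles are counted two per line; a heterozygous
    call contributes one of each allele.
    """
    out = []
    for marker in genotypes.columns:
        col = genotypes[marker].astype(str)
        called = col[col != missing]
        call_rate = len(called) / len(col) if len(col) else 0.0
        counts: dict[str, int] = {}
        n_het = 0
        for g in called:
            if g == het:
                n_het += 1
            else:
                counts[g] = counts.get(g, 0) + 2
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        if n_het and len(alleles) == 2:
            counts[alleles[0]] += n_het
            counts[alleles[1]] += n_het
        total = sum(counts.values())
        if len(alleles) >= 2 and total > 0:
            maf = min(counts[alleles[0]], counts[alleles[1]]) / total
        else:
            maf = 0.0
        out.append(
            LocusSummary(
                marker=marker,
                position=int(positions.get(marker, -1)),
                maf=float(maf),
                call_rate=float(call_rate),
                passes_filters=(maf > maf_min and call_rate > call_rate_min),
            )
        )
    return out


@dataclass
class LDPair:
    marker1: str
    marker2: str
    hap_freqs: dict  # (allele1, allele2) -> frequency
    D: float
    d_prime: float
    r2: float
    ci_low: float
    ci_high: float
    n_haplotypes: float


def _pair_counts(g1, g2, het: str, missing: str):
    """Phase-known haplotype counts and the double-heterozygote tally.

    Returns (alleles1, alleles2, counts 2x2 array, n_double_het).
    """
    g1 = [str(x) for x in g1]
    g2 = [str(x) for x in g2]
    a1 = sorted({x for x in g1 if x not in (het, missing)})
    a2 = sorted({x for x in g2 if x not in (het, missing)})
    if len(a1) != 2 or len(a2) != 2:
        raise DataError(
            "ld_pair needs two homozygous allele classes per locus "
            "(monomorphic or unfiltered input?)"
        )
    idx1 = {a1[0]: 0, a1[1]: 1}
    idx2 = {a2[0]: 0, a2[1]: 1}
    counts = np.zeros((2, 2))
    n_dh = 0
    for x, y in zip(g1, g2):
        if x == missing or y == missing:
            continue
        hx = het == x
        hy = het == y
        if hx and hy:
            n_dh += 1
        elif hx:
            counts[0, idx2[y]] += 1
            counts[1, idx2[y]] += 1
        elif hy:
            counts[idx1[x], 0] += 1
            counts[idx1[x], 1] += 1
        else:
            counts[idx1[x], idx2[y]] += 2
    return a1, a2, counts, n_dh


def haplotype_frequencies(
    counts: np.ndarray, n_double_het: int, tol: float = 1e-10, max_iter: int = 200
) -> np.ndarray:
    """EM haplotype frequencies for two biallelic loci.

    ``counts`` are phase-known haplotype counts (2x2); each double
    heterozygote contributes two haplotypes that are either cis
    (AB + ab) or trans (Ab + aB).  With no double heterozygotes this is
    exactly the normalized direct count.
    """
    total = counts.sum() + 2 * n_double_het
    if total == 0:
        raise DataError("no informative lines for this marker pair")
    f = (counts + 0.25) / (counts + 0.25).sum()
    if n_double_het == 0:
        return counts / total
    for _ in range(max_iter):
        cis = f[0, 0] * f[1, 1]
        trans = f[0, 1] * f[1, 0]
        p_cis = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = counts.copy().astype(float)
        new[0, 0] += n_double_het * p_cis
        new[1, 1] += n_double_het * p_cis
        new[0, 1] += n_double_het * (1 - p_cis)
        new[1, 0] += n_double_het * (1 - p_cis)
        new /= total
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return f


def _dprime_ci(
    counts: np.ndarray,
    n_dh: int,
    pA: float,
    pB: float,
    sign: float,
    grid: int = 101,
    lo_q: float = 0.05,
    hi_q: float = 0.95,
) -> tuple:
    """Likelihood-profile CI on |D'| over a grid, allele freqs held fixed."""
    pa, pb = 1 - pA, 1 - pB
    dmax = min(pA * pb, pa * pB) if sign >= 0 else min(pA * pB, pa * pb)
    if dmax <= 0:
        return 0.0, 0.0
    dgrid = np.linspace(0.0, 1.0, grid)
    ll = np.full(grid, -np.inf)
    for i, dp in enumerate(dgrid):
        D = (1.0 if sign >= 0 else -1.0) * dp * dmax
        f = np.array(
            [[pA * pB + D, pA * pb - D], [pa * pB - D, pa * pb + D]]
        )
        f = np.clip(f, 1e-12, None)
        val = float((counts * np.log(f)).sum())
        if n_dh:
            val += n_dh * np.log(f[0, 0] * f[1, 1] + f[0, 1] * f[1, 0])
        ll[i] = val
    lik = np.exp(ll - ll.max())
    cum = np.cumsum(lik)
    cum /= cum[-1]
    lo = float(dgrid[int(np.searchsorted(cum, lo_q))])
    hi = float(dgrid[min(int(np.searchsorted(cum, hi_q)), grid - 1)])
    return lo, hi


def ld_pair(
    g1: Sequence,
    g2: Sequence,
    marker1: str = "m1",
    marker2: str = "m2",
    het: str = "H",
    missing: str = "-",
) -> LDPair:
    """Pairwise D, D', r2 and the D' confidence interval for two loci."""
    a1, a2, counts, n_dh = _pair_counts(g1, g2, het, missing)
    f = haplotype_frequencies(counts, n_dh)
    pA = f[0].sum()
    pB = f[:, 0].sum()
    pa, pb = 1 - pA, 1 - pB
    D = float(f[0, 0] - pA * pB)
    denom = pA * pa * pB * pb
    r2 = D * D / denom if denom > 0 else float("nan")
    dmax = min(pA * pb, pa * pB) if D >= 0 else min(pA * pB, pa * pb)
    d_prime = abs(D) / dmax if dmax > 0 else float("nan")
    ci_low, ci_high = _dprime_ci(counts, n_dh, pA, pB, np.sign(D) or 1.0)
    hap_freqs = {
        (a1[i], a2[j]): float(f[i, j]) for i in range(2) for j in range(2)
    }
    return LDPair(
        marker1=marker1,
        marker2=marker2,
        hap_freqs=hap_freqs,
        D=D,
        d_prime=float(d_prime),
        r2=float(r2),
        ci_low=ci_low,
        ci_high=ci_high,
        n_haplotypes=float(counts.sum() + 2 * n_dh),
    )


@dataclass(frozen=True)
class LDBlock:
    markers: tuple
    start_pos: int
    end_pos: int

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos


def gabriel_blocks(
    pairs: Sequence[LDPair],
    marker_order: Sequence[str],
    positions: dict,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    informative_fraction: float = 0.95,
) -> list:
    """Gabriel confidence-interval block calling.

    A pair is strong LD when its D' CI is [>=0.70, >=0.98] and strong
    recombination when CI_high < 0.90; intermediate pairs are
    uninformative.  A candidate span of >= 2 markers is a block when at
    least ``informative_fraction`` of its informative pairs are strong LD
    (and it has at least one informative pair).  Maximal non-overlapping
    blocks are returned greedily, longest bp span first.
    """
    order = list(marker_order)
    index = {m: i for i, m in enumerate(order)}
    if len(order) < 2:
        return []
    state = {}
    for p in pairs:
        if p.marker1 in index and p.marker2 in index:
            i, j = sorted((index[p.marker1], index[p.marker2]))
            if p.ci_low >= strong_low and p.ci_high >= strong_high:
                state[(i, j)] = "strong"
            elif p.ci_high < recomb_high:
                state[(i, j)] = "recomb"
            else:
                state[(i, j)] = "uninformative"
    candidates = []
    n = len(order)
    for i in range(n):
        for j in range(i + 1, n):
            classes = [
                state.get((a, b))
                for a, b in itertools.combinations(range(i, j + 1), 2)
            ]
            informative = [c for c in classes if c in ("strong", "recomb")]
            if not informative:
                continue
            if sum(c == "strong" for c in informative) / len(informative) >= informative_fraction:
                span = positions[order[j]] - positions[order[i]]
                candidates.append((span, j - i, i, j))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    taken = np.zeros(n, dtype=bool)
    blocks = []
    for span, _, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            LDBlock(
                markers=tuple(order[i : j + 1]),
                start_pos=int(positions[order[i]]),
                end_pos=int(positions[order[j]]),
            )
        )
    blocks.sort(key=lambda b: b.start_pos)
    return blocks


def dprime_triangle(pairs: Sequence[LDPair], marker_order: Sequence[str]) -> str:
    """Text rendering of the D' half-matrix (heat-triangle), 0-9 scale."""
    index = {m: i for i, m in enumerate(marker_order)}
    n = len(marker_order)
    grid = [[" " for _ in range(n)] for _ in range(n)]
    for p in pairs:
        if p.marker1 in index and p.marker2 in index:
            i, j = sorted((index[p.marker1], index[p.marker2]))
            grid[i][j] = str(min(9, int(round(p.d_prime * 9))))
    lines = [f"{m:>12s} " + " ".join(grid[i][i + 1 :]) for i, m in enumerate(marker_order)]
    return "\n".join(lines)
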