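"""Per-gene haplotype-pattern (HP) mining, DRR, and introgression painting.

An HP is the ordered allele vector over one gene's markers across inbred
lines.  The wild-type line's vector is always HP1; alternative patterns are
numbered by descending member count with lexicographic tie-breaks, so the
numbering is deterministic.  Heterozygous calls ("H") are a distinct allele
state, never collapsed to a homozygote.  A line with missing calls joins an
existing HP only if its non-missing alleles match exactly one pattern.

The damage-reducing ratio (DRR) of an HP is its mean damage AUC divided by
the wild-type HP's mean AUC within the same BPH population; DRR < 1 means
the pattern reduces damage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

__all__ = [
    "HaplotypePattern",
    "IntrogressionSegment",
    "mine_hp",
    "hp_assignments",
    "drr",
    "paint_introgression",
    "paint_population",
    "donor_fraction_painted",
]


@dataclass
class HaplotypePattern:
    gene_id: str
    hp_number: int
    markers: tuple
    alleles: tuple
    member_lines: tuple

    @property
    def frequency(self) -> int:
        return len(self.member_lines)


def mine_hp(
    genotypes: pd.DataFrame,
    wt_line_id: str,
    gene_id: str = "",
    missing: str = "-",
) -> list:
    """Mine haplotype patterns for one gene.

    ``genotypes`` is a lines x markers frame of allele strings ("H" for
    heterozygous, ``missing`` for no call) restricted to the gene's
    markers, columns in map order.  The wild-type line must be fully
    genotyped (HP1 is undefined otherwise).  Returns patterns with member
    lines; lines whose missing-data vector matches no pattern, or more
    than one, stay unassigned.
    """
    if wt_line_id not in genotypes.index:
        raise DataError(f"wild-type line {wt_line_id!r} absent from genotype matrix")
    markers = tuple(genotypes.columns)
    wt_vec = tuple(str(a) for a in genotypes.loc[wt_line_id])
    if missing in wt_vec:
        raise DataError(
            f"wild-type line {wt_line_id!r} has missing calls; HP1 undefined"
        )
    complete: dict[tuple, list] = {}
    incomplete: list[tuple] = []
    for line, row in genotypes.iterrows():
        vec = tuple(str(a) for a in row)
        if missing in vec:
            incomplete.append((line, vec))
        else:
            complete.setdefault(vec, []).append(line)

    others = [(v, lines) for v, lines in complete.items() if v != wt_vec]
    others.sort(key=lambda item: (-len(item[1]), item[0]))
    ordered = [(wt_vec, complete.get(wt_vec, []))] + others
    members = {vec: list(lines) for vec, lines in ordered}

    for line, vec in incomplete:
        matches = [
            pvec
            for pvec, _ in ordered
            if all(a == missing or a == b for a, b in zip(vec, pvec))
        ]
        if len(matches) == 1:
            members[matches[0]].append(line)
        else:
            log.info(
                "line %s not assigned (%d candidate patterns)", line, len(matches)
            )

    return [
        HaplotypePattern(
            gene_id=gene_id,
            hp_number=i + 1,
            markers=markers,
            alleles=vec,
            member_lines=tuple(members[vec]),
        )
        for i, (vec, _) in enumerate(ordered)
    ]


def hp_assignments(patterns: Sequence[HaplotypePattern]) -> dict:
    """Mapping line_id -> hp_number over a gene's mined patterns."""
    out = {}
    for p in patterns:
        for line in p.member_lines:
            if line in out:
                raise DataError(f"line {line} assigned to more than one HP")
            out[line] = p.hp_number
    return out


def drr(mean_auc_hp: float, mean_auc_wt: float, ndigits: int = 3) -> float:
    """Damage-reducing ratio: HP mean AUC over the wild-type HP mean AUC."""
    if mean_auc_wt <= 0:
        raise DataError("wild-type mean AUC must be > 0")
    return round(mean_auc_hp / mean_auc_wt, ndigits)


# ---------------------------------------------------------------------------
# Graphical genotyping / introgression painting


@dataclass(frozen=True)
class IntrogressionSegment:
    line_id: str
    chrom: str
    start: int
    end: int
    origin: str  # donor | recipient | heterozygous | unknown
    n_markers: int


def paint_introgression(
    line_geno: Sequence[str],
    donor_geno: Sequence[str],
    recipient_geno: Sequence[str],
    positions: Sequence[int],
    chrom: str = "chr1",
    line_id: str = "line",
    het: str = "H",
    missing: str = "-",
) -> list:
    """Classify a line's chromosome into parental-origin segments.

    Each informative marker (polymorphic between the parents, called in the
    line) is classified donor / recipient / heterozygous / unknown by
    comparison with the parental alleles; maximal runs of one class become
    segments, with boundaries at the midpoint between adjacent markers of
    differing class.  Markers monomorphic between the parents are excluded
    with a warning; missing calls in the line are skipped.
    """
    pos = np.asarray(positions)
    if not np.all(np.diff(pos) > 0):
        raise DataError("marker positions must be strictly increasing")
    classes, kept_pos, n_mono = [], [], 0
    for g, d, r, p in zip(line_geno, donor_geno, recipient_geno, pos):
        g, d, r = str(g), str(d), str(r)
        if d == r:
            n_mono += 1
            continue
        if g == missing:
            continue
        if g == het:
            cls = "heterozygous"
        elif g == d:
            cls = "donor"
        elif g == r:
            cls = "recipient"
        else:
            cls = "unknown"
        classes.append(cls)
        kept_pos.append(int(p))
    if n_mono:
        log.warning("%d markers monomorphic between parents excluded", n_mono)
    if not classes:
        return []
    segments = []
    run_start_idx = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[run_start_idx]:
            start = (
                kept_pos[0]
                if run_start_idx == 0
                else (kept_pos[run_start_idx - 1] + kept_pos[run_start_idx]) // 2
            )
            end = (
                kept_pos[-1]
                if i == len(classes)
                else (kept_pos[i - 1] + kept_pos[i]) // 2
            )
            segments.append(
                IntrogressionSegment(
                    line_id=line_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    origin=classes[run_start_idx],
                    n_markers=i - run_start_idx,
                )
            )
            run_start_idx = i
    return segments


def paint_population(
    genotypes: pd.DataFrame,
    donor_line: str,
    recipient_line: str,
    positions: Sequence[int],
    chrom: str = "chr1",
    het: str = "H",
    missing: str = "-",
) -> dict:
    """Paint every non-parental line against the two parents.

    Returns ``{line_id: [IntrogressionSegment, ...]}``.
    """
    donor = genotypes.loc[donor_line]
    recipient = genotypes.loc[recipient_line]
    out = {}
    for line, row in genotypes.iterrows():
        if line in (donor_line, recipient_line):
            continue
        out[line] = paint_introgression(
            row, donor, recipient, positions, chrom=chrom, line_id=line,
            het=het, missing=missing,
        )
    return out


def donor_fraction_painted(segments: Sequence[IntrogressionSegment]) -> float:
    """Donor share of the painted span (het segments count half)."""
    if not segments:
        return 0.0
    total = sum(s.end - s.start for s in segments)
    if total == 0:
        return 0.0
    donor = sum(
        (s.end - s.start) * (1.0 if s.origin == "donor" else 0.5 if s.origin == "heterozygous" else 0.0)
        for s in segments
    )
    return donor / total
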