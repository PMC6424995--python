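"""Marker- and haplotype-level association with damage AUC.

Single-marker analysis is a one-way ANOVA across genotype classes (for two
classes this is equivalent to simple linear regression on allele dosage:
the F statistic is the squared pooled-variance t, and the variance
explained is identical).  PVE is reported as 100 * SS_between / SS_total,
the regression R-squared on the percent scale.  Significance stars follow
the convention * P < 0.05, ** P < 0.001, and no multiple-testing
correction is applied by default (Benjamini-Hochberg is available behind a
flag in :func:`single_marker_scan`).

Multiple-comparison letter groups use Tukey's HSD with an insert-and-absorb
compact letter display; resistance classes (R / MR / S) are anchored on the
letters of a resistant and a susceptible check line.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NoVariationError
from .hapmine import drr as _drr

__all__ = [
    "AssociationResult",
    "single_marker_assoc",
    "single_marker_scan",
    "hp_assoc",
    "tukey_letters",
    "classify_resistance",
]


def _stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AssociationResult:
    """One marker's or one gene's HP association with damage AUC."""

    target: str
    population_id: Optional[str]
    p_value: float
    pve: float  # percent of phenotypic variance explained (R^2 x 100)
    groups: pd.DataFrame  # columns: group, mean_auc, count [, p_vs_wt, drr]
    stars: str = ""
    drr: Optional[dict] = None  # significant group -> damage-reducing ratio

    def __post_init__(self):
        if not (0.0 <= self.pve <= 100.0 + 1e-9):
            raise DataError("PVE must lie in [0, 100]")
        self.stars = _stars(self.p_value)

    def summary(self) -> str:
        head = (
            f"{self.target}"
            + (f" [{self.population_id}]" if self.population_id else "")
            + f": P = {self.p_value:.4g}{self.stars}, PVE = {self.pve:.1f}%"
        )
        body = self.groups.to_string(index=False)
        return head + "\n" + body


def _anova(groups: Sequence[np.ndarray]) -> tuple:
    """One-way ANOVA: (F, p, pve) with pve = 100 * SSB / SST."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    sst = ssb + ssw
    if sst == 0:
        return 0.0, 1.0, 0.0
    pve = 100.0 * ssb / sst
    df1, df2 = k - 1, n - k
    if df2 <= 0:
        raise DataError("not enough residual degrees of freedom for ANOVA")
    if ssw == 0:
        # all within-group variance exhausted: perfectly separated groups
        return float("inf"), 0.0, pve
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return f, p, pve


def single_marker_assoc(
    genotypes: Sequence,
    auc: Sequence[float],
    target: str = "marker",
    population_id: Optional[str] = None,
) -> AssociationResult:
    """One-way ANOVA of damage AUC across a marker's genotype classes."""
    geno = np.asarray([str(g) for g in genotypes])
    y = np.asarray(auc, dtype=float)
    if len(geno) != len(y):
        raise DataError("genotype and AUC vectors differ in length")
    if len(y) < 3:
        raise DataError("need at least 3 observations")
    labels = sorted(set(geno))
    if len(labels) < 2:
        raise NoVariationError(f"{target}: single genotype class {labels}")
    groups = [y[geno == lab] for lab in labels]
    _, p, pve = _anova(groups)
    gtab = pd.DataFrame(
        {
            "group": labels,
            "mean_auc": [float(g.mean()) for g in groups],
            "count": [len(g) for g in groups],
        }
    )
    return AssociationResult(
        target=target, population_id=population_id, p_value=p, pve=pve, groups=gtab
    )


def single_marker_scan(
    genotypes: pd.DataFrame,
    auc: pd.Series,
    population_id: Optional[str] = None,
    adjust: Optional[str] = None,
) -> pd.DataFrame:
    """Association of every marker column with AUC; one row per marker.

    ``adjust="bh"`` appends Benjamini-Hochberg adjusted P values.
    """
    lines = genotypes.index.intersection(auc.index)
    rows = []
    for marker in genotypes.columns:
        try:
            res = single_marker_assoc(
                genotypes.loc[lines, marker], auc.loc[lines], target=marker,
                population_id=population_id,
            )
        except NoVariationError:
            continue
        rows.append((marker, res.p_value, res.pve, res.stars))
    out = pd.DataFrame(rows, columns=["marker", "p_value", "pve", "stars"])
    if adjust == "bh" and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    elif adjust not in (None, "none", "bh"):
        raise DataError(f"unknown adjustment {adjust!r}")
    return out


def hp_assoc(
    hp_labels: Sequence[int],
    auc: Sequence[float],
    wt_hp: int = 1,
    alpha: float = 0.05,
    target: str = "gene",
    population_id: Optional[str] = None,
) -> AssociationResult:
    """HP-level association for one gene.

    One-way ANOVA across haplotype patterns; each non-wild-type HP is then
    compared with the WT HP (pooled-variance t test) and, where that
    comparison is significant at ``alpha``, its damage-reducing ratio
    (HP mean AUC / WT mean AUC) is reported.  If the WT HP is absent the
    ANOVA is still reported and DRR is skipped with a warning.
    """
    hp = np.asarray([int(h) for h in hp_labels])
    y = np.asarray(auc, dtype=float)
    if len(hp) != len(y):
        raise DataError("HP and AUC vectors differ in length")
    labels = sorted(set(hp))
    if len(labels) < 2:
        raise NoVariationError(f"{target}: fewer than 2 HPs present")
    groups = {lab: y[hp == lab] for lab in labels}
    _, p, pve = _anova(list(groups.values()))

    rows = []
    drrs = {}
    wt_mean = float(groups[wt_hp].mean()) if wt_hp in groups else None
    if wt_mean is None:
        warnings.warn(
            f"{target}: wild-type HP{wt_hp} absent; DRR skipped", stacklevel=2
        )
    for lab in labels:
        g = groups[lab]
        row = {"group": f"HP{lab}", "mean_auc": float(g.mean()), "count": len(g)}
        if wt_mean is not None and lab != wt_hp:
            wt_vals = groups[wt_hp]
            if len(g) >= 1 and (len(g) + len(wt_vals)) >= 3:
                pooled_ss = ((g - g.mean()) ** 2).sum() + (
                    (wt_vals - wt_vals.mean()) ** 2
                ).sum()
                scale = 1.0 + abs(g.mean()) + abs(wt_vals.mean())
                if pooled_ss <= 1e-16 * scale**2:
                    # perfectly separated (or identical) constant groups
                    p_vs = 0.0 if abs(g.mean() - wt_vals.mean()) > 1e-12 * scale else 1.0
                else:
                    _, p_vs = stats.ttest_ind(g, wt_vals, equal_var=True)
                    p_vs = float(p_vs)
            else:
                p_vs = float("nan")
            row["p_vs_wt"] = p_vs
            if np.isfinite(p_vs) and p_vs < alpha and wt_mean > 0:
                ratio = _drr(float(g.mean()), wt_mean)
                row["drr"] = ratio
                drrs[f"HP{lab}"] = ratio
        rows.append(row)
    gtab = pd.DataFrame(rows)
    return AssociationResult(
        target=target,
        population_id=population_id,
        p_value=p,
        pve=pve,
        groups=gtab,
        drr=drrs or None,
    )


# ---------------------------------------------------------------------------
# Compact letter display and resistance classes


def tukey_letters(groups: dict, alpha: float = 0.05) -> dict:
    """Tukey HSD compact letter display.

    ``groups`` maps label -> observations.  Groups sharing a letter are not
    significantly different at ``alpha``.  With zero pooled variance,
    groups with unequal means are all declared distinct.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise DataError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    n_total = sum(len(a) for a in arrays.values())
    if n_total <= len(labels):
        raise DataError("pooled variance needs total n > number of groups")
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    significant = set()
    if ssw == 0:
        for a, b in itertools.combinations(labels, 2):
            if arrays[a].mean() != arrays[b].mean():
                significant.add(frozenset((a, b)))
    else:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        by_name = {str(k): k for k in labels}
        if len(by_name) != len(labels):
            raise DataError("group labels must be unique as strings")
        data = np.concatenate([arrays[k] for k in labels])
        cats = np.concatenate([[str(k)] * len(arrays[k]) for k in labels])
        res = pairwise_tukeyhsd(data, cats, alpha=alpha)
        uniq = list(np.unique(cats))
        for (a, b), rej in zip(itertools.combinations(uniq, 2), res.reject):
            if rej:
                significant.add(frozenset((by_name[a], by_name[b])))

    # insert-and-absorb CLD, groups ordered by ascending mean
    order = sorted(labels, key=lambda k: (arrays[k].mean(), str(k)))
    columns = [set(order)]
    for pair in significant:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.append(col - {a})
                columns.append(col - {b})
        # absorb: drop columns that are subsets of another
        columns = [
            c
            for i, c in enumerate(columns)
            if c and not any(i != j and c < d for j, d in enumerate(columns))
        ]
        # deduplicate
        uniq = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    columns.sort(key=lambda c: min(order.index(m) for m in c))
    letters = {k: "" for k in labels}
    for letter, col in zip(_letter_stream(), columns):
        for member in order:
            if member in col:
                letters[member] += letter
    return letters


def _letter_stream():
    import string

    for size in range(1, 3):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def classify_resistance(
    letters: dict,
    resistant_check: str,
    susceptible_check: str,
) -> dict:
    """Check-anchored R / MR / S classes from a compact letter display.

    A line sharing a letter with the resistant check and none with the
    susceptible check is R; sharing with the susceptible check only is S;
    anything else is MR.  If the two checks share a letter the assay lacks
    resolution and classification is refused.
    """
    for check in (resistant_check, susceptible_check):
        if check not in letters:
            raise DataError(f"check line {check!r} absent from letter display")
    r_set = set(letters[resistant_check])
    s_set = set(letters[susceptible_check])
    if r_set & s_set:
        raise DataError(
            "resistant and susceptible checks share a letter; "
            "classification refused (assay lacks resolution)"
        )
    out = {}
    for line, ls in letters.items():
        if line in (resistant_check, susceptible_check):
            continue
        l_set = set(ls)
        if l_set & r_set and not (l_set & s_set):
            out[line] = "R"
        elif l_set & s_set and not (l_set & r_set):
            out[line] = "S"
        else:
            out[line] = "MR"
    return out
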