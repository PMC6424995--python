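"""SNP-index / delta-SNP-index sliding-window QTL-seq scan.

The bulked-segregant statistic: per site, the SNP-index of a pool is the
fraction of reads carrying the donor (alternate) allele; the scan statistic
is the absolute difference between the susceptible- and resistant-pool
SNP-indexes, averaged over 2-Mb windows advanced in 10-kb steps.  Window
significance is judged against Monte-Carlo quantiles of the same statistic
under the null hypothesis of no QTL: individuals' genotypes are resampled
from the population's expected genotype frequencies, pool allele
frequencies formed, and reads drawn binomially at the observed depths.

Two null summaries are provided.  :func:`null_thresholds` gives per-site
|delta| quantiles stratified by depth (5x bins up to 100x, isotonic in
depth), matching the per-position confidence bands drawn on scan plots.
The window caller instead simulates the null distribution of each window's
*mean* |delta| from its member sites' observed depths, so that a 95%
window threshold is exceeded by 5% of null windows by construction.

The model-style entry point is :class:`QtlSeqScan` /
:class:`QtlSeqScanResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "snp_index",
    "delta_snp_index",
    "index_records",
    "sliding_windows",
    "bil_genotype_probs",
    "empirical_genotype_probs",
    "estimate_genotype_probs",
    "null_delta_samples",
    "null_quantile",
    "null_thresholds",
    "window_null_quantiles",
    "call_qtl",
    "QtlSeqScan",
    "QtlSeqScanResult",
]


# ---------------------------------------------------------------------------
# Per-site statistics


def snp_index(ref_depth: int, donor_depth: int) -> float:
    """Donor-allele read fraction at a site; NaN (masked) at zero depth."""
    if ref_depth < 0 or donor_depth < 0:
        raise DataError("depths must be non-negative")
    total = ref_depth + donor_depth
    if total == 0:
        return float("nan")
    return donor_depth / total


def delta_snp_index(si_susceptible: float, si_resistant: float) -> float:
    """|SNP-index(susceptible) - SNP-index(resistant)|, in [0, 1]."""
    return abs(si_susceptible - si_resistant)


def index_records(
    sites: Iterable,
    pool_susceptible: str,
    pool_resistant: str,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Per-site SNP-index table for a susceptible/resistant pool pair.

    Sites where either pool has total depth < ``min_depth`` get NaN
    (masked) indexes; NaN propagates to delta and such sites never count
    toward window means.
    """
    rows = []
    for s in sites:
        rs, ds = s.depths[pool_susceptible]
        rr, dr = s.depths[pool_resistant]
        si_s = snp_index(rs, ds) if rs + ds >= min_depth else float("nan")
        si_r = snp_index(rr, dr) if rr + dr >= min_depth else float("nan")
        delta = (
            delta_snp_index(si_s, si_r)
            if not (np.isnan(si_s) or np.isnan(si_r))
            else float("nan")
        )
        rows.append((s.chrom, s.pos, rs + ds, rr + dr, si_s, si_r, delta))
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "depth_s", "depth_r", "si_s", "si_r", "delta"],
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sliding windows


def _window_starts(length: int, window_size: int, step: int) -> np.ndarray:
    starts = [1]
    while starts[-1] + window_size - 1 < length:
        starts.append(starts[-1] + step)
    return np.asarray(starts, dtype=np.int64)


def sliding_windows(
    records: pd.DataFrame,
    chrom_lengths: dict,
    window_size: int = 2_000_000,
    step: int = 10_000,
    min_snps: int = 3,
) -> pd.DataFrame:
    """Mean |delta SNP-index| over sliding windows.

    Windows are anchored at position 1 and advanced by ``step``; membership
    is the half-open bp interval [start, start + window_size).  A terminal
    window is truncated at the chromosome end.  Windows holding fewer than
    ``min_snps`` informative sites are reported but flagged ``masked``.
    The mean is unweighted over member sites with defined delta.
    """
    if window_size <= 0:
        raise ConfigError("window_size must be > 0")
    if step <= 0:
        raise ConfigError("step must be > 0")
    out = []
    for chrom, length in chrom_lengths.items():
        sub = records[records["chrom"] == chrom]
        sub = sub[np.isfinite(sub["delta"])]
        pos = np.sort(sub["pos"].to_numpy())
        delta = sub.sort_values("pos", kind="mergesort")["delta"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        starts = _window_starts(int(length), window_size, step)
        ends = np.minimum(starts + window_size - 1, int(length))
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        for s, e, k, m in zip(starts, ends, n, mean):
            out.append((chrom, int(s), int(e), int(k), float(m), k < min_snps))
    df = pd.DataFrame(
        out, columns=["chrom", "start", "end", "n_snps", "mean_delta", "masked"]
    )
    return df


# ---------------------------------------------------------------------------
# Null model


def bil_genotype_probs(
    n_backcrosses: int = 3, n_selfings: int = 4
) -> tuple:
    """Expected (P0, P1, P2) donor-dosage genotype frequencies for a BIL.

    After b backcrosses the donor allele frequency is p = (1/2)^(b+1) and
    all donor material is heterozygous (het fraction 2p); each selfing
    generation halves the heterozygous fraction while p is conserved.
    """
    p = 0.5 ** (n_backcrosses + 1)
    het = 2.0 * p * 0.5**n_selfings
    p2 = p - het / 2.0
    p0 = 1.0 - het - p2
    return (p0, het, p2)


def empirical_genotype_probs(genotypes: np.ndarray) -> tuple:
    """Genome-wide (P0, P1, P2) frequencies from a 0/1/2 genotype matrix."""
    g = np.asarray(genotypes)
    n = g.size
    return tuple(float((g == k).sum()) / n for k in (0, 1, 2))


def null_delta_samples(
    rng: np.random.Generator,
    n_sims: int,
    pool_sizes: tuple,
    depth_s,
    depth_r,
    genotype_probs: tuple,
) -> np.ndarray:
    """Monte-Carlo |delta SNP-index| draws under the no-QTL null.

    For each draw, each pool's member genotypes are resampled independently
    from ``genotype_probs``, giving a pool donor-allele frequency; donor
    reads are then Binomial(depth, frequency).  ``depth_s``/``depth_r``
    may be scalars or per-draw arrays.
    """
    n_r, n_s = int(pool_sizes[0]), int(pool_sizes[1])
    if n_r < 1 or n_s < 1:
        raise DataError("pool sizes must be >= 1")
    probs = np.asarray(genotype_probs, dtype=float)
    counts_s = rng.multinomial(n_s, probs, size=n_sims)
    counts_r = rng.multinomial(n_r, probs, size=n_sims)
    freq_s = (counts_s[:, 1] + 2 * counts_s[:, 2]) / (2.0 * n_s)
    freq_r = (counts_r[:, 1] + 2 * counts_r[:, 2]) / (2.0 * n_r)
    d_s = np.broadcast_to(np.asarray(depth_s), (n_sims,))
    d_r = np.broadcast_to(np.asarray(depth_r), (n_sims,))
    reads_s = rng.binomial(d_s, freq_s)
    reads_r = rng.binomial(d_r, freq_r)
    with np.errstate(invalid="ignore"):
        si_s = np.where(d_s > 0, reads_s / np.maximum(d_s, 1), np.nan)
        si_r = np.where(d_r > 0, reads_r / np.maximum(d_r, 1), np.nan)
    return np.abs(si_s - si_r)


def null_quantile(draws: np.ndarray, level: float) -> float:
    """Null threshold at ``level``: the draw value whose strict exceedance
    fraction is closest to 1 - level.

    The null |delta| distribution is discrete (pool allele-frequency
    lattice times binomial read counts), so a plain empirical quantile can
    land on either side of a probability atom depending on simulation
    noise, flipping the realized test size far from nominal.  Following
    exact-test practice for discrete nulls, the threshold is the atom
    whose achievable size |P(|delta| > t) - (1 - level)| is smallest,
    which is stable across simulation seeds; significance downstream is
    strict exceedance of this threshold.
    """
    values, counts = np.unique(np.round(np.asarray(draws), 10), return_counts=True)
    frac_gt = 1.0 - np.cumsum(counts) / counts.sum()
    idx = int(np.argmin(np.abs(frac_gt - (1.0 - level))))
    return float(values[idx])


def null_thresholds(
    pool_sizes: tuple,
    genotype_probs: tuple,
    depths: Optional[Sequence[int]] = None,
    n_sims: int = 10_000,
    quantiles: tuple = (0.95, 0.99),
    seed: Optional[int] = None,
    bin_width: int = 5,
    max_depth: int = 100,
) -> pd.DataFrame:
    """Per-site null |delta| quantiles stratified by sequencing depth.

    Depth strata are ``bin_width``-wide bins up to ``max_depth`` (sites
    deeper than that share the top stratum); both pools are simulated at
    the stratum's representative depth.  Thresholds are made monotone
    non-increasing in depth (isotonic smoothing by a running minimum from
    deep to shallow), since the binomial read-sampling noise shrinks with
    depth.  ``depths`` optionally restricts the strata to those observed.
    """
    if any(not (0 < q < 1) for q in quantiles):
        raise ConfigError("quantiles must lie in (0, 1)")
    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} is very small for tail quantiles", stacklevel=2)
    rng = np.random.default_rng(seed)
    reps = np.arange(bin_width, max_depth + 1, bin_width)
    if depths is not None:
        observed = np.clip(
            (np.ceil(np.asarray(depths) / bin_width) * bin_width), bin_width, max_depth
        )
        reps = np.unique(observed.astype(int))
    rows = []
    for d in reps:
        draws = null_delta_samples(
            rng, n_sims, pool_sizes, int(d), int(d), genotype_probs
        )
        rows.append([int(d)] + [null_quantile(draws, q) for q in quantiles])
    cols = ["depth"] + [f"q{int(round(q * 100)):02d}" for q in quantiles]
    df = pd.DataFrame(rows, columns=cols).sort_values("depth").reset_index(drop=True)
    # isotonic: thresholds may not increase with depth
    for c in cols[1:]:
        df[c] = np.minimum.accumulate(df[c].to_numpy())
    return df


def estimate_genotype_probs(
    records: pd.DataFrame, inbreeding: float = 1.0 - 0.5**4
) -> tuple:
    """Null (P0, P1, P2) estimated from the pooled reads themselves.

    The donor-allele frequency p is the genome-wide mean donor read
    fraction over both pools; genotype frequencies assume an inbred
    population with inbreeding coefficient F (default the BC3F5 value
    1 - (1/2)^4): P(het) = 2 p (1-p) (1-F).
    """
    ok = np.isfinite(records["si_s"]) & np.isfinite(records["si_r"])
    if not ok.any():
        raise DataError("no informative sites to estimate allele frequency from")
    p = float(
        np.clip(
            0.5 * (records.loc[ok, "si_s"].mean() + records.loc[ok, "si_r"].mean()),
            1e-4,
            1 - 1e-4,
        )
    )
    p1 = 2.0 * p * (1.0 - p) * (1.0 - inbreeding)
    p2 = p - p1 / 2.0
    return (1.0 - p1 - p2, p1, p2)


def window_null_quantiles(
    records: pd.DataFrame,
    windows: pd.DataFrame,
    pool_sizes: tuple,
    genotype_probs: tuple,
    n_sims: int = 2_000,
    quantiles: tuple = (0.95, 0.99),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Null quantiles of each window's mean |delta|, from its member sites.

    The pools hold the same individuals at every site, so under the null
    the genotype-sampling part of |delta| is shared across linked sites
    rather than averaging away with window size.  Each simulation
    therefore resamples the two pools' genotype frequencies once per
    chromosome and draws read noise per site at the observed pool depths;
    window means over member sites then give ``n_sims`` null window means
    per window, whose quantiles become the window thresholds.  Returns
    ``windows`` with q95/q99-style columns appended (NaN for windows
    without informative sites).
    """
    if any(not (0 < q < 1) for q in quantiles):
        raise ConfigError("quantiles must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    qcols = [f"q{int(round(q * 100)):02d}" for q in quantiles]
    out = windows.copy()
    for c in qcols:
        out[c] = np.nan
    probs = np.asarray(genotype_probs, dtype=float)
    n_r, n_s = int(pool_sizes[0]), int(pool_sizes[1])
    for chrom in windows["chrom"].unique():
        sub = records[(records["chrom"] == chrom) & np.isfinite(records["delta"])]
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        n_sites = len(pos)
        widx = out.index[out["chrom"] == chrom]
        if n_sites == 0:
            continue
        depth_s = sub["depth_s"].to_numpy()
        depth_r = sub["depth_r"].to_numpy()
        counts_s = rng.multinomial(n_s, probs, size=n_sims)
        counts_r = rng.multinomial(n_r, probs, size=n_sims)
        freq_s = ((counts_s[:, 1] + 2 * counts_s[:, 2]) / (2.0 * n_s))[:, None]
        freq_r = ((counts_r[:, 1] + 2 * counts_r[:, 2]) / (2.0 * n_r))[:, None]
        reads_s = rng.binomial(depth_s[None, :], np.broadcast_to(freq_s, (n_sims, n_sites)))
        reads_r = rng.binomial(depth_r[None, :], np.broadcast_to(freq_r, (n_sims, n_sites)))
        with np.errstate(invalid="ignore", divide="ignore"):
            si_s = reads_s / np.maximum(depth_s[None, :], 1)
            si_r = reads_r / np.maximum(depth_r[None, :], 1)
        sims = np.abs(si_s - si_r)
        csum = np.concatenate(
            [np.zeros((n_sims, 1)), np.cumsum(sims, axis=1)], axis=1
        )
        starts = out.loc[widx, "start"].to_numpy()
        ends = out.loc[widx, "end"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends + 1, side="left")
        for row, l, h in zip(widx, lo, hi):
            if h > l:
                means = (csum[:, h] - csum[:, l]) / (h - l)
                for q, c in zip(quantiles, qcols):
                    out.loc[row, c] = null_quantile(means, q)
    return out


# ---------------------------------------------------------------------------
# QTL calling


@dataclass(frozen=True)
class QtlCall:
    chrom: str
    start: int
    end: int
    peak_start: int
    peak_end: int
    peak_mean_delta: float
    n_windows: int
    level: float


def call_qtl(windows: pd.DataFrame, level: float = 0.95) -> list:
    """Merge maximal runs of overlapping significant windows into QTL calls.

    A window is significant when unmasked and its mean |delta| strictly
    exceeds its null threshold at ``level`` (see :func:`null_quantile`
    for why the threshold is anchored on strict exceedance).  Each merged
    region reports its peak (maximum mean-delta) window.
    """
    qcol = f"q{int(round(level * 100)):02d}"
    if qcol not in windows.columns:
        raise DataError(f"windows carry no {qcol} threshold column")
    sig = windows[
        (~windows["masked"])
        & np.isfinite(windows["mean_delta"])
        & np.isfinite(windows[qcol])
        & (windows["mean_delta"] > windows[qcol])
    ]
    calls = []
    for chrom in sig["chrom"].unique():
        sub = sig[sig["chrom"] == chrom].sort_values("start")
        run = []
        prev_end = None
        for _, w in sub.iterrows():
            if prev_end is not None and w["start"] > prev_end + 1:
                calls.append(_finish_call(chrom, run, level))
                run = []
            run.append(w)
            prev_end = max(prev_end or 0, int(w["end"]))
        if run:
            calls.append(_finish_call(chrom, run, level))
    return calls


def _finish_call(chrom: str, run: list, level: float) -> QtlCall:
    peak = max(run, key=lambda w: w["mean_delta"])
    return QtlCall(
        chrom=chrom,
        start=int(min(w["start"] for w in run)),
        end=int(max(w["end"] for w in run)),
        peak_start=int(peak["start"]),
        peak_end=int(peak["end"]),
        peak_mean_delta=float(peak["mean_delta"]),
        n_windows=len(run),
        level=level,
    )


# ---------------------------------------------------------------------------
# Model / Results


class QtlSeqScan:
    """QTL-seq scan model over a susceptible/resistant pool contrast.

    Parameters
    ----------
    records
        Per-site index table from :func:`index_records` (columns chrom,
        pos, depth_s, depth_r, si_s, si_r, delta).
    chrom_lengths
        Mapping chromosome name -> length in bp.
    pool_sizes
        (n_resistant, n_susceptible) individuals bulked per pool.
    genotype_probs
        Null (P0, P1, P2) donor-dosage frequencies; by default estimated
        from the records' genome-wide donor read fraction
        (:func:`estimate_genotype_probs`), which is robust to the
        selection history of the population.  The Mendelian BC3F5
        expectation is available via :func:`bil_genotype_probs`.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        chrom_lengths: dict,
        pool_sizes: tuple = (19, 16),
        genotype_probs: Optional[tuple] = None,
    ):
        required = {"chrom", "pos", "depth_s", "depth_r", "delta"}
        if not required.issubset(records.columns):
            raise DataError(f"records missing columns {required - set(records.columns)}")
        self.records = records
        self.chrom_lengths = dict(chrom_lengths)
        self.pool_sizes = tuple(pool_sizes)
        self.genotype_probs = (
            tuple(genotype_probs)
            if genotype_probs
            else estimate_genotype_probs(records)
        )

    @classmethod
    def from_sites(
        cls,
        sites: Sequence,
        chrom_lengths: dict,
        pool_susceptible: str,
        pool_resistant: str,
        pool_sizes: tuple = (19, 16),
        genotype_probs: Optional[tuple] = None,
        min_depth: int = 1,
    ) -> "QtlSeqScan":
        rec = index_records(sites, pool_susceptible, pool_resistant, min_depth=min_depth)
        return cls(rec, chrom_lengths, pool_sizes, genotype_probs)

    def fit(
        self,
        window_size: int = 2_000_000,
        step: int = 10_000,
        min_snps: int = 3,
        n_sims: int = 2_000,
        quantiles: tuple = (0.95, 0.99),
        level: float = 0.95,
        seed: Optional[int] = None,
    ) -> "QtlSeqScanResult":
        windows = sliding_windows(
            self.records, self.chrom_lengths, window_size, step, min_snps
        )
        windows = window_null_quantiles(
            self.records,
            windows,
            self.pool_sizes,
            self.genotype_probs,
            n_sims=n_sims,
            quantiles=quantiles,
            seed=seed,
        )
        calls = call_qtl(windows, level=level)
        params = dict(
            window_size=window_size,
            step=step,
            min_snps=min_snps,
            n_sims=n_sims,
            quantiles=quantiles,
            level=level,
            seed=seed,
            pool_sizes=self.pool_sizes,
            genotype_probs=self.genotype_probs,
        )
        return QtlSeqScanResult(self.records, windows, calls, params)


@dataclass
class QtlSeqScanResult:
    """Fitted scan: per-site records, window statistics and QTL calls."""

    records: pd.DataFrame
    windows: pd.DataFrame
    calls: list
    params: dict

    def summary(self) -> str:
        n_sig = int(
            (
                (~self.windows["masked"])
                & (self.windows["mean_delta"] > self.windows[self._qcol])
            ).sum()
        )
        lines = [
            "QTL-seq scan summary",
            "====================",
            f"sites (informative): {int(np.isfinite(self.records['delta']).sum())}"
            f" / {len(self.records)}",
            f"windows: {len(self.windows)} "
            f"({int(self.windows['masked'].sum())} masked, {n_sig} significant "
            f"at level {self.params['level']})",
            f"window size / step: {self.params['window_size']} / {self.params['step']} bp",
            f"pool sizes (R, S): {self.params['pool_sizes']}",
            f"QTL calls: {len(self.calls)}",
        ]
        for c in self.calls:
            lines.append(
                f"  {c.chrom}:{c.start}-{c.end}  peak {c.peak_start}-{c.peak_end} "
                f"mean|dSNP|={c.peak_mean_delta:.3f} ({c.n_windows} windows)"
            )
        return "\n".join(lines)

    @property
    def _qcol(self) -> str:
        return f"q{int(round(self.params['level'] * 100)):02d}"

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.calls])
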