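"""Synthetic populations, phenotypes and pooled sequencing data.

Emulates the experimental design the downstream analysis assumes:

* a backcross inbred line (BIL) population — a susceptible recurrent parent
  crossed to a resistant donor, backcrossed ``n_backcrosses`` times and
  selfed ``n_selfings`` generations, with planted resistance QTLs;
* daily seedling damage scores per BPH population and replicate whose
  trapezoid AUC separates resistant from susceptible genotypes;
* pooled and individual ddRAD-style sequencing allele depths (Poisson depth
  per site, binomial donor-read sampling at the pool allele frequency);
* a fast-neutron mutant population with a configurable single-base
  substitution / deletion / insertion mutation mix.

Meioses use a no-interference model: a Poisson number of crossovers per
chromosome placed uniformly.  Everything is driven by one
:class:`numpy.random.Generator` derived from ``SimConfig.seed``, so outputs
are bit-identical across runs of the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .phenotyping import DamageSeries
from .vario import SnpSite

__all__ = [
    "Qtl",
    "SimConfig",
    "SimTruth",
    "simulate_bil_population",
    "simulate_damage_scores",
    "simulate_pool_seq",
    "simulate_mutant_population",
]

MUTATION_TYPES = ("SBS", "deletion", "insertion")


@dataclass(frozen=True)
class Qtl:
    """A planted resistance QTL.

    ``effect`` is the AUC reduction (score*days) conferred by a homozygous
    donor genotype; positive effect means the donor allele lowers damage.
    """

    chrom: int  # 0-based chromosome index
    pos: int  # bp
    effect: float


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic BIL / mutant experiment.

    Defaults mirror the screened population: 105 BC3F5 BILs, pools of 19
    resistant and 16 susceptible lines, ~20x pooled sequencing depth, five
    daily damage scores on the 1-9 SES scale, and a fast-neutron mutation
    spectrum of 56% single-base substitutions, 23% deletions and 21%
    insertions.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 30_000_000
    marker_spacing_bp: int = 25_000
    recomb_rate: float = 1.5  # expected crossovers per chromosome per meiosis
    qtls: tuple = (Qtl(0, 6_780_000, 10.0), Qtl(1, 16_220_000, 8.0))
    n_backcrosses: int = 3
    n_selfings: int = 4  # BC3F1 -> BC3F5
    n_lines: int = 105
    pool_sizes: tuple = (19, 16)  # (resistant, susceptible)
    mean_depth: float = 20.0
    mutation_rate_per_line: float = 9.6
    mutation_type_mix: tuple = (0.56, 0.23, 0.21)
    noise_sd: float = 1.0
    baseline_auc: float = 34.0  # genetic AUC of a line with no donor QTL allele
    n_days: int = 5
    populations: tuple = ("CNT", "TPY", "UBN")
    population_effect_scale: Optional[dict] = None  # pop -> multiplier on QTL effects
    retained_intervals: tuple = ()  # optional foreground-selected (chrom, start, end)
    select_resistant_backcross: bool = True  # keep donor alleles at QTLs through backcrossing
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "marker_spacing_bp",
            "n_lines",
            "n_days",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_backcrosses", "n_selfings"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.recomb_rate < 0:
            raise ConfigError("recomb_rate must be >= 0")
        if self.mean_depth < 1:
            raise ConfigError("mean_depth must be >= 1")
        if self.mutation_rate_per_line < 0:
            raise ConfigError("mutation_rate_per_line must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(self.mutation_type_mix) != 3 or any(
            p < 0 for p in self.mutation_type_mix
        ):
            raise ConfigError("mutation_type_mix must be 3 non-negative proportions")
        if abs(sum(self.mutation_type_mix) - 1.0) > 1e-9:
            raise ConfigError("mutation_type_mix must sum to 1")
        if any(n < 0 for n in self.pool_sizes) or len(self.pool_sizes) != 2:
            raise ConfigError("pool_sizes must be two non-negative counts")
        for q in self.qtls:
            if not (0 <= q.chrom < self.n_chromosomes):
                raise ConfigError(f"qtls: chromosome index {q.chrom} out of range")
            if not (1 <= q.pos <= self.chrom_length_bp):
                raise ConfigError(f"qtls: position {q.pos} outside chromosome")

    @property
    def chrom_names(self) -> tuple:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def chrom_lengths(self) -> dict:
        return {name: self.chrom_length_bp for name in self.chrom_names}


@dataclass
class SimTruth:
    """Ground truth for a simulated BIL population.

    ``genotypes`` codes donor-allele dosage 0/1/2 (0 = recipient homozygote,
    2 = donor homozygote) per line x marker.  ``qtl_dosage`` carries the
    dosage at the exact planted QTL positions, which need not be markers.
    """

    config: SimConfig
    line_ids: tuple
    marker_chrom: np.ndarray  # chromosome index per marker
    marker_pos: np.ndarray  # bp per marker
    genotypes: np.ndarray  # n_lines x n_markers, int8 in {0,1,2}
    qtl_dosage: np.ndarray  # n_lines x n_qtls
    auc_genetic: pd.DataFrame  # index line_id, one column per population

    def __post_init__(self):
        g = self.genotypes
        if g.shape != (len(self.line_ids), len(self.marker_pos)):
            raise DataError("genotype matrix dimensions do not match lines x markers")
        if not np.isin(g, (0, 1, 2)).all():
            raise DataError("genotype codes must be in {0, 1, 2}")

    @property
    def marker_names(self) -> list:
        return [
            f"M_{self.config.chrom_names[c]}_{p}"
            for c, p in zip(self.marker_chrom, self.marker_pos)
        ]

    def donor_fraction(self) -> np.ndarray:
        """Per-line donor genome fraction estimated over all markers."""
        return self.genotypes.mean(axis=1) / 2.0

    def genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes, index=list(self.line_ids), columns=self.marker_names
        )


# ---------------------------------------------------------------------------
# Meiosis


def _gamete(rng, haplos, positions, chrom_length, recomb_rate):
    """One recombinant gamete from a pair of haplotype arrays over loci."""
    n_co = rng.poisson(recomb_rate)
    start = rng.integers(2)
    if n_co == 0:
        return haplos[start].copy()
    breaks = np.sort(rng.uniform(0, chrom_length, size=n_co))
    seg = np.searchsorted(breaks, positions)
    choice = (start + seg) % 2
    return np.where(choice == 0, haplos[0], haplos[1])


def _marker_grid(config: SimConfig):
    """Loci per chromosome: regular marker grid plus the exact QTL positions."""
    marker_chrom, marker_pos = [], []
    loci = []
    for c in range(config.n_chromosomes):
        pos = np.arange(
            config.marker_spacing_bp // 2,
            config.chrom_length_bp + 1,
            config.marker_spacing_bp,
            dtype=np.int64,
        )
        qtl_pos = np.array(
            [q.pos for q in config.qtls if q.chrom == c], dtype=np.int64
        )
        allpos = np.unique(np.concatenate([pos, qtl_pos]))
        loci.append(allpos)
        marker_chrom.append(np.full(len(pos), c))
        marker_pos.append(pos)
    return loci, np.concatenate(marker_chrom), np.concatenate(marker_pos)


def simulate_bil_population(config: SimConfig) -> SimTruth:
    """Simulate ``n_lines`` independent BIL lineages.

    Each line descends from its own F1 plant through ``n_backcrosses``
    backcrosses to the recurrent parent and ``n_selfings`` selfing
    generations; heterozygosity halves per selfing generation in
    expectation, and the expected donor genome fraction after b
    backcrosses is (1/2)^(b+1).

    If ``retained_intervals`` is non-empty, backcross gametes are resampled
    (foreground marker selection) until the donor allele is retained at
    every marker inside those intervals.  With
    ``select_resistant_backcross`` (the default), the backcrossed parent of
    each generation is additionally required to keep the donor allele at
    every planted QTL, emulating the phenotypic selection of resistant
    plants at each backcross generation; the final selfing generations are
    unselected, so QTLs segregate ~1:1 among the finished lines while
    unlinked background stays at the (1/2)^(b+1) expectation.
    """
    rng = np.random.default_rng(config.seed)
    loci, marker_chrom, marker_pos = _marker_grid(config)
    n_markers = len(marker_pos)
    qtls = list(config.qtls)

    retained_mask = []
    for c in range(config.n_chromosomes):
        mask = np.zeros(len(loci[c]), dtype=bool)
        for (rc, a, b) in config.retained_intervals:
            if rc == c:
                mask |= (loci[c] >= a) & (loci[c] <= b)
        if config.select_resistant_backcross:
            for q in qtls:
                if q.chrom == c:
                    mask |= loci[c] == q.pos
        retained_mask.append(mask)

    genotypes = np.empty((config.n_lines, n_markers), dtype=np.int8)
    qtl_dosage = np.empty((config.n_lines, len(qtls)), dtype=np.int8)

    for i in range(config.n_lines):
        chrom_genos = []
        line_qtl = {}
        for c in range(config.n_chromosomes):
            pos = loci[c]
            zero = np.zeros(len(pos), dtype=np.int8)
            one = np.ones(len(pos), dtype=np.int8)
            plant = (zero, one)  # F1: recipient + donor haplotype
            for _ in range(config.n_backcrosses):
                for _attempt in range(1000):
                    g = _gamete(rng, plant, pos, config.chrom_length_bp, config.recomb_rate)
                    if not retained_mask[c].any() or g[retained_mask[c]].all():
                        break
                plant = (zero, g)
            for _ in range(config.n_selfings):
                g1 = _gamete(rng, plant, pos, config.chrom_length_bp, config.recomb_rate)
                g2 = _gamete(rng, plant, pos, config.chrom_length_bp, config.recomb_rate)
                plant = (g1, g2)
            geno = plant[0].astype(np.int8) + plant[1].astype(np.int8)
            chrom_genos.append(geno)
            for qi, q in enumerate(qtls):
                if q.chrom == c:
                    line_qtl[qi] = geno[np.searchsorted(pos, q.pos)]
        # split loci back into the marker grid
        offset = 0
        for c in range(config.n_chromosomes):
            pos = loci[c]
            grid = marker_pos[marker_chrom == c]
            idx = np.searchsorted(pos, grid)
            n = len(grid)
            genotypes[i, offset : offset + n] = chrom_genos[c][idx]
            offset += n
        for qi in range(len(qtls)):
            qtl_dosage[i, qi] = line_qtl.get(qi, 0)

    line_ids = tuple(f"BIL{i + 1:03d}" for i in range(config.n_lines))
    effects = np.array([q.effect for q in qtls])
    scale = config.population_effect_scale or {}
    auc = {}
    for pop in config.populations:
        s = float(scale.get(pop, 1.0))
        auc[pop] = config.baseline_auc - (qtl_dosage / 2.0) @ (effects * s)
    auc_genetic = pd.DataFrame(auc, index=list(line_ids))
    return SimTruth(
        config=config,
        line_ids=line_ids,
        marker_chrom=marker_chrom,
        marker_pos=marker_pos,
        genotypes=genotypes,
        qtl_dosage=qtl_dosage,
        auc_genetic=auc_genetic,
    )


# ---------------------------------------------------------------------------
# Phenotypes


def _ramp_scores(auc_target: float, n_days: int, slope: float = 1.0) -> np.ndarray:
    """Daily scores as a damage ramp whose trapezoid AUC equals the target.

    A linear series symmetric around its mean m has trapezoid AUC m*(n-1)
    regardless of slope, so the mean is set to auc/(n-1) and the slope
    capped so the ramp stays on the 1-9 scale.
    """
    m = auc_target / (n_days - 1)
    m = min(max(m, 1.0), 9.0)
    half = (n_days - 1) / 2.0
    cap = min((9.0 - m) / half, (m - 1.0) / half) if half > 0 else 0.0
    s = min(slope, max(cap, 0.0))
    return m + s * (np.arange(n_days) - half)


def simulate_damage_scores(
    truth: SimTruth,
    n_days: Optional[int] = None,
    n_reps: int = 3,
    noise_sd: Optional[float] = None,
    seed: Optional[int] = None,
) -> list:
    """Daily damage scores per line x BPH population x replicate.

    Scores are the genetic damage ramp plus N(0, noise_sd) ordinal noise,
    clamped to the 1-9 SES scale.  With no noise and an on-scale ramp the
    trapezoid AUC of each series equals the line's genetic AUC exactly, so
    the AUC gap between an all-donor and a no-donor line equals the summed
    QTL effects.
    """
    config = truth.config
    n_days = config.n_days if n_days is None else int(n_days)
    if n_days < 2:
        raise ConfigError("n_days must be >= 2 (AUC needs two time points)")
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    noise = config.noise_sd if noise_sd is None else float(noise_sd)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = []
    for line in truth.line_ids:
        for pop in config.populations:
            base = _ramp_scores(float(truth.auc_genetic.loc[line, pop]), n_days)
            for rep in range(1, n_reps + 1):
                scores = base + rng.normal(0.0, noise, size=n_days) if noise > 0 else base
                scores = np.clip(scores, 1.0, 9.0)
                out.append(
                    DamageSeries(
                        line_id=line,
                        population_id=pop,
                        replicate=rep,
                        scores=tuple(np.round(scores, 3)),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Pooled sequencing


def simulate_pool_seq(
    truth: SimTruth,
    pool_assignment: dict,
    config: Optional[SimConfig] = None,
    individuals: Sequence[str] = (),
    mean_depth: Optional[float] = None,
    seed: Optional[int] = None,
) -> list:
    """Pooled (and optional per-individual) allele depths at every marker.

    ``pool_assignment`` maps pool name -> member line ids.  Per site and
    pool, depth ~ Poisson(mean_depth) and donor reads ~ Binomial(depth, f)
    where f is the pool's true donor-allele frequency (mean dosage / 2).
    Individuals listed in ``individuals`` are sequenced the same way with
    f = dosage/2.
    """
    config = config or truth.config
    depth_mean = config.mean_depth if mean_depth is None else float(mean_depth)
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    index = {line: i for i, line in enumerate(truth.line_ids)}
    freqs = {}
    for pool, members in pool_assignment.items():
        members = list(members)
        if not members:
            raise DataError(f"pool {pool!r} is empty")
        missing = [m for m in members if m not in index]
        if missing:
            raise DataError(f"pool {pool!r}: unknown lines {missing}")
        rows = [index[m] for m in members]
        freqs[pool] = truth.genotypes[rows].mean(axis=0) / 2.0
    for line in individuals:
        if line not in index:
            raise DataError(f"individual {line!r} not in truth")
        freqs[line] = truth.genotypes[index[line]] / 2.0

    n_markers = len(truth.marker_pos)
    depth = {name: rng.poisson(depth_mean, size=n_markers) for name in freqs}
    donor = {
        name: rng.binomial(depth[name], freqs[name]) for name in freqs
    }
    sites = []
    chrom_names = config.chrom_names
    for j in range(n_markers):
        depths = {
            name: (int(depth[name][j] - donor[name][j]), int(donor[name][j]))
            for name in freqs
        }
        sites.append(
            SnpSite(
                chrom=chrom_names[truth.marker_chrom[j]],
                pos=int(truth.marker_pos[j]),
                ref_allele="A",
                donor_allele="G",
                depths=depths,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Fast-neutron mutant population


def simulate_mutant_population(
    config: SimConfig,
    n_lines: Optional[int] = None,
    genes: Optional[Sequence[tuple]] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-line mutation lists for a fast-neutron mutant population.

    Mutation counts per line are Poisson(mutation_rate_per_line); positions
    are uniform over the genome; types are drawn from ``mutation_type_mix``
    (SBS, deletion, insertion).  ``genes`` is an optional list of
    (gene_id, chrom_name, start, end) intervals; a mutation falling inside
    one is annotated with that gene id.

    Returns a DataFrame with columns line_id, chrom, pos, mut_type, gene_id.
    """
    n_lines = config.n_lines if n_lines is None else int(n_lines)
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    chrom_names = config.chrom_names
    rows = []
    for i in range(n_lines):
        line = f"JHN{i + 1:05d}"
        k = rng.poisson(config.mutation_rate_per_line)
        if k == 0:
            continue
        chroms = rng.integers(config.n_chromosomes, size=k)
        pos = rng.integers(1, config.chrom_length_bp + 1, size=k)
        types = rng.choice(len(MUTATION_TYPES), size=k, p=list(config.mutation_type_mix))
        for c, p, t in zip(chroms, pos, types):
            gene_id = None
            if genes:
                for gid, gchrom, a, b in genes:
                    if gchrom == chrom_names[c] and a <= p <= b:
                        gene_id = gid
                        break
            rows.append((line, chrom_names[c], int(p), MUTATION_TYPES[t], gene_id))
    return pd.DataFrame(
        rows, columns=["line_id", "chrom", "pos", "mut_type", "gene_id"]
    )
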