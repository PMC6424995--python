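"""Variant ingestion, quality filtering, and coding-effect annotation.

Replaces the alignment/variant-calling stages of a ddRAD-seq experiment with
ingestion of per-sample allele depths (VCF 4.x with AD, or the in-memory
:class:`SnpSite` container), and annotates biallelic SNPs and indels against
explicit gene models (ordered CDS segments plus the spliced CDS sequence).

Conventions: genomic and CDS coordinates are 1-based inclusive at every
external surface; the protein length reported for a CDS of length L is
L/3 - 1, i.e. the stop codon is excluded; the amino-acid (codon) index of a
CDS position p is ceil(p/3).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio.Seq import Seq

from .errors import DataError, NonCodingError

log = logging.getLogger(__name__)

__all__ = [
    "SnpSite",
    "GeneModel",
    "VariantEffect",
    "read_variants",
    "write_variants",
    "filter_sites",
    "cds_coordinate",
    "annotate_effect",
    "read_gene_models",
    "write_effects",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class SnpSite:
    """A biallelic site with per-sample/pool (ref, donor) allele depths."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    donor_allele: str
    depths: dict  # sample/pool name -> (ref_depth, donor_depth)
    site_quality: float = 60.0
    base_quality: float = 37.0

    def __post_init__(self):
        if self.pos < 1:
            raise DataError(f"site {self.chrom}:{self.pos}: pos must be >= 1")
        if self.ref_allele == self.donor_allele:
            raise DataError(
                f"site {self.chrom}:{self.pos}: ref and donor alleles identical"
            )
        for sample, (r, d) in self.depths.items():
            if r < 0 or d < 0:
                raise DataError(
                    f"site {self.chrom}:{self.pos} sample {sample}: negative depth"
                )

    def total_depth(self, sample: str) -> int:
        r, d = self.depths[sample]
        return r + d

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.donor_allele) == 1


@dataclass
class GeneModel:
    """A gene's coding structure: ordered CDS segments and spliced sequence.

    ``cds_segments`` are 1-based inclusive genomic intervals listed in coding
    (5'->3') order; for a minus-strand gene that means descending genomic
    coordinates.  ``cds_seq`` is the already-spliced coding-strand sequence.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple
    cds_seq: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise DataError(f"{self.gene_id}: strand must be '+' or '-'")
        segs = tuple((int(a), int(b)) for a, b in self.cds_segments)
        object.__setattr__(self, "cds_segments", segs)
        self.cds_seq = str(self.cds_seq).upper()
        total = sum(b - a + 1 for a, b in segs)
        if total != len(self.cds_seq):
            raise DataError(
                f"{self.gene_id}: CDS segments span {total} bp but sequence is "
                f"{len(self.cds_seq)} bp"
            )
        if len(self.cds_seq) % 3 != 0:
            raise DataError(
                f"{self.gene_id}: CDS length {len(self.cds_seq)} not divisible by 3"
            )
        for (a, b) in segs:
            if a > b:
                raise DataError(f"{self.gene_id}: segment {a}-{b} reversed")
        # segments must be non-overlapping and ordered 5'->3' on the coding strand
        genomic_order = segs if self.strand == "+" else segs[::-1]
        for (a1, b1), (a2, b2) in zip(genomic_order, genomic_order[1:]):
            if a2 <= b1:
                raise DataError(f"{self.gene_id}: CDS segments overlap or unordered")
        if not self.cds_seq.startswith("ATG"):
            warnings.warn(f"{self.gene_id}: CDS does not start with ATG", stacklevel=2)

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def protein_length(self) -> int:
        """Encoded protein length with the stop codon excluded."""
        return self.cds_length // 3 - 1


@dataclass(frozen=True)
class VariantEffect:
    gene_id: str
    effect_class: str  # synonymous | missense | stop_gained | inframe_indel | frameshift | non_coding
    cds_pos: Optional[int] = None
    cds_length: Optional[int] = None
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    protein_length: Optional[int] = None
    inserted_aa: Optional[int] = None  # net residues gained (+) or lost (-) by an in-frame indel

    @property
    def aa_change(self) -> str:
        if self.effect_class == "missense":
            return f"{self.ref_aa} > {self.alt_aa}{self.codon_index}/{self.protein_length}"
        if self.effect_class == "stop_gained":
            return f"stop codon{self.codon_index}/{self.protein_length}"
        if self.effect_class == "inframe_indel" and self.inserted_aa is not None:
            kind = "ins" if self.inserted_aa > 0 else "del"
            return f"{abs(self.inserted_aa)}-aa-{kind}{self.codon_index}/{self.protein_length}"
        return "-"


# ---------------------------------------------------------------------------
# VCF I/O


def read_variants(path, multiallelic: str = "skip") -> list:
    """Read a VCF 4.x with per-sample AD fields into :class:`SnpSite` records.

    ``multiallelic`` is ``"skip"`` (drop with a warning, the default — the
    downstream analysis is strictly biallelic) or ``"split"`` (emit one site
    per alternate allele, AD taken from the matching ALT column).
    """
    if multiallelic not in ("skip", "split"):
        raise DataError("multiallelic must be 'skip' or 'split'")
    sites: list[SnpSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        if "AD" not in vcf.header.formats:
            raise DataError(f"{path}: FORMAT/AD missing from VCF header")
        samples = list(vcf.header.samples)
        has_minbq = "MINBQ" in vcf.header.info
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) == 0:
                continue
            alt_indices = range(len(alts)) if multiallelic == "split" else (0,)
            if len(alts) > 1 and multiallelic == "skip":
                log.warning(
                    "skipping multiallelic record %s:%d", rec.chrom, rec.pos
                )
                continue
            for ai in alt_indices:
                depths = {}
                for s in samples:
                    ad = rec.samples[s].get("AD")
                    if ad is None or ad[0] is None:
                        raise DataError(
                            f"{path}: record {rec.chrom}:{rec.pos} sample {s}: AD missing"
                        )
                    depths[s] = (int(ad[0]), int(ad[ai + 1]))
                sites.append(
                    SnpSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        donor_allele=alts[ai],
                        depths=depths,
                        site_quality=float(rec.qual) if rec.qual is not None else 60.0,
                        base_quality=(
                            float(rec.info["MINBQ"])
                            if has_minbq and "MINBQ" in rec.info
                            else 37.0
                        ),
                    )
                )
    return sites


def write_variants(path, sites: Sequence[SnpSite], contig_lengths: Optional[dict] = None) -> None:
    """Write sites as a plain-text VCF 4.2 with per-sample AD (ref,alt)."""
    sites = list(sites)
    if not sites:
        raise DataError("no sites to write")
    samples = list(sites[0].depths)
    header = pysam.VariantHeader()
    contigs = contig_lengths or {}
    seen = dict(contigs)
    for s in sites:
        if s.chrom not in seen:
            seen[s.chrom] = None
    for chrom, length in seen.items():
        if length:
            header.contigs.add(chrom, length=length)
        else:
            header.contigs.add(chrom)
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    header.info.add("MINBQ", 1, "Float", "Minimum supporting base quality")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in sites:
            if list(s.depths) != samples:
                raise DataError("all sites must carry the same sample set, in order")
            rec = out.new_record(
                contig=s.chrom,
                start=s.pos - 1,
                alleles=(s.ref_allele, s.donor_allele),
                qual=s.site_quality,
            )
            rec.info["MINBQ"] = float(s.base_quality)
            for name in samples:
                rec.samples[name]["AD"] = s.depths[name]
            out.write(rec)


# ---------------------------------------------------------------------------
# Filtering


def filter_sites(
    sites: Iterable[SnpSite],
    min_site_quality: float = 15.0,
    min_base_quality: float = 20.0,
    min_depth: int = 6,
    samples: Optional[Sequence[str]] = None,
) -> list:
    """Apply the RAD-tag quality and coverage filters.

    A site is retained iff site_quality >= ``min_site_quality``,
    base_quality >= ``min_base_quality``, and total depth >= ``min_depth``
    in every sample/pool in ``samples`` (all carried samples if None).
    Removal counts per rule are logged.
    """
    if min(min_site_quality, min_base_quality, min_depth) < 0:
        raise DataError("filter thresholds must be >= 0")
    kept = []
    dropped = {"site_quality": 0, "base_quality": 0, "depth": 0}
    for site in sites:
        if site.site_quality < min_site_quality:
            dropped["site_quality"] += 1
            continue
        if site.base_quality < min_base_quality:
            dropped["base_quality"] += 1
            continue
        check = samples if samples is not None else list(site.depths)
        if any(site.total_depth(s) < min_depth for s in check):
            dropped["depth"] += 1
            continue
        kept.append(site)
    log.info(
        "filter_sites: kept %d, dropped %s", len(kept), dropped
    )
    return kept


# ---------------------------------------------------------------------------
# Coding-effect annotation


def cds_coordinate(gene: GeneModel, genomic_pos: int) -> int:
    """1-based CDS position of a genomic coordinate within the gene's CDS.

    Offsets accumulate across segments in coding order; on the minus strand
    the count starts from the 3'-most genomic boundary of the first coding
    segment.
    """
    offset = 0
    for a, b in gene.cds_segments:
        if a <= genomic_pos <= b:
            if gene.strand == "+":
                return offset + (genomic_pos - a) + 1
            return offset + (b - genomic_pos) + 1
        offset += b - a + 1
    raise NonCodingError(
        f"{gene.gene_id}: position {genomic_pos} is outside the CDS"
    )


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_effect(gene: GeneModel, site: SnpSite) -> VariantEffect:
    """Classify a variant's effect on the gene's coding sequence.

    SNPs are translated codon-wise with the standard genetic code;
    a substitution creating a stop is ``stop_gained``.  Indels whose net
    length change is a multiple of 3 are ``inframe_indel`` (with the
    residue count gained/lost), anything else is ``frameshift``.  A site
    outside the CDS yields a ``non_coding`` result rather than an error.
    """
    try:
        cds_pos = cds_coordinate(gene, site.pos)
    except NonCodingError:
        return VariantEffect(gene_id=gene.gene_id, effect_class="non_coding")

    length = gene.cds_length
    codon_index = math.ceil(cds_pos / 3)

    if not site.is_snp:
        net = len(site.donor_allele) - len(site.ref_allele)
        if net % 3 == 0:
            return VariantEffect(
                gene_id=gene.gene_id,
                effect_class="inframe_indel",
                cds_pos=cds_pos,
                cds_length=length,
                codon_index=codon_index,
                protein_length=gene.protein_length,
                inserted_aa=net // 3,
            )
        return VariantEffect(
            gene_id=gene.gene_id,
            effect_class="frameshift",
            cds_pos=cds_pos,
            cds_length=length,
            codon_index=codon_index,
            protein_length=gene.protein_length,
        )

    alt_base = site.donor_allele
    if gene.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    ref_base = gene.cds_seq[cds_pos - 1]
    expected_ref = (
        site.ref_allele
        if gene.strand == "+"
        else site.ref_allele.translate(_COMPLEMENT)
    )
    if ref_base != expected_ref:
        warnings.warn(
            f"{gene.gene_id}: reference allele at CDS {cds_pos} is {ref_base}, "
            f"VCF says {expected_ref}",
            stacklevel=2,
        )
    codon_start = (codon_index - 1) * 3
    ref_codon = gene.cds_seq[codon_start : codon_start + 3]
    within = cds_pos - 1 - codon_start
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gained"
    else:
        effect = "missense"
    return VariantEffect(
        gene_id=gene.gene_id,
        effect_class=effect,
        cds_pos=cds_pos,
        cds_length=length,
        codon_index=codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        protein_length=gene.protein_length,
    )


# ---------------------------------------------------------------------------
# Gene-model ingestion (GFF3 + CDS FASTA) and annotation output


def read_gene_models(gff3_path, cds_fasta_path) -> dict:
    """Load gene models from a GFF3 and a spliced-CDS FASTA.

    CDS features are grouped by their parent (mRNA/gene) ID; the FASTA must
    carry one record per gene/transcript ID with the spliced coding-strand
    sequence.  Returns ``{gene_id: GeneModel}``.
    """
    import gffutils
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    groups: dict[str, list] = {}
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.attributes.get("ID", ["?"])[0]])
        gid = parents[0]
        groups.setdefault(gid, []).append((cds.start, cds.end))
        strands[gid] = cds.strand
        chroms[gid] = cds.seqid
    models = {}
    for gid, segs in groups.items():
        if gid not in seqs:
            raise DataError(f"{gid}: CDS sequence missing from {cds_fasta_path}")
        segs.sort()
        if strands[gid] == "-":
            segs = segs[::-1]
        models[gid] = GeneModel(
            gene_id=gid,
            chrom=chroms[gid],
            strand=strands[gid],
            cds_segments=tuple(segs),
            cds_seq=seqs[gid],
        )
    return models


def write_effects(path, rows: Sequence[tuple]) -> None:
    """Write an annotation TSV mirroring the (position, gene, SNP pos/CDS
    length, effect, AAC position/protein length) report layout.

    ``rows`` are (SnpSite, VariantEffect) pairs.
    """
    out = []
    for site, eff in rows:
        out.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "gene_id": eff.gene_id,
                "cds_pos/cds_length": (
                    f"{eff.cds_pos}/{eff.cds_length}" if eff.cds_pos else "-"
                ),
                "effect": eff.effect_class,
                "aa_change": eff.aa_change,
            }
        )
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)
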