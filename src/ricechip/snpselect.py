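"""SNP discovery, the 35-bp clear-flank rule, functional annotation and
manifest summary statistics.

SNPs enter either from a multiple alignment of one gene across accessions
(columns with exactly two nucleotide states and no gap) or from bi-allelic
VCF rows. A SNP survives the clear-flank filter only if a full 35-nt flank
exists on both sides and no other candidate variant falls anywhere in that
71-nt window, so every retained SNP can be tiled as an interference-free
probe.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .models import GeneModel, SNPRecord

logger = logging.getLogger(__name__)

FLANK = 35


def trunc2(x: float) -> float:
    """Truncate (not round) to two decimals, as the chip summaries print."""
    return math.floor(x * 100.0) / 100.0


# ---------------------------------------------------------------------------
# SNP calling

def call_snps(
    aligned_sequences: list[str] | dict[str, str],
    gene: GeneModel | None = None,
    snp_prefix: str = "snp",
) -> list[SNPRecord]:
    """Bi-allelic SNPs from a gap-aware multiple alignment of one gene.

    A column is a candidate SNP iff it shows exactly two nucleotide states
    and no gap/N. The majority state is the reference allele (ties broken
    alphabetically). Positions are 1-based alignment columns; when a gene
    model is supplied they are lifted to genomic coordinates.
    """
    seqs = (
        list(aligned_sequences.values())
        if isinstance(aligned_sequences, dict)
        else list(aligned_sequences)
    )
    if not seqs:
        return []
    seqs = [s.upper() for s in seqs]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    (n_cols,) = lengths

    gene_id = gene.gene_id if gene else ""
    chrom = gene.chrom if gene else "."
    offset = gene.start - 1 if gene else 0

    snps: list[SNPRecord] = []
    n_multi = n_gapped = 0
    for col in range(n_cols):
        states = Counter(s[col] for s in seqs)
        if any(ch not in "ACGT" for ch in states):
            n_gapped += 1
            continue
        if len(states) != 2:
            if len(states) > 2:
                n_multi += 1
            continue
        # majority state is ref; tie -> alphabetical
        (a, ca), (b, cb) = sorted(states.items())
        ref, alt = (a, b) if ca >= cb else (b, a)
        pos = col + 1 + offset
        snps.append(
            SNPRecord(
                snp_id=f"{snp_prefix}_{len(snps) + 1:04d}",
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene_id=gene_id,
            )
        )
    if n_multi or n_gapped:
        logger.info(
            "discarded %d multi-state and %d gap/ambiguous columns",
            n_multi, n_gapped,
        )
    return snps


def snps_from_vcf_rows(
    rows: list[tuple[str, int, str, str, str]], gene: GeneModel
) -> list[SNPRecord]:
    """Wrap bi-allelic VCF rows falling inside the gene span."""
    return [
        SNPRecord(snp_id=rid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                  gene_id=gene.gene_id)
        for chrom, pos, ref, alt, rid in rows
        if chrom == gene.chrom and gene.start <= pos <= gene.end
    ]


# ---------------------------------------------------------------------------
# clear-flank filtering

def filter_flank_clear(
    snps: list[SNPRecord],
    gene_sequence: str,
    window: int = FLANK,
    origin: int = 1,
) -> list[SNPRecord]:
    """Keep SNPs whose +/- ``window`` neighbourhood is complete and clean.

    A SNP is retained iff (a) the window ``pos - window .. pos + window``
    lies entirely within the sequence and (b) no *other* candidate variant
    falls inside that window. Retained records get their flanks attached.
    ``origin`` is the genomic coordinate of sequence position 1, so callers
    may pass genomic SNPs together with ``gene.start``.

    The result is independent of input order.
    """
    gene_sequence = gene_sequence.upper()
    length = len(gene_sequence)
    local = [s.pos - origin + 1 for s in snps]
    occupied = sorted(local)

    kept: list[SNPRecord] = []
    for snp, pos in zip(snps, local):
        if pos - window < 1 or pos + window > length:
            continue
        lo, hi = pos - window, pos + window
        i = np.searchsorted(occupied, lo, side="left")
        j = np.searchsorted(occupied, hi, side="right")
        # the window always contains the SNP itself
        if j - i != 1:
            continue
        if gene_sequence[pos - 1] != snp.ref:
            logger.warning(
                "%s: reference base %r != sequence %r at position %d",
                snp.snp_id, snp.ref, gene_sequence[pos - 1], pos,
            )
        flank_left = gene_sequence[pos - 1 - window: pos - 1]
        flank_right = gene_sequence[pos: pos + window]
        if "N" in flank_left or "N" in flank_right:
            continue
        kept.append(
            SNPRecord(
                snp_id=snp.snp_id, chrom=snp.chrom, pos=snp.pos,
                ref=snp.ref, alt=snp.alt, gene_id=snp.gene_id,
                flank_left=flank_left, flank_right=flank_right,
                region=snp.region,
            )
        )
    return kept


# ---------------------------------------------------------------------------
# functional annotation

def annotate_region(snp: SNPRecord, gene: GeneModel) -> str:
    """Classify a SNP as synonymous/nonsynonymous/intron/utr5/utr3/unknown.

    CDS SNPs are translated in their containing codon with the reference
    and the alternate allele; minus-strand genes are handled by reading the
    CDS on the reverse complement (alleles complemented accordingly).
    """
    kind = gene.feature_at(snp.pos)
    if kind is None:
        return "unknown"
    if kind != "CDS":
        return kind
    if gene.sequence is None:
        raise ValueError(f"{gene.gene_id}: sequence required for CDS annotation")
    gene.check_protein_coding()

    intervals = gene.cds_intervals()
    # offset of snp.pos within the plus-strand concatenated CDS
    offset = 0
    for s, e in intervals:
        if s <= snp.pos <= e:
            offset += snp.pos - s
            break
        offset += e - s + 1
    cds_plus = "".join(
        gene.sequence[s - gene.start: e - gene.start + 1] for s, e in intervals
    )

    if gene.strand == "+":
        cds, idx = cds_plus, offset
        ref, alt = snp.ref, snp.alt
    else:
        cds = str(Seq(cds_plus).reverse_complement())
        idx = len(cds) - 1 - offset
        comp = str.maketrans("ACGT", "TGCA")
        ref, alt = snp.ref.translate(comp), snp.alt.translate(comp)

    if cds[idx] != ref:
        logger.warning(
            "%s: CDS base %r != ref allele %r", snp.snp_id, cds[idx], ref
        )
    codon_start = (idx // 3) * 3
    codon_ref = cds[codon_start: codon_start + 3]
    codon_alt = (
        codon_ref[: idx % 3] + alt + codon_ref[idx % 3 + 1:]
    )
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


# ---------------------------------------------------------------------------
# manifest summaries

@dataclass
class CategorySummary:
    """Per-category gene/SNP accounting of the chip manifest."""

    category: str
    n_genes: int
    n_snps: int
    snps_per_gene: float | None          # truncated to 2 decimals
    snps_per_kbp: float | None           # per total gene kbp, when known
    per_chromosome: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class RegionSummary:
    """Region-class counts/percentages plus mean adjacent-SNP spacing."""

    counts: dict[str, int]
    percentages: dict[str, int]          # rounded to nearest integer
    total: int
    mean_adjacent_kbp: float | None = None


def summarize_categories(
    counts: pd.DataFrame, gene_kbp: dict[str, float] | None = None
) -> list[CategorySummary]:
    """Category summaries from a (category, chrom, n_genes, n_snps) table.

    ``snps_per_gene`` is truncated, not rounded, to two decimals; a
    category with zero genes reports an absent (None) quotient.
    """
    required = {"category", "chrom", "n_genes", "n_snps"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    out: list[CategorySummary] = []
    for category, grp in counts.groupby("category", sort=False):
        n_genes = int(grp["n_genes"].sum())
        n_snps = int(grp["n_snps"].sum())
        per_chrom = {
            str(r.chrom): (int(r.n_genes), int(r.n_snps))
            for r in grp.itertuples()
        }
        spg = trunc2(n_snps / n_genes) if n_genes else None
        spk = None
        if gene_kbp and gene_kbp.get(category):
            spk = trunc2(n_snps / gene_kbp[category])
        out.append(
            CategorySummary(category, n_genes, n_snps, spg, spk, per_chrom)
        )
    return out


def grand_totals(summaries: list[CategorySummary]) -> dict[str, int]:
    """Chip-wide totals: genes, SNPs, SC (CSCWR+SCR) SNPs, per-chromosome."""
    per_chrom: Counter = Counter()
    for s in summaries:
        for chrom, (_, n_snps) in s.per_chromosome.items():
            per_chrom[chrom] += n_snps
    return {
        "n_genes": sum(s.n_genes for s in summaries),
        "n_snps": sum(s.n_snps for s in summaries),
        "n_sc_snps": sum(
            s.n_snps for s in summaries if s.category in ("CSCWR", "SCR")
        ),
        "per_chromosome": dict(per_chrom),
    }


def summarize_regions(
    region_counts: dict[str, int],
    total: int | None = None,
    positions: dict[str, list[int]] | None = None,
) -> RegionSummary:
    """Region shares on the manifest plus mean adjacent-SNP distance.

    Percentages are computed on the manifest total and rounded to the
    nearest integer. Adjacent distances are taken between consecutive
    sorted positions within each chromosome only (kbp).
    """
    total = total if total is not None else sum(region_counts.values())
    if total <= 0:
        raise ValueError("manifest total must be positive")
    pct = {
        k: int(round(100.0 * v / total)) for k, v in region_counts.items()
    }
    mean_kbp = None
    if positions:
        gaps: list[int] = []
        for pos in positions.values():
            srt = sorted(pos)
            gaps.extend(b - a for a, b in zip(srt, srt[1:]))
        if gaps:
            mean_kbp = float(np.mean(gaps)) / 1000.0
    return RegionSummary(dict(region_counts), pct, total, mean_kbp)


def exonic_percentage(region_counts: dict[str, int], total: int) -> int:
    """Percent of manifest SNPs in coding exons (syn + nonsyn), rounded."""
    exonic = region_counts.get("synonymous", 0) + region_counts.get(
        "nonsynonymous", 0
    )
    return int(round(100.0 * exonic / total))


def summarize_manifest(
    manifest: pd.DataFrame, gene_categories: dict[str, str]
) -> tuple[list[CategorySummary], RegionSummary]:
    """Summarise a scored manifest frame (included rows only)."""
    inc = manifest[manifest["included"]]
    rows = []
    for (category, chrom), grp in inc.assign(
        category=inc["gene_id"].map(gene_categories)
    ).groupby(["category", "chrom"]):
        rows.append(
            {
                "category": category,
                "chrom": chrom,
                "n_genes": grp["gene_id"].nunique(),
                "n_snps": len(grp),
            }
        )
    cats = summarize_categories(pd.DataFrame(rows))
    region_counts = inc["region"].value_counts().to_dict()
    positions = {
        chrom: grp["pos"].tolist() for chrom, grp in inc.groupby("chrom")
    }
    regions = summarize_regions(region_counts, len(inc), positions)
    return cats, regions
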