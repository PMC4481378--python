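"""Readers and writers for the external formats the pipeline touches.

FASTA is read through Bio.SeqIO, GFF3 through gffutils, VCF through pysam;
the tab-delimited similarity, genotype and manifest tables are plain pandas
round-trips with validated schemas.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .models import (
    CALL_TO_CODE,
    FormatError,
    Feature,
    GeneModel,
    GenotypeMatrix,
    SimilarityHit,
)

logger = logging.getLogger(__name__)

_FASTA_ALPHABET = frozenset("ACGTN")

SIMILARITY_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "align_len", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "bit_score",
]

MANIFEST_COLUMNS = [
    "snp_id", "chrom", "pos", "ref", "alt", "gene_id", "region",
    "probe_fwd", "probe_rev", "score_fwd", "score_rev", "tier", "included",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercased sequence map.

    Duplicate ids and characters outside A/C/G/T/N are format errors; an
    empty file yields an empty map with a warning.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise FormatError(
                f"{record.id}: non-ACGTN characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models

def _intron_gaps(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Gaps between consecutive exonic blocks -> intron intervals."""
    introns = []
    blocks = sorted(blocks)
    for (_, left_end), (right_start, _) in zip(blocks, blocks[1:]):
        if right_start > left_end + 1:
            introns.append((left_end + 1, right_start - 1))
    return introns


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/CDS/UTR features into GeneModel objects.

    When a gene has several mRNAs the transcript with the longest total CDS
    is used. Introns are not read from the file: they are derived as the
    gaps between consecutive CDS/UTR blocks of the chosen transcript.
    """
    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        best_feats: list[Feature] | None = None
        best_cds_len = -1
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            blocks: list[tuple[str, int, int]] = []
            for child in db.children(mrna, order_by="start"):
                kind = {
                    "CDS": "CDS",
                    "five_prime_UTR": "utr5",
                    "three_prime_UTR": "utr3",
                }.get(child.featuretype)
                if kind is None:
                    continue
                if child.start < gene.start or child.end > gene.end:
                    raise FormatError(
                        f"{gene.id}: {child.featuretype} "
                        f"[{child.start},{child.end}] outside gene span"
                    )
                blocks.append((kind, child.start, child.end))
            cds_len = sum(e - s + 1 for k, s, e in blocks if k == "CDS")
            if cds_len > best_cds_len:
                best_cds_len = cds_len
                feats = [Feature(k, s, e) for k, s, e in blocks]
                feats += [
                    Feature("intron", s, e)
                    for s, e in _intron_gaps([(s, e) for _, s, e in blocks])
                ]
                best_feats = sorted(feats, key=lambda f: f.start)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                features=best_feats or [],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# similarity table (12-column BLAST-style)

def read_similarity_table(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column tab-delimited hit table.

    Self-hits (query == subject) are retained; callers filter via
    ``hit.is_self``. A raw alignment score is not part of the tabular
    format, so ``raw_score`` is carried as NaN.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-delimited columns, "
                    f"got {len(parts)}"
                )
            hits.append(
                SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    align_len=int(parts[3]),
                    raw_score=float("nan"),
                    bit_score=float(parts[11]),
                )
            )
    return hits


def write_similarity_table(hits: list[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                        str(h.align_len), "0", "0", "1", str(h.align_len),
                        "1", str(h.align_len), "0.0", f"{h.bit_score:.2f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# genotype matrix table

def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read the tab-delimited genotype table.

    Layout: header ``marker_id`` + marker ids; two metadata rows named
    ``chrom`` and ``pos``; then one row per sample with calls in
    {AA, AB, BB, NC}.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "chrom" not in df.index or "pos" not in df.index:
        raise FormatError("genotype table missing 'chrom'/'pos' metadata rows")
    marker_ids = list(df.columns)
    chrom = list(df.loc["chrom"])
    pos = [int(p) for p in df.loc["pos"]]
    body = df.drop(index=["chrom", "pos"])
    calls = np.empty(body.shape, dtype=np.int8)
    for i, sample in enumerate(body.index):
        for j, marker in enumerate(marker_ids):
            token = body.iat[i, j]
            if token not in CALL_TO_CODE:
                raise FormatError(
                    f"unknown call token {token!r} at sample {sample!r}, "
                    f"marker {marker!r}"
                )
            calls[i, j] = CALL_TO_CODE[token]
    return GenotypeMatrix(list(body.index), marker_ids, chrom, pos, calls)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    meta = pd.DataFrame(
        [list(matrix.marker_chrom), [str(p) for p in matrix.marker_pos]],
        index=["chrom", "pos"],
        columns=matrix.marker_ids,
    )
    out = pd.concat([meta, matrix.to_frame()])
    out.index.name = "marker_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF

def read_vcf_snps(path: str | Path) -> list[tuple[str, int, str, str, str]]:
    """Bi-allelic SNP rows from a VCF as (chrom, pos, ref, alt, id) tuples.

    Indels and multi-allelic rows are skipped; the skipped count is logged.
    """
    rows: list[tuple[str, int, str, str, str]] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in "ACGT"
                or alts[0].upper() not in "ACGT"
            ):
                skipped += 1
                continue
            rows.append(
                (rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper(),
                 rec.id or f"{rec.chrom}:{rec.pos}")
            )
    if skipped:
        logger.info("skipped %d non-SNP/multi-allelic VCF rows", skipped)
    return rows


# ---------------------------------------------------------------------------
# gene lists, manifest, BED

def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene ids, one per line; '#' lines ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                ids.add(token)
    return ids


def write_manifest(frame: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    frame[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    frame["included"] = frame["included"].astype(bool)
    return frame


def write_bed(
    intervals: list[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (chrom, bed_start, bed_end, name) rows as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
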