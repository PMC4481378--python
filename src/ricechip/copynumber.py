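"""Single-copy vs multi-copy gene classification from pairwise similarity.

Genes are screened all-vs-all; any inter-gene hit at or above a bit-score
threshold (default 200) links the two genes into one paralog family. Genes
left isolated are single-copy (SC); connected components of size >= 2 are
multi-copy (MC) families and the family's copy count is the component size.

The bundled aligner is a Smith-Waterman local alignment with affine gaps
under legacy megablast-style nucleotide scoring (+2/-3, gap open 5,
extend 2); raw scores are converted to bits with the Karlin-Altschul
formula ``bits = (lambda * S - ln K) / ln 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from .models import SimilarityHit

DEFAULT_BIT_THRESHOLD = 200.0


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring and Karlin-Altschul constants.

    Gap penalties follow the BLAST convention: a gap of length k costs
    ``gap_open + k * gap_extend``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625   # nats per raw-score unit
    k: float = 0.41

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)


@dataclass(frozen=True)
class CopyNumberResult:
    gene_id: str
    status: str            # "SC" or "MC"
    family_id: str
    copy_count: int

    def __post_init__(self) -> None:
        if (self.status == "SC") != (self.copy_count == 1):
            raise ValueError("status SC iff copy_count == 1")


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    # BLAST charges open + extend for the first gap base
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def local_align(
    seq_a: str,
    seq_b: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> SimilarityHit | None:
    """Best local alignment of two nucleotide sequences, or None.

    Returns None when either sequence is empty or no positive-scoring
    local alignment exists. Intended for desk-scale inputs (a few kb);
    genome-scale screens should import precomputed hit tables instead.
    """
    scheme = scheme or ScoringScheme()
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        return None
    if set(seq_a) - set("ACGT") or set(seq_b) - set("ACGT"):
        raise ValueError("sequences must be over ACGT")
    aligner = _aligner(scheme)
    raw = aligner.score(seq_a, seq_b)
    if raw <= 0:
        return None
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    align_len = counts.identities + counts.mismatches + counts.gaps
    pct_id = 100.0 * counts.identities / align_len if align_len else 0.0
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct_id,
        align_len=align_len,
        raw_score=float(raw),
        bit_score=scheme.bit_score(raw),
    )


def all_vs_all(
    sequences: dict[str, str], scheme: ScoringScheme | None = None
) -> list[SimilarityHit]:
    """Pairwise local alignment over every unordered gene pair."""
    hits = []
    ids = sorted(sequences)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            hit = local_align(sequences[a], sequences[b], scheme, a, b)
            if hit is not None:
                hits.append(hit)
    return hits


class _DisjointSet:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def classify_copy_number(
    gene_ids: list[str],
    hits: list[SimilarityHit],
    threshold_bits: float = DEFAULT_BIT_THRESHOLD,
) -> list[CopyNumberResult]:
    """Partition genes into SC singletons and MC paralog families.

    An undirected edge joins two genes for every inter-gene hit with
    ``bit_score >= threshold_bits`` (inclusive). Self-hits are ignored.
    The family id is the lexicographically smallest member id.
    """
    genes = set(gene_ids)
    if len(genes) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    dsu = _DisjointSet(genes)
    for hit in hits:
        if hit.is_self or hit.bit_score < threshold_bits:
            continue
        for gid in (hit.query_id, hit.subject_id):
            if gid not in genes:
                raise ValueError(f"hit references unknown gene {gid!r}")
        dsu.union(hit.query_id, hit.subject_id)

    members: dict[str, list[str]] = {}
    for gid in gene_ids:
        members.setdefault(dsu.find(gid), []).append(gid)

    results = []
    for group in members.values():
        family_id = min(group)
        size = len(group)
        status = "SC" if size == 1 else "MC"
        for gid in group:
            results.append(CopyNumberResult(gid, status, family_id, size))
    results.sort(key=lambda r: r.gene_id)
    return results


def family_sizes(results: list[CopyNumberResult]) -> dict[str, int]:
    """Copy count per family (one entry per family)."""
    return {r.family_id: r.copy_count for r in results}


def mean_family_copies(
    results: list[CopyNumberResult], multi_copy_only: bool = True
) -> float:
    """Average number of copies per family (MC families by default)."""
    sizes = [
        n for n in family_sizes(results).values()
        if n >= 2 or not multi_copy_only
    ]
    if not sizes:
        raise ValueError("no qualifying families")
    return sum(sizes) / len(sizes)


def partition_categories(
    copy_results: list[CopyNumberResult],
    conserved_wr_list: set[str],
    agcr_list: set[str],
) -> dict[str, str]:
    """Assign the four chip design categories.

    AGCR membership overrides copy-number status; remaining SC genes split
    into CSCWR (on the conserved wheat-rice ortholog list) vs SCR; remaining
    MC genes become MCR.
    """
    overlap = conserved_wr_list & agcr_list
    if overlap:
        raise ValueError(
            f"genes in both conserved and AGCR lists: {sorted(overlap)[:5]}"
        )
    categories: dict[str, str] = {}
    for res in copy_results:
        if res.gene_id in agcr_list:
            categories[res.gene_id] = "AGCR"
        elif res.status == "SC":
            categories[res.gene_id] = (
                "CSCWR" if res.gene_id in conserved_wr_list else "SCR"
            )
        else:
            categories[res.gene_id] = "MCR"
    return categories
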