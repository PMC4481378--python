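"""Recipient-genome background recovery for marker-assisted backcross lines.

Informative markers are those at which the two parents carry different
homozygous calls. Each line marker is classified against the parents as
recipient-type (R), donor-type (D), heterozygous (H) or missing (M), and
background recovery is the graphical-genotyping statistic

    recovery % = 100 * (R + 0.5 * H) / (R + H + D)

computed genome-wide and per chromosome. Runs of donor-type markers are
painted as donor segments with boundaries at inter-marker midpoints, and
per-gene haplotype recovery is reported for an agronomic gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import AA, AB, BB, NOCALL, GeneModel, GenotypeMatrix


@dataclass(frozen=True)
class MarkerOrigin:
    """Parental-origin call for one informative marker in one line."""

    marker_id: str
    chrom: str
    pos: int
    origin: str  # R / D / H / M

    def __post_init__(self) -> None:
        if self.origin not in {"R", "D", "H", "M"}:
            raise ValueError(f"invalid origin {self.origin!r}")


@dataclass
class RecoveryReport:
    overall_pct: float
    per_chrom_pct: dict[str, float | None]
    donor_segments: list[tuple[str, int, int, str]] = field(default_factory=list)
    gene_status: dict[str, str] = field(default_factory=dict)
    gene_recovery_pct: float | None = None


def informative_markers(
    matrix: GenotypeMatrix, recipient: str, donor: str
) -> set[str]:
    """Marker ids where both parents are called, homozygous, and differ."""
    r, d = matrix.row(recipient), matrix.row(donor)
    hom = {AA, BB}
    keep = [
        mid
        for mid, rc, dc in zip(matrix.marker_ids, r, d)
        if rc in hom and dc in hom and rc != dc
    ]
    return set(keep)


def classify_line(
    matrix: GenotypeMatrix,
    line: str,
    recipient: str,
    donor: str,
    informative: set[str] | None = None,
) -> list[MarkerOrigin]:
    """Per-marker parental origin of a line, in matrix marker order."""
    if informative is None:
        informative = informative_markers(matrix, recipient, donor)
    if not informative:
        raise ValueError("no informative markers between the parents")
    lrow, rrow, drow = matrix.row(line), matrix.row(recipient), matrix.row(donor)
    origins: list[MarkerOrigin] = []
    for j, mid in enumerate(matrix.marker_ids):
        if mid not in informative:
            continue
        call = int(lrow[j])
        if call == NOCALL:
            origin = "M"
        elif call == AB:
            origin = "H"
        elif call == rrow[j]:
            origin = "R"
        elif call == drow[j]:
            origin = "D"
        else:
            raise ValueError(
                f"line call at {mid} matches neither parent nor AB/NoCall"
            )
        origins.append(
            MarkerOrigin(mid, str(matrix.marker_chrom[j]),
                         int(matrix.marker_pos[j]), origin)
        )
    return origins


def _recovery(counts: dict[str, int]) -> float | None:
    denom = counts.get("R", 0) + counts.get("H", 0) + counts.get("D", 0)
    if denom == 0:
        return None
    return 100.0 * (counts.get("R", 0) + 0.5 * counts.get("H", 0)) / denom


def recovery_stats(
    origins: list[MarkerOrigin],
) -> tuple[float, dict[str, float | None]]:
    """Genome-wide and per-chromosome recipient recovery percentages.

    Missing (M) markers are excluded from numerator and denominator; a
    chromosome with no informative data reports None.
    """
    overall: dict[str, int] = {}
    per_chrom: dict[str, dict[str, int]] = {}
    for o in origins:
        overall[o.origin] = overall.get(o.origin, 0) + 1
        per_chrom.setdefault(o.chrom, {})
        per_chrom[o.chrom][o.origin] = per_chrom[o.chrom].get(o.origin, 0) + 1
    total = _recovery(overall)
    if total is None:
        raise ValueError("no informative non-missing markers")
    return total, {c: _recovery(cnt) for c, cnt in per_chrom.items()}


def donor_segments(
    origins: list[MarkerOrigin],
    chrom_lengths: dict[str, int] | None = None,
) -> list[tuple[str, int, int, str]]:
    """Paint maximal donor (D) and heterozygous (H) runs as BED intervals.

    Segment boundaries fall at the midpoint between the run's bounding
    markers and the nearest discordant neighbours; runs touching a
    chromosome end clip to 0 / the chromosome length (last marker position
    when no length is supplied). Output is 0-based half-open, sorted, with
    the run type ('donor' or 'het') in the name column.
    """
    by_chrom: dict[str, list[MarkerOrigin]] = {}
    for o in origins:
        by_chrom.setdefault(o.chrom, []).append(o)

    segments: list[tuple[str, int, int, str]] = []
    for chrom in by_chrom:
        markers = sorted(by_chrom[chrom], key=lambda o: o.pos)
        chrom_end = (
            chrom_lengths[chrom] if chrom_lengths and chrom in chrom_lengths
            else markers[-1].pos
        )
        # collapse M markers: they are uninformative for segment calling
        informative = [o for o in markers if o.origin != "M"]
        i = 0
        while i < len(informative):
            kind = informative[i].origin
            if kind == "R":
                i += 1
                continue
            j = i
            while j + 1 < len(informative) and informative[j + 1].origin == kind:
                j += 1
            if i == 0:
                bed_start = 0
            else:
                bed_start = (informative[i - 1].pos + informative[i].pos) // 2
            if j == len(informative) - 1:
                bed_end = chrom_end
            else:
                bed_end = (informative[j].pos + informative[j + 1].pos) // 2
            name = "donor" if kind == "D" else "het"
            segments.append((chrom, bed_start, bed_end, name))
            i = j + 1
    segments.sort(key=lambda s: (s[0], s[1]))
    return segments


def gene_haplotype_recovery(
    origins: list[MarkerOrigin],
    gene_models: list[GeneModel],
    gene_list: set[str] | None = None,
) -> tuple[dict[str, str], float | None]:
    """Per-gene recipient-haplotype status and percent fully recovered.

    A gene is 'recipient' iff every informative in-gene marker is R
    (missing ignored), 'donor' when any marker is D, 'het' when no D but
    at least one H, and 'no_data' without informative markers. The
    recovery percentage is over genes with data only.
    """
    wanted = (
        [g for g in gene_models if gene_list is None or g.gene_id in gene_list]
    )
    status: dict[str, str] = {}
    for gene in wanted:
        in_gene = [
            o for o in origins
            if o.chrom == gene.chrom and gene.start <= o.pos <= gene.end
            and o.origin != "M"
        ]
        if not in_gene:
            status[gene.gene_id] = "no_data"
        elif any(o.origin == "D" for o in in_gene):
            status[gene.gene_id] = "donor"
        elif any(o.origin == "H" for o in in_gene):
            status[gene.gene_id] = "het"
        else:
            status[gene.gene_id] = "recipient"
    with_data = [s for s in status.values() if s != "no_data"]
    pct = (
        100.0 * sum(1 for s in with_data if s == "recipient") / len(with_data)
        if with_data
        else None
    )
    return status, pct


def analyze_line(
    matrix: GenotypeMatrix,
    line: str,
    recipient: str,
    donor: str,
    gene_models: list[GeneModel] | None = None,
    gene_list: set[str] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> RecoveryReport:
    """Full background-recovery report for one backcross-derived line."""
    informative = informative_markers(matrix, recipient, donor)
    origins = classify_line(matrix, line, recipient, donor, informative)
    overall, per_chrom = recovery_stats(origins)
    segments = donor_segments(origins, chrom_lengths)
    gene_status: dict[str, str] = {}
    gene_pct: float | None = None
    if gene_models:
        gene_status, gene_pct = gene_haplotype_recovery(
            origins, gene_models, gene_list
        )
    return RecoveryReport(
        overall_pct=overall,
        per_chrom_pct=per_chrom,
        donor_segments=segments,
        gene_status=gene_status,
        gene_recovery_pct=gene_pct,
    )
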