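"""Sample and marker quality control on genotype call matrices.

Filtering mirrors array-QC practice: samples are screened on an externally
supplied dish-QC (DQC) statistic with a strict > 0.85 cut-off, then markers
are screened on call rate with a strict > 0.95 cut-off computed over the
retained samples. DQC itself derives from raw array intensity channels and
is treated here as per-sample metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import NOCALL, GenotypeMatrix

DEFAULT_DQC_MIN = 0.85
DEFAULT_MARKER_RATE_MIN = 0.95


@dataclass
class QCReport:
    sample_call_rate: pd.Series
    marker_call_rate: pd.Series
    samples_failed: list[str] = field(default_factory=list)
    markers_failed: list[str] = field(default_factory=list)
    replicate_concordance: float | None = None
    thresholds: dict[str, float] = field(default_factory=dict)


def call_rates(matrix: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-marker called fractions (NoCall is uncalled)."""
    if matrix.n_samples == 0 or matrix.n_markers == 0:
        raise ValueError("empty genotype matrix")
    called = matrix.calls != NOCALL
    per_sample = pd.Series(
        called.mean(axis=1), index=matrix.sample_ids, name="call_rate"
    )
    per_marker = pd.Series(
        called.mean(axis=0), index=matrix.marker_ids, name="call_rate"
    )
    return per_sample, per_marker


def qc_filter(
    matrix: GenotypeMatrix,
    sample_dqc: dict[str, float],
    marker_rate_min: float = DEFAULT_MARKER_RATE_MIN,
    dqc_min: float = DEFAULT_DQC_MIN,
    sample_rate_min: float | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """One-pass QC: drop low-DQC samples, then low-call-rate markers.

    Both thresholds are strict: a sample survives only with DQC > dqc_min
    and a marker only with call rate > marker_rate_min among retained
    samples. An optional sample call-rate floor (also strict) is applied
    alongside DQC. The operation is idempotent.
    """
    missing = [s for s in matrix.sample_ids if s not in sample_dqc]
    if missing:
        raise ValueError(f"samples missing DQC values: {missing[:5]}")

    sample_rate, _ = call_rates(matrix)
    keep_samples = [
        s for s in matrix.sample_ids
        if sample_dqc[s] > dqc_min
        and (sample_rate_min is None or sample_rate[s] > sample_rate_min)
    ]
    samples_failed = [s for s in matrix.sample_ids if s not in set(keep_samples)]
    if not keep_samples:
        raise ValueError("all samples failed DQC/call-rate screening")

    trimmed = matrix.subset(samples=keep_samples)
    _, marker_rate = call_rates(trimmed)
    keep_markers = [
        m for m in trimmed.marker_ids if marker_rate[m] > marker_rate_min
    ]
    markers_failed = [
        m for m in trimmed.marker_ids if marker_rate[m] <= marker_rate_min
    ]
    filtered = trimmed.subset(markers=keep_markers)

    final_sample_rate, final_marker_rate = call_rates(filtered)
    report = QCReport(
        sample_call_rate=final_sample_rate,
        marker_call_rate=final_marker_rate,
        samples_failed=samples_failed,
        markers_failed=markers_failed,
        thresholds={
            "dqc_min": dqc_min,
            "marker_rate_min": marker_rate_min,
            **(
                {"sample_rate_min": sample_rate_min}
                if sample_rate_min is not None
                else {}
            ),
        },
    )
    return filtered, report


def replicate_concordance(
    matrix: GenotypeMatrix, pairs: list[tuple[str, str]]
) -> float:
    """Mean agreement of declared replicate pairs over co-called markers.

    Pairs with zero co-called markers are excluded with a warning.
    """
    fractions = []
    for a, b in pairs:
        ra, rb = matrix.row(a), matrix.row(b)
        both = (ra != NOCALL) & (rb != NOCALL)
        n = int(both.sum())
        if n == 0:
            warnings.warn(
                f"replicate pair ({a}, {b}) has no co-called markers; "
                "excluded", stacklevel=2,
            )
            continue
        fractions.append(float(np.sum(ra[both] == rb[both])) / n)
    if not fractions:
        raise ValueError("no usable replicate pairs")
    return float(np.mean(fractions))
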